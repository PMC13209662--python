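"""Shared fixtures: small fast geometries and the full evaluation cohort."""
from __future__ import annotations

import numpy as np
import pytest

from organotrace import GeometryPriors, OpticsModel
from organotrace.pipeline import run_cohort


@pytest.fixture()
def small_geometry() -> GeometryPriors:
    """A 512-px canvas that still fits one full-size organoid (fast)."""
    return GeometryPriors(canvas_shape=(512, 512))


@pytest.fixture()
def quiet_optics() -> OpticsModel:
    """Noise-free identity-scale optics for deterministic intensity checks."""
    return OpticsModel(baseline=0.0, photon_gain=0.0, read_noise_sd=0.0,
                       signal_counts=1.0)


@pytest.fixture(scope="session")
def evaluation_cohort():
    """The default 30 healthy + 30 injured single-organoid cohort.

    Computed once per session; several tests read its vectors, scene
    bookkeeping, and ROC summaries.
    """
    return run_cohort(30, 30, seed=1)


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
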