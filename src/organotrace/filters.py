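"""Smoothing primitives shared by the renderer and the clearing surrogate."""
from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi

# Above this sigma (in pixels) a spatial Gaussian becomes slower than an
# FFT product, so we switch to a reflect-padded Fourier-domain Gaussian.
_FFT_SIGMA_THRESHOLD = 8.0


def gaussian_smooth(data: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian blur with reflective boundary handling and unit DC gain.

    The kernel integrates to one, so the total intensity of content away
    from the borders is conserved.  ``sigma_px <= 0`` returns a float copy
    (delta kernel).
    """
    arr = np.asarray(data, dtype=np.float64)
    if sigma_px <= 0:
        return arr.copy()
    if sigma_px < _FFT_SIGMA_THRESHOLD:
        return ndi.gaussian_filter(arr, sigma_px, mode="reflect")
    pad = int(math.ceil(4.0 * sigma_px))
    # np.pad's reflect mode cannot extend past the array size; small
    # images with huge sigmas fall back to the spatial filter.
    if pad >= min(arr.shape) - 1:
        return ndi.gaussian_filter(arr, sigma_px, mode="reflect", truncate=4.0)
    padded = np.pad(arr, pad, mode="reflect")
    freq = np.fft.rfft2(padded)
    freq = ndi.fourier_gaussian(freq, sigma_px, n=padded.shape[-1])
    out = np.fft.irfft2(freq, s=padded.shape)
    return out[pad:-pad, pad:-pad]
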