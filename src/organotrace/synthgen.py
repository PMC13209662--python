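"""Synthetic organoid scenes and paired widefield renderings.

The generator emulates phalloidin-stained mouse intestinal organoids as
seen on a widefield epifluorescence microscope.  Each organoid is a
star-convex body (radial profile around a centre) decorated with
Gaussian-bump lobes that mimic crypt budding, an apical F-actin ring
drawn as a bright band just inside the boundary, and a dim interior
fill.  Healthy organoids carry several lobes and a sharp bright ring;
injured (DSS-treated) organoids are collapsed — lobes suppressed, ring
contrast strongly reduced, interior signal diffuse, boundary rougher —
and route a larger fraction of their light through the out-of-focus
haze.

Rendering convolves the noiseless specimen grid with a narrow in-focus
PSF and a broad out-of-focus PSF, mixes the two by a haze fraction, adds
a camera baseline, and applies Poisson photon noise followed by Gaussian
read noise.

The module also hosts two protocol-arithmetic helpers (serial dilution
series, cells per Matrigel dome) used by the wet-lab bookkeeping around
the imaging workflow.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .frames import CalibrationError, DomainError, ImageFrame
from .filters import gaussian_smooth

HEALTHY = "healthy"
INJURED = "injured"


class PlacementError(RuntimeError):
    """Raised when organoids cannot be placed on the requested canvas."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OrganoidShape:
    """Parametric outline and staining pattern of one organoid.

    ``lobes`` is a list of ``(angle_rad, lobe_radius_um, lobe_offset_um)``:
    each lobe adds a radial Gaussian bump of height ``lobe_offset`` and
    angular width ``lobe_radius / body_radius`` centred at ``angle``.
    ``boundary_roughness`` scales a zero-mean, unit-RMS harmonic
    perturbation of the body radius (coefficients in ``roughness_modes``).
    """

    center: tuple[float, float]  # (x, y) µm
    body_radius: float  # µm
    lobes: list[tuple[float, float, float]]
    ring_thickness: float  # µm
    ring_amplitude: float  # relative intensity
    interior_fill: float  # relative intensity
    boundary_roughness: float
    condition: str
    roughness_modes: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    # Injury phenotype of the staining pattern: fill_softness > 0 makes the
    # interior a diffuse Gaussian falloff (relative sigma in body radii)
    # instead of a uniform fill; ring_coverage < 1 breaks the apical rim
    # into patchy arcs (gap pattern in ring_gap_modes).
    fill_softness: float = 0.0
    ring_coverage: float = 1.0
    ring_gap_modes: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        if self.body_radius <= 0:
            raise DomainError("body_radius must be positive")
        if self.ring_thickness <= 0:
            raise DomainError("ring_thickness must be positive")
        if not 0.0 <= self.interior_fill <= self.ring_amplitude:
            raise DomainError("interior_fill must lie in [0, ring_amplitude]")
        if self.condition not in (HEALTHY, INJURED):
            raise DomainError(f"unknown condition {self.condition!r}")
        self.roughness_modes = np.asarray(self.roughness_modes, dtype=np.float64).reshape(-1, 3)
        self.ring_gap_modes = np.asarray(self.ring_gap_modes, dtype=np.float64).reshape(-1, 3)
        if not 0.0 < self.ring_coverage <= 1.0:
            raise DomainError("ring_coverage must lie in (0, 1]")

    # radial outline ---------------------------------------------------
    def radius_profile(self, theta: np.ndarray) -> np.ndarray:
        """Boundary radius (µm) at polar angle(s) ``theta``."""
        theta = np.asarray(theta, dtype=np.float64)
        perturb = np.zeros_like(theta)
        for k, a, b in self.roughness_modes:
            perturb += a * np.cos(k * theta) + b * np.sin(k * theta)
        r = self.body_radius * (1.0 + self.boundary_roughness * perturb)
        for angle, lobe_radius, lobe_offset in self.lobes:
            width = lobe_radius / self.body_radius  # radians
            d = np.angle(np.exp(1j * (theta - angle)))  # wrapped difference
            r = r + lobe_offset * np.exp(-0.5 * (d / width) ** 2)
        return r

    def max_radius(self) -> float:
        theta = np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False)
        return float(np.max(self.radius_profile(theta)))


@dataclass
class OpticsModel:
    """Widefield image-formation parameters.

    The out-of-focus PSF must be much broader than the in-focus one
    (``haze_sigma >= 10 * infocus_sigma``); ``haze_fraction`` is the share
    of specimen light routed through the broad blur.  ``signal_counts``
    converts the generator's relative intensities (ring amplitude 1.0)
    into detector counts.  ``photon_gain = 0`` disables Poisson noise and
    ``read_noise_sd = 0`` disables read noise.
    """

    pixel_size: float = 2.0  # µm / px
    infocus_sigma: float = 2.0  # µm
    haze_sigma: float = 100.0  # µm
    haze_fraction: float = 0.3
    baseline: float = 10.0  # counts
    photon_gain: float = 2.0  # counts / photon
    read_noise_sd: float = 2.0  # counts
    signal_counts: float = 1000.0  # counts at relative intensity 1.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise CalibrationError("pixel_size must be positive")
        if self.infocus_sigma > 0 and self.haze_sigma < 10.0 * self.infocus_sigma:
            raise DomainError("haze_sigma must be at least 10x infocus_sigma")
        if not 0.0 <= self.haze_fraction < 1.0:
            raise DomainError("haze_fraction must lie in [0, 1)")
        for name in ("baseline", "photon_gain", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


@dataclass
class ConditionEffect:
    """How DSS-like injury transforms the healthy shape priors.

    Defaults reproduce the qualitative injured phenotype: collapsed
    outline (all lobes suppressed), strongly reduced apical ring
    contrast, diffuse interior signal, rougher boundary, and more light
    lost to haze.
    """

    ring_amplitude_multiplier: float = 0.3
    interior_fill_level: float = 0.3
    haze_fraction_multiplier: float = 1.5
    lobe_suppression: float = 1.0
    roughness_increment: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.lobe_suppression <= 1.0:
            raise DomainError("lobe_suppression is a probability")
        if self.ring_amplitude_multiplier >= 1.0:
            raise DomainError("injured ring_amplitude_multiplier must be < 1")
        if self.interior_fill_level <= 0:
            raise DomainError("injured interior_fill_level must be > 0")
        if self.haze_fraction_multiplier <= 1.0:
            raise DomainError("injured haze_fraction_multiplier must be > 1")


@dataclass
class GeometryPriors:
    """Sampling priors for organoid geometry and the scene canvas.

    Diameters are sampled uniformly in ``diameter_range`` (the body
    diameter before lobes).  Jitter entries are half-widths of uniform
    multiplicative perturbations emulating organoid-to-organoid
    biological variability in staining and optical depth.
    """

    canvas_shape: tuple[int, int] = (1024, 1024)  # px (row, col)
    pixel_size: float = 2.0  # µm / px
    diameter_range: tuple[float, float] = (400.0, 500.0)  # µm
    n_lobes_range: tuple[int, int] = (4, 6)
    lobe_offset_frac: tuple[float, float] = (0.18, 0.30)  # of body radius
    lobe_radius_range: tuple[float, float] = (28.0, 40.0)  # µm
    ring_thickness: float = 15.0  # µm
    ring_amplitude: float = 1.0
    interior_fill: float = 0.05
    boundary_roughness: float = 0.015
    roughness_mode_range: tuple[int, int] = (6, 16)
    ring_gap_mode_range: tuple[int, int] = (4, 10)
    # per-organoid injury severity: relative sigma of the diffuse fill and
    # surviving fraction of the apical rim, sampled uniformly per organoid
    injured_fill_softness: tuple[float, float] = (0.2, 0.55)
    injured_ring_coverage: tuple[float, float] = (0.5, 0.8)
    injured_ring_thinning: float = 0.6  # degraded apical F-actin: thinner rim
    amplitude_jitter: float = 0.15
    haze_jitter: float = 0.2
    # Matrigel autofluorescence / illumination nonuniformity: a smooth,
    # bounded, large-scale random field added at render time (never part
    # of the organoid truth).  Its correlation length sits at the
    # clearing feature scale, so it is background to the clearing step
    # but tilts the widefield histogram and contour positions.
    debris_amplitude: tuple[float, float] = (0.02, 0.08)  # relative units
    debris_correlation: float = 400.0  # µm
    min_separation: float = 20.0  # µm between outlines
    edge_margin: float = 10.0  # µm
    max_attempts: int = 1000


@dataclass
class SceneTruth:
    """Ground truth for one rendered field.

    ``truth_grid`` is the noiseless specimen intensity (relative units,
    zero outside the union of ``object_masks``); ``haze_multiplier``
    scales the optics haze fraction for this scene (injury routes more
    light out of focus).
    """

    truth_grid: np.ndarray
    object_masks: list[np.ndarray]
    conditions: list[str]
    shapes: list[OrganoidShape]
    seed: int
    pixel_size: float
    haze_multiplier: float = 1.0
    # smooth non-negative Matrigel autofluorescence/debris texture, kept
    # separate so truth_grid stays zero outside the organoid masks
    debris_grid: np.ndarray | None = None


# ---------------------------------------------------------------------------
# shape sampling and rasterization
# ---------------------------------------------------------------------------


def _sample_shape(rng: np.random.Generator, condition: str, geometry: GeometryPriors,
                  effect: ConditionEffect) -> OrganoidShape:
    diameter = rng.uniform(*geometry.diameter_range)
    body_radius = diameter / 2.0

    lo, hi = geometry.n_lobes_range
    n_lobes = int(rng.integers(lo, hi + 1))
    rotation = rng.uniform(0.0, 2.0 * math.pi)
    lobes: list[tuple[float, float, float]] = []
    for k in range(n_lobes):
        angle = rotation + 2.0 * math.pi * k / n_lobes
        angle += rng.uniform(-0.3, 0.3) * 2.0 * math.pi / n_lobes
        lobe_radius = rng.uniform(*geometry.lobe_radius_range)
        lobe_offset = rng.uniform(*geometry.lobe_offset_frac) * body_radius
        lobes.append((float(np.angle(np.exp(1j * angle))), lobe_radius, lobe_offset))

    k_lo, k_hi = geometry.roughness_mode_range
    ks = np.arange(k_lo, k_hi + 1, dtype=float)
    coeffs_a = rng.normal(size=ks.size)
    coeffs_b = rng.normal(size=ks.size)
    rms = math.sqrt(0.5 * float(np.sum(coeffs_a**2 + coeffs_b**2)))
    if rms > 0:
        coeffs_a /= rms
        coeffs_b /= rms
    modes = np.column_stack([ks, coeffs_a, coeffs_b])

    ring_amp = geometry.ring_amplitude * (1.0 + rng.uniform(-1, 1) * geometry.amplitude_jitter)
    interior = geometry.interior_fill
    roughness = geometry.boundary_roughness
    ring_thickness = geometry.ring_thickness
    fill_softness = 0.0
    ring_coverage = 1.0

    g_lo, g_hi = geometry.ring_gap_mode_range
    gk = np.arange(g_lo, g_hi + 1, dtype=float)
    gap_a = rng.normal(size=gk.size)
    gap_b = rng.normal(size=gk.size)
    g_rms = math.sqrt(0.5 * float(np.sum(gap_a**2 + gap_b**2)))
    if g_rms > 0:
        gap_a /= g_rms
        gap_b /= g_rms
    gap_modes = np.column_stack([gk, gap_a, gap_b])

    if condition == INJURED:
        kept = [lb for lb in lobes if rng.uniform() >= effect.lobe_suppression]
        lobes = kept[:1]  # injured organoids carry at most one residual bud
        ring_amp *= effect.ring_amplitude_multiplier
        interior = effect.interior_fill_level * (1.0 + rng.uniform(-1, 1) * geometry.amplitude_jitter)
        roughness += effect.roughness_increment
        ring_thickness *= geometry.injured_ring_thinning
        fill_softness = rng.uniform(*geometry.injured_fill_softness)
        ring_coverage = rng.uniform(*geometry.injured_ring_coverage)
    interior = min(interior, ring_amp)

    return OrganoidShape(
        center=(0.0, 0.0),
        body_radius=body_radius,
        lobes=lobes,
        ring_thickness=ring_thickness,
        ring_amplitude=ring_amp,
        interior_fill=interior,
        boundary_roughness=roughness,
        condition=condition,
        roughness_modes=modes,
        fill_softness=fill_softness,
        ring_coverage=ring_coverage,
        ring_gap_modes=gap_modes,
    )


def _rasterize(shape: OrganoidShape, canvas: tuple[int, int], pixel_size: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Render one shape onto a full-canvas (intensity, mask) pair."""
    nrow, ncol = canvas
    cx, cy = shape.center
    rmax = shape.max_radius() + 2.0 * pixel_size
    r0 = max(int((cy - rmax) / pixel_size) - 1, 0)
    r1 = min(int((cy + rmax) / pixel_size) + 2, nrow)
    c0 = max(int((cx - rmax) / pixel_size) - 1, 0)
    c1 = min(int((cx + rmax) / pixel_size) + 2, ncol)
    rows = np.arange(r0, r1, dtype=np.float64) * pixel_size
    cols = np.arange(c0, c1, dtype=np.float64) * pixel_size
    yy, xx = np.meshgrid(rows - cy, cols - cx, indexing="ij")
    dist = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    rb = shape.radius_profile(theta)
    inside = dist <= rb
    ring = inside & (dist >= rb - shape.ring_thickness)
    if shape.ring_coverage < 1.0 and ring.any():
        # break the apical rim into patchy arcs: keep the fraction of rim
        # pixels where the angular gap pattern is lowest
        gap = np.zeros_like(theta)
        for k, a, b in shape.ring_gap_modes:
            gap += a * np.cos(k * theta) + b * np.sin(k * theta)
        cutoff = np.quantile(gap[ring], shape.ring_coverage)
        ring &= gap <= cutoff
    if shape.fill_softness > 0:
        sigma = shape.fill_softness * np.maximum(rb, 1e-9)
        fill = shape.interior_fill * np.exp(-0.5 * (dist / sigma) ** 2)
    else:
        fill = np.full_like(dist, shape.interior_fill)
    window = np.where(ring, shape.ring_amplitude, np.where(inside, fill, 0.0))
    intensity = np.zeros(canvas, dtype=np.float64)
    mask = np.zeros(canvas, dtype=bool)
    intensity[r0:r1, c0:c1] = window
    mask[r0:r1, c0:c1] = inside
    return intensity, mask


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def generate_scene(n_organoids: int, condition: str,
                   geometry: GeometryPriors | None = None,
                   effect: ConditionEffect | None = None,
                   seed: int = 0) -> SceneTruth:
    """Place ``n_organoids`` non-overlapping organoids of one condition.

    Deterministic for a fixed seed.  Raises :class:`PlacementError` when
    rejection sampling cannot fit an organoid within
    ``geometry.max_attempts`` attempts.
    """
    if n_organoids < 1:
        raise DomainError("n_organoids must be >= 1")
    geometry = geometry or GeometryPriors()
    effect = effect or ConditionEffect()
    rng = np.random.default_rng(seed)

    nrow, ncol = geometry.canvas_shape
    height = nrow * geometry.pixel_size
    width = ncol * geometry.pixel_size

    shapes: list[OrganoidShape] = []
    radii: list[float] = []
    for _ in range(n_organoids):
        shape = _sample_shape(rng, condition, geometry, effect)
        rmax = shape.max_radius()
        lo = rmax + geometry.edge_margin
        if lo >= width - lo or lo >= height - lo:
            raise PlacementError(
                f"canvas {geometry.canvas_shape} px is too small for an organoid of "
                f"outline radius {rmax:.0f} µm"
            )
        placed = False
        for _attempt in range(geometry.max_attempts):
            cx = rng.uniform(lo, width - lo)
            cy = rng.uniform(lo, height - lo)
            ok = all(
                math.hypot(cx - s.center[0], cy - s.center[1])
                >= rmax + r + geometry.min_separation
                for s, r in zip(shapes, radii)
            )
            if ok:
                shape.center = (cx, cy)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place organoid {len(shapes) + 1}/{n_organoids} without overlap "
                f"after {geometry.max_attempts} rejection-sampling attempts"
            )
        shapes.append(shape)
        radii.append(rmax)

    truth = np.zeros(geometry.canvas_shape, dtype=np.float64)
    masks: list[np.ndarray] = []
    for shape in shapes:
        intensity, mask = _rasterize(shape, geometry.canvas_shape, geometry.pixel_size)
        truth = np.maximum(truth, intensity)
        masks.append(mask)

    base_mult = 1.0 if condition == HEALTHY else effect.haze_fraction_multiplier
    haze_multiplier = base_mult * (1.0 + rng.uniform(-1, 1) * geometry.haze_jitter)

    debris = None
    amp_lo, amp_hi = geometry.debris_amplitude
    if amp_hi > 0:
        amplitude = rng.uniform(amp_lo, amp_hi)
        texture = gaussian_smooth(rng.normal(size=geometry.canvas_shape),
                                  geometry.debris_correlation / geometry.pixel_size)
        rms = float(np.sqrt(np.mean(texture**2)))
        if rms > 0:
            texture /= rms
        # bounded in [0, amplitude]: a smooth tilt, never a segmentable blob
        debris = amplitude * 0.5 * (1.0 + np.tanh(texture))

    return SceneTruth(
        truth_grid=truth,
        object_masks=masks,
        conditions=[condition] * n_organoids,
        shapes=shapes,
        seed=int(seed),
        pixel_size=geometry.pixel_size,
        haze_multiplier=float(haze_multiplier),
        debris_grid=debris,
    )


def _effective_haze_fraction(scene: SceneTruth, optics: OpticsModel) -> float:
    return min(optics.haze_fraction * scene.haze_multiplier, 0.95)


def render_widefield(scene: SceneTruth, optics: OpticsModel | None = None,
                     seed: int = 0) -> ImageFrame:
    """Render the widefield image of a scene.

    WF = (1 − h)·blur(truth, infocus_sigma) + h·blur(truth, haze_sigma)
    + baseline + noise, clipped at zero.  Both blurs use unit-sum kernels
    so the noiseless total intensity (before baseline) is conserved for
    interior content.  Deterministic for a fixed seed.
    """
    optics = optics or OpticsModel()
    if not np.isclose(scene.pixel_size, optics.pixel_size, rtol=1e-9, atol=0.0):
        raise CalibrationError(
            f"scene pixel size {scene.pixel_size} µm/px does not match optics "
            f"{optics.pixel_size} µm/px"
        )
    ps = optics.pixel_size
    specimen = scene.truth_grid
    if scene.debris_grid is not None:
        specimen = specimen + scene.debris_grid
    signal = specimen * optics.signal_counts
    h = _effective_haze_fraction(scene, optics)
    infocus = gaussian_smooth(signal, optics.infocus_sigma / ps)
    haze = gaussian_smooth(signal, optics.haze_sigma / ps)
    wf = (1.0 - h) * infocus + h * haze + optics.baseline

    rng = np.random.default_rng(seed)
    if optics.photon_gain > 0:
        photons = np.clip(wf, 0.0, None) / optics.photon_gain
        wf = rng.poisson(photons).astype(np.float64) * optics.photon_gain
    if optics.read_noise_sd > 0:
        wf = wf + rng.normal(0.0, optics.read_noise_sd, size=wf.shape)
    np.clip(wf, 0.0, None, out=wf)
    return ImageFrame(wf, ps)


def render_infocus(scene: SceneTruth, optics: OpticsModel | None = None) -> ImageFrame:
    """Noiseless in-focus-only rendering (reference for haze-removal checks)."""
    optics = optics or OpticsModel()
    signal = scene.truth_grid * optics.signal_counts
    data = gaussian_smooth(signal, optics.infocus_sigma / optics.pixel_size)
    return ImageFrame(data, optics.pixel_size)


# ---------------------------------------------------------------------------
# protocol arithmetic
# ---------------------------------------------------------------------------


def round_significant(x: float, sig_figs: int) -> float:
    """Round ``x`` to ``sig_figs`` significant figures."""
    if sig_figs < 1:
        raise DomainError("sig_figs must be >= 1")
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, sig_figs - 1 - exponent)


def dose_series(stock: float, dilution_factor: float, n_steps: int,
                sig_figs: int = 3) -> list[float]:
    """Serial dilution series ``[stock, stock/f, ..., stock/f**n_steps]``.

    Each concentration is rounded to ``sig_figs`` significant figures,
    matching how dose ladders are reported on plate maps.
    """
    if stock <= 0:
        raise DomainError("stock concentration must be positive")
    if dilution_factor <= 1:
        raise DomainError("dilution_factor must exceed 1")
    if n_steps < 0:
        raise DomainError("n_steps must be >= 0")
    return [round_significant(stock / dilution_factor**k, sig_figs)
            for k in range(n_steps + 1)]


def cells_per_dome(density: float, volume: float) -> int:
    """Cells seeded per Matrigel dome.

    ``density`` is in cells/cm³ and ``volume`` in µL (1 µL = 10⁻³ cm³);
    the product is rounded to the nearest whole cell.
    """
    if density < 0 or volume < 0:
        raise DomainError("density and volume must be non-negative")
    return int(round(density * volume * 1e-3))
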