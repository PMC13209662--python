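# Methods

## The measurement

`organotrace` quantifies epithelial integrity of intestinal organoids from a
single widefield (WF) fluorescence image by *differential* morphometry.  The
WF image is processed with a computational-clearing step to obtain a cleared
(CC) image; both images are segmented with identical parameters; each
organoid is described by its area A (µm²), perimeter P (µm) and circularity
c = 4πA/P²; and the per-organoid displacement from the WF point to the CC
point in (A, P, c) space — the CC−WF vector — is the diagnostic signal.

The rationale: in an intact organoid the phalloidin stain draws a bright,
sharp apical F-actin ring, so the segmented outline is pinned to a
high-contrast edge and barely moves when the out-of-focus background is
removed.  In an injured organoid the signal is weak and diffuse and the
apparent outline is substantially shaped by haze; removing that haze moves
the outline a lot.  The absolute per-component shift therefore acts as an
injury score, summarized by ROC analysis with injured as the positive class.

## Synthetic scenes

The generator emulates phalloidin-stained mouse intestinal organoids
(400–500 µm diameter) in Matrigel, imaged at 2 µm/px over a 1024×1024 px
(~2×2 mm) field.

**Geometry.** An organoid is a star-convex radial profile around its centre:
a body radius (sampled uniformly from 400–500 µm diameter) perturbed by a
unit-RMS harmonic roughness term (modes 6–16, amplitude 0.015 healthy /
0.025 injured) plus Gaussian angular bumps modelling crypt buds.  Healthy
organoids carry 4–6 narrow buds (angular width from a 28–40 µm lobe radius,
radial height 0.18–0.30 of the body radius); injury suppresses all buds
(collapse).  These priors were calibrated once so that, at cohort level,
healthy outlines have longer perimeters and lower circularity while mean
areas differ by well under 20% — the direction and magnitude pattern of the
DSS contrast the pipeline is meant to reproduce.

**Staining pattern.**  Intensity is relative to a ring amplitude of 1.0
(±15% per-organoid jitter).  Healthy: a 15 µm apical ring just inside the
boundary over a dim uniform interior (0.05).  Injured: ring amplitude ×0.3
and thinned ×0.6, the rim broken into patchy arcs (surviving coverage
sampled 0.5–0.8, gap pattern from low-order harmonics), and the interior
replaced by a diffuse Gaussian falloff (level 0.3, relative sigma sampled
0.2–0.55).  The two severity axes — fill softness (how shallow the boundary
gradient is) and rim coverage (how bridgeable the outline is) — are sampled
independently, which is what gives the area shift a different, weaker
class separation than the perimeter/circularity shifts.

**Background.**  Each scene carries a smooth, bounded Matrigel
autofluorescence/illumination field: a Gaussian random field with 400 µm
correlation length mapped through ½(1+tanh) and scaled by a per-scene
amplitude of 0.02–0.08.  It is stored separately from the organoid truth
grid.  Because its spatial scale sits at the clearing feature scale it is
removed from the CC image but tilts the WF histogram and contour positions —
a smooth, shape-preserving source of area noise in both classes.

**Optics and noise.**  WF = (1−h)·G(truth, σ_in) + h·G(truth, σ_haze) +
baseline + noise, with σ_in = 2 µm, σ_haze = 100 µm (unit-sum kernels,
reflective borders; FFT evaluation above 8 px sigma), baseline 10 counts and
a signal scale of 1000 counts.  The haze fraction is 0.3 for healthy scenes,
×1.5 for injured (more light scattered out of focus by the disrupted
epithelium), with ±20% per-scene jitter.  Noise is Poisson on photon counts
(gain 2 counts/photon) followed by Gaussian read noise (sd 2 counts),
clipped at zero.  Setting gain and read noise to zero disables noise; all
randomness flows from a single per-call seed, so every artefact is
bit-reproducible.

## Computational clearing surrogate

Vendor "instant computational clearing" is proprietary; this package
implements a documented surrogate with the same contract: isolate the
large-scale out-of-focus background and subtract it while preserving
in-focus structure.  The background is an iterative lower envelope:

    b₀ = S(image);  b_{k+1} = S(min(b_k, image))

where S is a Gaussian smoother of sigma `feature_scale/4` (median window
`feature_scale/2` as an alternative), iterated up to 10 times with a 10⁻³
relative-change early stop, finished by a pointwise `min` with the image and
clipped at zero.  The default feature scale is 450 µm, the midpoint of the
organoid diameter range it should be matched to.  Properties: the envelope
is non-negative and bounded by the image; a constant field is classified
entirely as background; the estimate is linear under positive intensity
scaling; features narrower than ~`feature_scale/10` retain ≥90% of their
amplitude.  Borders use reflective padding to avoid edge darkening that
would bias edge-adjacent morphometrics.

One deliberate consequence: a diffuse plateau at the feature scale itself
(an injured organoid's interior) is partially classified as background, and
repeated clearing keeps eroding it — the operation is approximately
idempotent only for sub-feature-scale content.  This is not a defect; it is
precisely the asymmetry between sharp and diffuse signal that the CC−WF
score exploits.

## Segmentation

A deterministic classical pipeline replaces the interactive deep-learning
segmentation used with commercial suites: Gaussian presmooth (4 µm) → Otsu
(or manual) threshold → hole filling (lumens count toward area) →
morphological opening (6 µm radius) → 8-connected labelling → area filter
(5000 µm², far below a 400 µm organoid) → consecutive relabelling.  A blank
image yields an empty label map with a logged warning.  The same parameters
are always applied to the WF and CC images of a pair; unequal treatment
would confound the CC−WF shift with parameter differences.

## Morphometrics

Area is the pixel count × pixel area.  Perimeter uses the 4-direction
Crofton estimator (recorded as `crofton-4` in output metadata); it is
validated against an independent subpixel marching-squares contour oracle
to within 2% on digital disks.  Circularity 4πA/P² can exceed 1 slightly on
small/coarse digital shapes; values above 1.05 are clamped to 1.05 and
flagged rather than rejected.

## Pairing, vectors, scores

WF and CC objects are matched greedily by descending IoU (ties: smaller
centroid distance, then smaller id), rejecting pairs under IoU 0.3.
Unmatched objects cannot define a shift and are excluded, but their counts
are reported — a high unmatched rate is itself a quality signal (severely
injured organoids occasionally contract so much under clearing that they
fall below the IoU floor).

Per pair, the vector is (ΔA, ΔP, Δc) = CC − WF.  Per-component injury
scores are the absolute shifts.  For a combined score the three
incommensurate components are robust-standardized over the cohort
(subtract the median of absolute shifts, divide by 1.4826×MAD, falling back
to the SD and then to 1 when degenerate) before taking the Euclidean norm;
the combined score is an extension beyond the per-component readout and is
labelled as such in reports.

## ROC analysis

Curves are built by sweeping thresholds over distinct score values (ties
enter jointly); the trapezoidal AUC equals the Mann–Whitney statistic
exactly, which the tests verify against brute-force pair enumeration.
Confidence intervals use the DeLong variance with a normal approximation,
truncated to [0,1]; perfect separation collapses the interval and is
flagged as degenerate (a stratified bootstrap is available for
cross-checking).  The operating point maximizes the Youden index
J = sensitivity + specificity − 1 (ties: higher sensitivity, then lower
threshold).  Injured is always the positive class and higher scores mean
more likely injured.

## Problem sizes and numerical choices

The reference experiment is 30 healthy + 30 injured single-organoid scenes
(per-scene seeds derived deterministically from one base seed), a size at
which the full pipeline runs in a few minutes on one core while the DeLong
intervals are already informative.  At that size and the defaults above the
circularity- and perimeter-shift scores separate the classes at AUC ≈
0.95–1.0 and the area shift is consistently the weakest component —
mirroring the qualitative ordering the differential readout is designed to
show.  Smoothing switches from spatial to padded-FFT evaluation above 8 px
sigma; envelope iteration stops early below a 10⁻³ relative change;
pairing and labelling are fully deterministic, and reruns with the same
seed are bit-identical end to end.

## What the synthetic cohort does and does not show

The generator reproduces the *mechanisms* the differential readout relies
on — sharp-ring versus diffuse-signal contrast, haze at a much larger
spatial scale than in-focus structure, broken apical rims, background
texture, camera noise — but not real microscopy: no z-structure or depth-
dependent PSF, no multi-channel stains, no touching or out-of-frame
organoids, no true Matrigel debris particles, and segmentation here is
classical rather than learned.  Passing cohorts therefore demonstrate that
the pipeline's statistics behave as designed under a faithful image-formation
model, not that any particular AUC will be attained on a given instrument's
data.  Absolute circularity values also depend on the perimeter estimator;
comparisons across software should use the same estimator throughout.
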