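# Methods

## Imaging model and coordinate conventions

All images are grayscale `T × H × W` stacks with a frame interval Δt (s) and
pixel size (µm) supplied explicitly — vendor TIFF tags are not parsed, since
in practice the scale is set by hand at acquisition. Coordinates are 0-based,
`x` is the column, `y` the row, and pixel centers sit at integer positions.
Integer stacks round-trip bit-identically through TIFF; float stacks are
stored as 32-bit float.

## Synthetic acquisitions

The simulator emulates variable-angle TIRF acquisitions of single
PM-resident fluorophores. Defaults follow the typical regime for membrane
cargo (200 frames, Δt = 0.15 s → a 30 s window, 0.1 µm pixels).

Per movie:

- **Arrivals.** New particles appear per frame as Poisson(`arrival_rate`),
  placed uniformly inside a PSF-safe margin. An optional `n_initial`
  population is present at frame 0 and recorded left-censored; it models a
  stable, pre-existing cohort such as a raft-marker protein.
- **Dwells.** Each particle draws a membrane dwell from
  `exponential(mean_s)` or `fixed(s)` and stays for
  `max(1, ceil(dwell/Δt))` frames — a particle visible at all dwelt at least
  one exposure. Dwells running past the last frame are truncated and
  recorded right-censored (`death_cause = "end"`), never resampled, so
  overlength kymograph traces are reproducible. Photobleaching terminates
  emission with probability `bleach_rate` per frame and is recorded as its
  own death cause: only dwell-law expiry counts as a membrane-departure
  event.
- **Motion.** 2D Brownian steps with per-axis variance `2·D·Δt`, converted
  to pixels. The default D = 0.002 µm²/s gives a step SD of ~0.25 px per
  150 ms frame — quasi-stationary on the kymograph timescale, as appropriate
  for the scan-line method (a strongly mobile particle has no single line
  position).
- **Camera.** Each live particle emits Poisson(`photons_per_frame`) photons
  per frame, rendered as a pixel-integrated Gaussian (difference of error
  functions over pixel bounds, not center sampling, so photometry is correct
  at small σ). Per-pixel Poisson background and Gaussian read noise are
  added; negative values are clipped at zero. Defaults (400 photons/frame,
  σ = 1.3 px, background 20, read noise 2) give a peak SNR of roughly 4–5 —
  spots clearly detectable at a 150 ms exposure. These are a documented
  choice of a realistic operating point, not a measured calibration.
- **Second channel.** A `coloc_fraction` of channel-A particles get a
  channel-B partner reusing the A path exactly; channel B is rendered after
  applying a known `(dx, dy)` offset (the chromatic/geometric "model error"
  between optical paths) and also receives its own independent arrivals.

One seeded `numpy` Generator drives a whole simulation; identical parameters
and seed give bit-identical movies and ground-truth tables.

What the simulator does **not** emulate: anisotropic or depth-dependent
PSFs, evanescent-field decay, sCMOS fixed-pattern noise, merge/split events,
or 3D motion. Passing recovery tests therefore demonstrates correctness of
the analysis chain under an idealized but physically reasonable camera and
motion model — not robustness to every artifact of real acquisitions.

## Spot detection and linking

Spots are called per frame by a negated Laplacian-of-Gaussian at the PSF
scale; maxima must exceed the filtered median by `k = 3` robust SDs
(1.4826 × MAD — robust to the bright spots themselves). Near-duplicate
maxima within ~2σ are suppressed strongest-first. Sub-pixel positions come
from an intensity-weighted centroid in a `(2·ceil(3σ)+1)²` window with the
window median subtracted; windows clipped by the border are kept but flagged
`edge`. On noiseless frames, where the MAD collapses to zero, a scale tied
to the response range is substituted so that isolated ideal spots are still
found.

Linking is greedy nearest-neighbour: per frame, all (active track, new spot)
pairs within `max_disp × (gap+1)` are sorted globally by distance (ties by
lower track id) and assigned first-come; unmatched spots seed new tracks and
tracks may bridge up to `max_gap = 1` missing frames (single-frame
blinking). Greedy assignment is deterministic and adequate at the particle
densities of interest; it is isolated behind one function and swappable for
optimal bipartite matching. Localizations are canonically ordered within a
frame first, so linking is invariant to input permutation. The default
search radius is 3 px, or `3·sqrt(2·D·Δt)/pixel_size` when a diffusion
bound is known. At `k = 3` a few noise maxima per frame survive; they form
1–2 frame tracks and are neutralized downstream (below) rather than by
raising the detection threshold, which would cost sensitivity at the
segment ends.

## Kymographs and dwell segments

A scan line samples unit-spaced points from `p0` toward `p1`
(`L = floor(|p1−p0|)+1` points — the last point falls short of `p1` for
non-integer lengths). For each point, `linewidth` (odd; default 11) samples
spaced 1 px along the perpendicular are read by bilinear interpolation and
reduced by max (default) or mean. Axis-aligned integer lines with width 1
reduce to exact pixel reads; extraction is verified against a brute-force
nested-loop oracle to 1e−9.

**Binarization.** Signal pixels are those above a sigma-clipped background
estimate: starting from the lower half of the intensity distribution, the
threshold `median + 3·(1.4826·MAD)` is iterated to a fixed point. Plain
whole-matrix median/MAD statistics fail when a resident particle spans the
whole movie and covers ~half of the kymograph pixels; initializing from the
lower half keeps the estimate on the background mode, while for pure noise
the iteration relaxes back to the usual `median + 3σ`. (The original
interactive protocol never states a threshold; this is this package's
explicit, documented choice. Otsu's method is available as an alternative.)

**Segments.** 8-connected components of the signal mask become dwell
segments; components overlapping in space but separated by at most
`max_gap_frames = 1` are bridged (blinking), and components smaller than
`min_area_px = 4` pixels are discarded — a real diffraction-limited visit
covers at least ~2 columns × 2 frames, while isolated noise exceedances are
1–3 pixels. Segment frames are inclusive: `dwell = (end − start + 1)·Δt`.

**Censoring.** Segments touching frame 0 or frame T−1 are censored on that
side and excluded from dwell summaries — mirroring the practice of
abandoning overlength lines rather than imputing them. No survival-model
correction is attempted (a documented non-goal); consequently reported mean
dwells are conditional on the visit fitting inside the recording window.

**Validation.** Each uncensored segment is cross-checked against the
trajectories: a trajectory supports a segment if ≥ `min_support_frames = 3`
of its localizations during the segment's time span fall inside the
footprint (the covered stretch of line, widened by half the linewidth and by
`match_radius = 2` px). Exactly one supporter whose start/end agree within
±2 frames (sub-threshold first/last frames) → `validated`; two or more
supporters → `rejected(merged)` — the fused-trace artifact; none →
`rejected(unsupported)`. The 3-frame support minimum means brief incursions
(stray noise detections, a particle clipping a footprint corner) can neither
anchor nor veto a segment, at the cost that dwells shorter than three frames
are never validated. Validation replaces interactive rotation of the 2D+t
volume; static orthogonal maximum-intensity projections (xy, xt, yt) are
rendered as the visual counterpart.

## Spatial clustering index

`SCI = mean(top set) / mean(bottom set)` where both sets contain
`max(1, floor(0.05·n))` pixels of the (optionally ROI-restricted) image —
floor with a 1-pixel minimum fixes the otherwise-unstated tie/rounding
behavior. SCI is scale-invariant and equals 1 for a constant image; it is
undefined (an error, with a suggested background offset) when the bottom
mean is zero. Stacks are scored per frame and summarized as mean ± SD, with
the per-frame values retained, since whether the index should be pooled
per cell or per frame is a reporting choice.

## Two-channel registration and colocalization

The inter-channel offset is estimated by Fourier phase cross-correlation
with local upsampling (sub-pixel precision ≈ 1/upsample px) and applied as a
translation-only resampling (bilinear; out-of-bounds pixels filled with the
frame median and masked invalid). Translation covers the chromatic offset at
this field size; an affine model is deliberately out of scope. Featureless
inputs return the identity flagged low-confidence (Pearson score of the
aligned overlap < 0.2).

Colocalization is **A-conditional** by design — the scientific question is
whether the mobile receptor enters the stable marker's domains, not the
reverse. Per A-trajectory, the best B-partner maximizes co-present frames
with per-frame distance ≤ 2 px (≈ the diffraction limit at 0.1 µm/px), ties
broken by smaller mean distance; `overlap ≥ 3` frames ⇒ colocalized. The
summary fraction carries a bootstrap 95% CI over A-trajectories. In the
recovery benchmark, the channel transform is calibrated once on a fully
colocalized acquisition (the in-silico analogue of a bead calibration) —
phase correlation has nothing to lock onto when the channels share no
structure — and A-trajectories shorter than `min_frames + 2` frames are
excluded from the denominator: with a 3-frame overlap requirement, a single
detection dropout in the other channel would misclassify a 3-frame track, so
the colocalized state of such brief tracks is not assessable. The
kymograph-level counterpart reports `|A⁺ ∩ B⁺| / |A⁺|` over binarized
kymograph pixels from the same scan line — asymmetric under A↔B unless
`|A⁺| = |B⁺|`, with the A-conditional direction fixed and stated.

## Pipeline, statistics, and reproducibility

`run_pipeline` executes input → track → scan lines → kymograph/dwell → SCI →
colocalization from one config; any stage failure aborts with the stage name
and cause, and per-stage counts (trajectories, segments kept/rejected by
reason) make rejection rates auditable. Auto scan-line mode places a
horizontal line of length `2·ceil(3σ)+1` px through each trajectory's
time-median position (trajectories shorter than 3 frames are skipped as
likely stray detections; centers are clamped so the footprint stays in
bounds) — deterministic where manual particle selection is not. A manifest
(config + package version + seed) accompanies every run; identical config
and seed reproduce every output byte.

Group comparisons use a two-sample *t*-test. Welch's flavor is the default —
there is no a-priori variance-homogeneity guarantee between treatments — and
the classic equal-variance Student's flavor is available where comparability
with that convention is wanted. Censored dwells are rejected outright, with
an instruction to filter, so an "overlength" trace can never leak into a
mean.

## Benchmark problem sizes

The recovery experiments (`smkymo.evaluation`, also driven by
`scripts/acceptance.py`) use: ~300 particles at 1.5 arrivals/frame in a
256×256 px field for dwell recovery (footprint collisions stay rare at that
density); 20 pre-existing particles with a 60 s mean dwell in 64×64 px for
the censoring regime; 50 noise replicates of a constructed two-particle
fused trace for merged-trace rejection; and ~200 A-particles per condition
at colocalized fractions {0, 0.3, 0.6, 1.0} in 128×128 px. Each experiment
completes in seconds to tens of seconds on one CPU.

## Known limitations

- Dwell estimates are frame-quantized (±1 frame discretization) and
  conditional on uncensored visits; no survival correction.
- Greedy linking can swap identities at high densities or large
  displacements; densities well below one particle per search disc are
  assumed.
- Validation needs trajectories from the same stack; segments over regions
  where detection fails are rejected as unsupported rather than rescued.
- The SCI depends on the analyzed region containing genuine background in
  its lower percentile; a saturated or offset-free image makes it undefined.
- Registration is translation-only; field-dependent distortion is not
  modeled.
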