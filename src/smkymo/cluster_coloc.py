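"""Spatial clustering index, two-channel registration, and colocalization.

The spatial clustering index (SCI) quantifies lateral organisation of a
membrane protein in a single-molecule image: the mean of the brightest 5% of
pixels divided by the mean of the dimmest 5%.  A homogeneous field gives
SCI = 1; concentrating the same photon budget into fewer, brighter puncta
raises it.

Two-colour experiments need the chromatic/geometric offset between the
channels (e.g. GFP vs mCherry optical paths) corrected before any
colocalization call; this is done by sub-pixel phase cross-correlation and a
translation-only resampling.  Colocalization itself is reported two ways:
trajectory overlap (fraction of channel-A particles co-moving with a
channel-B particle within a distance threshold for a minimum number of
frames — A-conditional by design) and kymograph overlap (fraction of A-signal
pixels coinciding with B-signal along the same scan line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .detect_track import Trajectory
from .errors import ParameterError, UndefinedSCIError
from .image_io import ImageStack
from .kymograph import Kymograph, _binarize

__all__ = [
    "SCIResult",
    "RegistrationTransform",
    "ColocResult",
    "KymographOverlap",
    "compute_sci",
    "estimate_registration",
    "apply_registration",
    "colocalize_trajectories",
    "kymograph_overlap",
]


@dataclass
class SCIResult:
    """Spatial clustering index of an image or stack.

    For a stack the SCI is computed per frame; ``value``/``sd`` are then the
    mean and SD over frames and ``per_frame`` holds the individual values.
    """

    value: float
    percentile: float
    n_top: int
    n_bottom: int
    n_roi_pixels: int
    sd: float | None = None
    per_frame: list[float] | None = None


def _sci_of_values(values: np.ndarray, percentile: float) -> tuple[float, int]:
    n = values.size
    k = max(1, int(np.floor(percentile * n)))
    srt = np.sort(values, kind="stable")
    bottom = srt[:k]
    top = srt[n - k:]
    bottom_mean = float(bottom.mean())
    if bottom_mean == 0.0:
        raise UndefinedSCIError(
            "bottom-percentile mean is 0; SCI undefined — add a background "
            "offset or enlarge the ROI"
        )
    return float(top.mean()) / bottom_mean, k


def compute_sci(
    image: np.ndarray | ImageStack,
    roi: np.ndarray | None = None,
    percentile: float = 0.05,
) -> SCIResult:
    """Compute the spatial clustering index.

    ``value = mean(top set) / mean(bottom set)`` where both sets hold
    ``max(1, floor(percentile * n))`` pixels of the (ROI-restricted) image.
    A 3D stack is scored per frame and summarised as mean and SD.
    """
    if not (0 < percentile <= 0.5):
        raise ParameterError("percentile must be in (0, 0.5]")
    pixels = image.pixels if isinstance(image, ImageStack) else np.asarray(image)
    if pixels.ndim == 2:
        frames = pixels[np.newaxis]
    elif pixels.ndim == 3:
        frames = pixels
    else:
        raise ParameterError("image must be 2D or a T x H x W stack")
    if np.any(frames < 0):
        raise ParameterError("SCI requires non-negative intensities")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != frames.shape[1:]:
            raise ParameterError("roi mask must match the frame shape")
        n_roi = int(roi.sum())
    else:
        n_roi = frames.shape[1] * frames.shape[2]
    if n_roi < 2:
        raise ParameterError("roi must contain at least 2 pixels")

    values = []
    k = 0
    for frame in frames:
        vals = frame[roi] if roi is not None else frame.ravel()
        v, k = _sci_of_values(np.asarray(vals, dtype=np.float64), percentile)
        values.append(v)
    if len(values) == 1:
        return SCIResult(
            value=values[0],
            percentile=percentile,
            n_top=k,
            n_bottom=k,
            n_roi_pixels=n_roi,
        )
    arr = np.asarray(values)
    return SCIResult(
        value=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        per_frame=values,
        percentile=percentile,
        n_top=k,
        n_bottom=k,
        n_roi_pixels=n_roi,
    )


@dataclass
class RegistrationTransform:
    """Sub-pixel translation of channel B relative to channel A.

    ``(dx, dy)`` is the offset such that ``B[y, x] ~ A[y - dy, x - dx]``;
    :func:`apply_registration` undoes it.  ``score`` is the Pearson
    correlation of the aligned overlap; featureless inputs return the
    identity with ``low_confidence`` set.
    """

    dx: float
    dy: float
    score: float
    low_confidence: bool = False


def estimate_registration(
    image_a: np.ndarray,
    image_b: np.ndarray,
    upsample: int = 20,
) -> RegistrationTransform:
    """Estimate the translation between two channels by phase correlation.

    Fourier phase cross-correlation with local upsampling gives sub-pixel
    precision of roughly ``1 / upsample`` px.  Flat (featureless) images have
    no correlation peak; the identity is returned flagged low-confidence.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError("images must share one shape")
    if a.std() == 0.0 or b.std() == 0.0:
        return RegistrationTransform(0.0, 0.0, 0.0, low_confidence=True)
    shift, error, _ = phase_cross_correlation(
        a, b, upsample_factor=upsample, normalization=None
    )
    # skimage returns the (row, col) shift that maps B onto A; our transform
    # stores B's offset relative to A, which is its negation.
    dy, dx = -float(shift[0]), -float(shift[1])

    aligned = ndimage.shift(b, (-dy, -dx), order=1, mode="nearest")
    score = float(np.corrcoef(a.ravel(), aligned.ravel())[0, 1])
    return RegistrationTransform(
        dx=dx, dy=dy, score=score, low_confidence=bool(score < 0.2)
    )


def apply_registration(
    stack: ImageStack, transform: RegistrationTransform
) -> tuple[ImageStack, np.ndarray]:
    """Translate every frame by ``(-dx, -dy)`` to align channel B onto A.

    Bilinear interpolation; pixels sampled from outside the frame are filled
    with the frame's median and marked invalid in the returned mask (True =
    valid).  Integer shifts relocate pixels exactly.
    """
    dx, dy = transform.dx, transform.dy
    h, w = stack.frame_shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    src_y = ys + dy
    src_x = xs + dx
    valid = (src_y >= 0) & (src_y <= h - 1) & (src_x >= 0) & (src_x <= w - 1)
    coords = np.stack([src_y.ravel(), src_x.ravel()])
    out = np.empty_like(stack.pixels, dtype=np.float64)
    for t in range(stack.n_frames):
        frame = stack.frame(t).astype(np.float64)
        fill = float(np.median(frame))
        warped = ndimage.map_coordinates(
            frame, coords, order=1, mode="nearest"
        ).reshape(h, w)
        warped[~valid] = fill
        out[t] = warped
    registered = ImageStack(
        pixels=np.clip(out, 0.0, None),
        frame_interval_s=stack.frame_interval_s,
        pixel_size_um=stack.pixel_size_um,
        channel_label=stack.channel_label,
    )
    return registered, valid


@dataclass
class ColocResult:
    """Trajectory-overlap colocalization, conditioned on channel A.

    ``per_trajectory`` has one row per A-trajectory: best B-partner id,
    overlap frames (co-present frames with distance <= threshold), overlap
    fraction of the A lifetime, mean pairwise distance during overlap, and
    the colocalized call.  ``summary`` is the colocalized fraction among
    A-trajectories with a bootstrap percentile CI.
    """

    per_trajectory: pd.DataFrame
    summary: float | None
    ci_low: float | None
    ci_high: float | None
    dist_thresh_px: float
    min_frames: int
    flagged_empty: bool = False


def colocalize_trajectories(
    trajs_a: list[Trajectory],
    trajs_b: list[Trajectory],
    dist_thresh_px: float = 2.0,
    min_frames: int = 3,
    n_boot: int = 500,
    seed: int = 0,
) -> ColocResult:
    """Call colocalization per A-trajectory against registered B-trajectories.

    For each A-trajectory the best B-partner maximises the number of
    co-present frames with per-frame distance <= ``dist_thresh_px`` (ties:
    smaller mean distance).  A-trajectories with ``overlap_frames >=
    min_frames`` are colocalized.  The summary fraction carries a bootstrap
    95% CI over A-trajectories.
    """
    if dist_thresh_px <= 0:
        raise ParameterError("dist_thresh_px must be > 0")
    if min_frames < 1:
        raise ParameterError("min_frames must be >= 1")
    if not trajs_a:
        return ColocResult(
            per_trajectory=pd.DataFrame(
                columns=[
                    "traj_a",
                    "traj_b",
                    "overlap_frames",
                    "overlap_fraction",
                    "mean_dist_px",
                    "colocalized",
                ]
            ),
            summary=None,
            ci_low=None,
            ci_high=None,
            dist_thresh_px=dist_thresh_px,
            min_frames=min_frames,
            flagged_empty=True,
        )

    b_index = [
        (tr.id, dict(zip(tr.frames.tolist(), tr.xy))) for tr in trajs_b
    ]
    rows = []
    for ta in trajs_a:
        frames_a = ta.frames
        xy_a = ta.xy
        lifetime = len(frames_a)
        best = (0, np.inf, None)  # (overlap, mean_dist, b_id)
        for b_id, b_pos in b_index:
            dists = [
                float(np.hypot(*(xy_a[i] - b_pos[f])))
                for i, f in enumerate(frames_a.tolist())
                if f in b_pos
            ]
            close = [d for d in dists if d <= dist_thresh_px]
            if not close:
                continue
            overlap = len(close)
            mean_d = float(np.mean(close))
            if overlap > best[0] or (overlap == best[0] and mean_d < best[1]):
                best = (overlap, mean_d, b_id)
        overlap, mean_d, b_id = best
        rows.append(
            (
                ta.id,
                b_id,
                overlap,
                overlap / lifetime,
                mean_d if np.isfinite(mean_d) else np.nan,
                overlap >= min_frames,
            )
        )
    per = pd.DataFrame(
        rows,
        columns=[
            "traj_a",
            "traj_b",
            "overlap_frames",
            "overlap_fraction",
            "mean_dist_px",
            "colocalized",
        ],
    )
    coloc = per["colocalized"].to_numpy(dtype=bool)
    summary = float(coloc.mean())
    rng = np.random.default_rng(seed)
    n = len(coloc)
    boots = rng.choice(coloc.astype(float), size=(n_boot, n), replace=True)
    frac = boots.mean(axis=1)
    return ColocResult(
        per_trajectory=per,
        summary=summary,
        ci_low=float(np.percentile(frac, 2.5)),
        ci_high=float(np.percentile(frac, 97.5)),
        dist_thresh_px=dist_thresh_px,
        min_frames=min_frames,
    )


@dataclass
class KymographOverlap:
    """A-conditional pixel overlap of two kymographs on the same scan line.

    ``fraction = |A+ ∩ B+| / |A+|`` over kymograph pixels; asymmetric by
    construction (the question is whether A-signal sits on pre-existing
    B-signal).  ``rgb`` is a merged T x L x 3 view (A in red, B in green,
    overlap yellow); ``undefined`` flags an empty A mask.
    """

    fraction: float | None
    n_a: int
    n_overlap: int
    rgb: np.ndarray
    undefined: bool = False


def kymograph_overlap(
    kymo_a: Kymograph,
    kymo_b: Kymograph,
    threshold_method: str = "mad",
    threshold_k: float = 3.0,
) -> KymographOverlap:
    """Fraction of A-signal kymograph pixels that coincide with B-signal.

    Both kymographs (same scan line on registered stacks) are binarized with
    the segment-detection threshold; the A-conditional overlap fraction and a
    merged RGB kymograph are returned.
    """
    if kymo_a.matrix.shape != kymo_b.matrix.shape:
        raise ParameterError("kymographs must share one shape")
    mask_a = _binarize(kymo_a.matrix, threshold_method, threshold_k)
    mask_b = _binarize(kymo_b.matrix, threshold_method, threshold_k)
    rgb = np.zeros(mask_a.shape + (3,), dtype=np.float32)
    rgb[..., 0] = mask_a
    rgb[..., 1] = mask_b
    n_a = int(mask_a.sum())
    n_overlap = int((mask_a & mask_b).sum())
    if n_a == 0:
        return KymographOverlap(
            fraction=None, n_a=0, n_overlap=0, rgb=rgb, undefined=True
        )
    return KymographOverlap(
        fraction=n_overlap / n_a, n_a=n_a, n_overlap=n_overlap, rgb=rgb
    )
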