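"""Kymograph extraction, dwell-segment detection, censoring and validation.

A kymograph is a space-time image: one row per movie frame, one column per
sample point along a scan line.  A membrane protein sitting under the line
appears as a horizontal streak whose length is its dwell time.  Two rules
guard the dwell estimates:

* **Censoring** — a streak touching the first or last frame ("overlength
  line") has an unknown true duration; it is flagged and excluded from dwell
  summaries rather than measured.
* **Trajectory cross-validation** — a streak can be an artifact of two
  particles successively occupying the same line position, which fuses their
  runs into one long line.  Each segment is checked against the full 2D+t
  trajectories: exactly one supporting trajectory with matching start/end
  validates the segment; two or more reject it as *merged*; none rejects it
  as *unsupported*.  This automates the by-eye check of rotating the 2D+t
  volume in a 3D viewer, whose static stand-in (orthogonal projections) is
  also provided.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .detect_track import Trajectory, _robust_sd
from .errors import DegenerateThresholdError, GeometryError, ParameterError
from .image_io import ImageStack

__all__ = [
    "ScanLine",
    "Kymograph",
    "DwellSegment",
    "sample_line",
    "extract_kymograph",
    "detect_segments",
    "measure_dwell",
    "validate_segment",
    "validate_segments",
    "render_views",
    "mean_dwell",
]

DEFAULT_LINEWIDTH = 11  # odd; the recommended width for plant-cell particles

STATUS_PENDING = "pending"
STATUS_VALIDATED = "validated"
STATUS_REJECTED = "rejected"
REASON_MERGED = "merged"
REASON_UNSUPPORTED = "unsupported"
REASON_CENSORED = "censored"


@dataclass(frozen=True)
class ScanLine:
    """A straight scan line with an odd pixel width.

    ``p0`` and ``p1`` are (x, y) endpoints in pixels; ``linewidth`` is the
    number of 1 px-spaced parallel samples taken across the line (odd only;
    11 is the recommended choice for most particles in plant cells).
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    linewidth: int = DEFAULT_LINEWIDTH

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise ParameterError("scan line endpoints must differ")
        if self.linewidth < 1 or self.linewidth % 2 == 0:
            raise ParameterError(
                f"linewidth must be an odd number >= 1, got {self.linewidth}"
            )

    @property
    def length(self) -> float:
        return math.hypot(
            self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]
        )

    @property
    def direction(self) -> tuple[float, float]:
        L = self.length
        return (
            (self.p1[0] - self.p0[0]) / L,
            (self.p1[1] - self.p0[1]) / L,
        )

    @property
    def normal(self) -> tuple[float, float]:
        ux, uy = self.direction
        return -uy, ux


@dataclass
class Kymograph:
    """T x L space-time matrix extracted along one scan line."""

    matrix: np.ndarray
    positions: np.ndarray  # (L, 2) sample points (x, y) along the line
    line: ScanLine
    reduction: str
    frame_interval_s: float

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class DwellSegment:
    """A contiguous time run of signal in a kymograph.

    ``dwell_s`` counts frames inclusively — ``(end - start + 1) * dt`` — and
    is defined only for uncensored segments; a segment touching the first or
    last frame is censored and never contributes a dwell value.
    """

    start_frame: int
    end_frame: int
    col_min: int
    col_max: int
    censored_left: bool
    censored_right: bool
    frame_interval_s: float
    status: str = STATUS_PENDING
    reason: str = ""
    support_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ParameterError("segment start must be <= end")

    @property
    def censored(self) -> bool:
        return self.censored_left or self.censored_right

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def dwell_s(self) -> float | None:
        if self.censored:
            return None
        return self.n_frames * self.frame_interval_s


def sample_line(line: ScanLine) -> np.ndarray:
    """Unit-spaced (x, y) sample points from p0 toward p1.

    Spacing is exactly 1 px along the line and ``L = floor(|p1 - p0|) + 1``
    points are produced, so the last point falls short of ``p1`` when the
    line length is not an integer (the endpoint rule).
    """
    L = int(math.floor(line.length)) + 1
    ux, uy = line.direction
    i = np.arange(L, dtype=float)
    return np.column_stack((line.p0[0] + i * ux, line.p0[1] + i * uy))


def _sample_grid(line: ScanLine) -> np.ndarray:
    """(L, linewidth, 2) coordinates: width samples perpendicular to the line."""
    pts = sample_line(line)
    nx, ny = line.normal
    offsets = np.arange(line.linewidth, dtype=float) - (line.linewidth - 1) / 2
    grid = np.empty((len(pts), line.linewidth, 2))
    grid[..., 0] = pts[:, None, 0] + offsets[None, :] * nx
    grid[..., 1] = pts[:, None, 1] + offsets[None, :] * ny
    return grid


def extract_kymograph(
    stack: ImageStack,
    line: ScanLine,
    reduction: str = "max",
) -> Kymograph:
    """Extract a T x L kymograph along ``line``.

    For every frame and every sample point along the line, the image is
    sampled (bilinear interpolation) at ``linewidth`` points spaced 1 px along
    the perpendicular, and reduced across the width by ``max`` (default) or
    ``mean``.  Axis-aligned integer lines reduce to exact pixel reads.
    """
    if reduction not in ("max", "mean"):
        raise ParameterError("reduction must be 'max' or 'mean'")
    grid = _sample_grid(line)
    h, w = stack.frame_shape
    xs = grid[..., 0]
    ys = grid[..., 1]
    eps = 1e-9
    if (
        xs.min() < -eps
        or ys.min() < -eps
        or xs.max() > w - 1 + eps
        or ys.max() > h - 1 + eps
    ):
        raise GeometryError(
            "scan line plus linewidth leaves the image bounds "
            f"(x range [{xs.min():.2f}, {xs.max():.2f}], "
            f"y range [{ys.min():.2f}, {ys.max():.2f}] vs {w}x{h})"
        )
    T = stack.n_frames
    L, lw = grid.shape[:2]
    # One 3D interpolation call: integer time coordinates select frames
    # exactly, bilinear interpolation acts only in-plane.
    yc = np.broadcast_to(np.clip(ys, 0, h - 1).ravel(), (T, L * lw))
    xc = np.broadcast_to(np.clip(xs, 0, w - 1).ravel(), (T, L * lw))
    tc = np.broadcast_to(np.arange(T, dtype=float)[:, None], (T, L * lw))
    volume = stack.pixels
    if not np.issubdtype(volume.dtype, np.floating):
        volume = volume.astype(np.float64)
    samples = ndimage.map_coordinates(
        volume,
        np.stack([tc.ravel(), yc.ravel(), xc.ravel()]),
        order=1,
        mode="nearest",
    ).reshape(T, L, lw)
    samples = samples.astype(np.float64, copy=False)
    reduce_fn = np.max if reduction == "max" else np.mean
    matrix = reduce_fn(samples, axis=2)
    return Kymograph(
        matrix=matrix,
        positions=sample_line(line),
        line=line,
        reduction=reduction,
        frame_interval_s=stack.frame_interval_s,
    )


def _clipped_background_threshold(
    values: np.ndarray, k: float, max_iter: int = 10
) -> float:
    """Background median + k robust SDs with iterative sigma clipping.

    Plain median/MAD statistics break once signal occupies a large share of
    the kymograph (a particle resident for the whole movie covers half the
    pixels); clipping values above median + k*MAD and re-estimating converges
    onto the background mode in a few iterations.
    """
    # Start from the lower half (background-dominated as long as signal
    # covers < 50% of pixels) and iterate the threshold to a fixed point;
    # for pure noise the iteration relaxes back up to ~median + k sigma.
    v = values[values <= np.median(values)]
    thr = math.inf
    for _ in range(max_iter):
        if v.size < 4:
            break
        mu, sd = float(np.median(v)), _robust_sd(v)
        new_thr = mu + k * sd
        if abs(new_thr - thr) <= 1e-6 * (1.0 + abs(new_thr)):
            thr = new_thr
            break
        thr = new_thr
        v = values[values <= thr]
    if not math.isfinite(thr):
        thr = float(np.median(values)) + k * _robust_sd(values)
    return thr


def _binarize(
    matrix: np.ndarray, threshold_method: str = "mad", threshold_k: float = 3.0
) -> np.ndarray:
    """Foreground mask of a kymograph (or any intensity image).

    ``mad``: sigma-clipped background median + k robust SDs.  ``otsu``:
    bimodal-histogram split.  A constant nonzero image has no meaningful
    threshold and raises.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.max() == m.min():
        if m.max() > 0:
            raise DegenerateThresholdError(
                "kymograph is constant/saturated; no threshold separates "
                "signal from background"
            )
        return np.zeros_like(m, dtype=bool)
    if threshold_method == "mad":
        thr = _clipped_background_threshold(m.ravel(), threshold_k)
    elif threshold_method == "otsu":
        thr = float(threshold_otsu(m))
    else:
        raise ParameterError("threshold_method must be 'mad' or 'otsu'")
    return m > thr


def detect_segments(
    kymo: Kymograph,
    threshold_method: str = "mad",
    threshold_k: float = 3.0,
    max_gap_frames: int = 1,
    min_area_px: int = 4,
) -> list[DwellSegment]:
    """Find contiguous signal runs (dwell segments) in a kymograph.

    The matrix is binarized, signal pixels are grouped into 8-connected
    spatiotemporal components, and components that overlap in space but are
    separated in time by at most ``max_gap_frames`` (single-frame blinking at
    the default of 1) are bridged into one segment.  Components smaller than
    ``min_area_px`` pixels are discarded before bridging: a real
    diffraction-limited visit covers at least a couple of columns (the PSF
    width) for at least a frame or two, whereas isolated threshold
    exceedances of the noise are 1-3 pixels.  Segments touching frame 0 or
    the last frame are flagged censored on that side.
    """
    if max_gap_frames < 0:
        raise ParameterError("max_gap_frames must be >= 0")
    mask = _binarize(kymo.matrix, threshold_method, threshold_k)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    boxes = []
    for label_i, (sl_t, sl_c) in enumerate(ndimage.find_objects(labels), 1):
        if areas[label_i - 1] < min_area_px:
            continue
        boxes.append(
            [sl_t.start, sl_t.stop - 1, sl_c.start, sl_c.stop - 1]
        )
    if not boxes:
        return []
    # Bridge gaps: union components whose column ranges intersect and whose
    # time separation is within max_gap_frames.
    parent = list(range(len(boxes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    changed = True
    while changed:
        changed = False
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                ri, rj = find(i), find(j)
                if ri == rj:
                    continue
                bi, bj = boxes[i], boxes[j]
                cols_overlap = bi[2] <= bj[3] and bj[2] <= bi[3]
                gap = max(bi[0], bj[0]) - min(bi[1], bj[1]) - 1
                if cols_overlap and gap <= max_gap_frames:
                    parent[rj] = ri
                    changed = True
    merged: dict[int, list[int]] = {}
    for i, box in enumerate(boxes):
        root = find(i)
        if root not in merged:
            merged[root] = list(box)
        else:
            mb = merged[root]
            mb[0] = min(mb[0], box[0])
            mb[1] = max(mb[1], box[1])
            mb[2] = min(mb[2], box[2])
            mb[3] = max(mb[3], box[3])

    T = kymo.n_frames
    segments = [
        DwellSegment(
            start_frame=t0,
            end_frame=t1,
            col_min=c0,
            col_max=c1,
            censored_left=t0 == 0,
            censored_right=t1 == T - 1,
            frame_interval_s=kymo.frame_interval_s,
        )
        for t0, t1, c0, c1 in merged.values()
    ]
    segments.sort(key=lambda s: (s.start_frame, s.col_min))
    return segments


def measure_dwell(
    seg: DwellSegment, frame_interval_s: float | None = None
) -> float | None:
    """Dwell time in seconds, or ``None`` for a censored segment.

    A particle visible in a single frame dwelt for at least one exposure, so
    frames are counted inclusively: ``(end - start + 1) * dt``.
    """
    if seg.censored:
        return None
    dt = seg.frame_interval_s if frame_interval_s is None else frame_interval_s
    return seg.n_frames * dt


def mean_dwell(segments: list[DwellSegment]) -> float | None:
    """Mean dwell over validated, uncensored segments; ``None`` if there are
    none (the overlength-dominated case where no dwell should be reported)."""
    values = [
        s.dwell_s
        for s in segments
        if s.status == STATUS_VALIDATED and s.dwell_s is not None
    ]
    if not values:
        return None
    return float(np.mean(values))


def _footprint_coords(
    kymo: Kymograph, seg: DwellSegment
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Line-frame geometry of a segment's footprint.

    Returns the line origin and unit direction plus the along-line interval
    [s0, s1] covered by the segment's columns.
    """
    line = kymo.line
    origin = np.asarray(line.p0, dtype=float)
    u = np.asarray(line.direction, dtype=float)
    return origin, u, float(seg.col_min), float(seg.col_max)


def _trajectory_cache(
    trajectories: list[Trajectory],
) -> dict[str, list]:
    """Precompute (frames, xy, bbox) per trajectory; the per-localization
    properties are O(n) on every access and dominate validation cost
    otherwise.  Entries are split by length so that segments needing >= 3
    supporting frames skip the (typically numerous) 1-2 frame detections
    without touching them."""
    all_entries = []
    for tr in trajectories:
        frames = tr.frames
        xy = tr.xy
        bbox = np.array(
            [xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max()]
        )
        all_entries.append((tr, frames, xy, bbox))
    return {
        "all": all_entries,
        "long": [e for e in all_entries if len(e[1]) >= 3],
    }


def validate_segment(
    seg: DwellSegment,
    kymo: Kymograph,
    trajectories: list[Trajectory],
    match_radius_px: float = 2.0,
    agree_frames: int = 2,
    min_support_frames: int = 3,
) -> DwellSegment:
    """Cross-validate a dwell segment against 2D+t trajectories.

    A trajectory supports the segment if at least ``min_support_frames`` of
    its localizations during ``[start_frame, end_frame]`` fall inside the
    segment's footprint: the stretch of scan line covered by the segment's
    columns, widened by half the linewidth across the line and by
    ``match_radius_px`` in both directions.  The minimum keeps one- or
    two-frame incursions — stray noise detections, or a particle briefly
    crossing the footprint without fusing into the streak — from anchoring or
    vetoing a segment.

    Outcome: censored -> rejected(censored); >= 2 supporting trajectories ->
    rejected(merged) (two particles fused into one line); none ->
    rejected(unsupported); exactly one whose start/end agree with the segment
    within ``agree_frames`` -> validated, else rejected(unsupported).
    """
    return _validate_cached(
        seg,
        kymo,
        _trajectory_cache(trajectories),
        match_radius_px,
        agree_frames,
        min_support_frames,
    )


def _validate_cached(
    seg: DwellSegment,
    kymo: Kymograph,
    cache: dict[str, list],
    match_radius_px: float,
    agree_frames: int,
    min_support_frames: int,
) -> DwellSegment:
    if seg.censored:
        return replace(
            seg, status=STATUS_REJECTED, reason=REASON_CENSORED
        )
    origin, u, s0, s1 = _footprint_coords(kymo, seg)
    half_width = (kymo.line.linewidth - 1) / 2.0
    # Conservative axis-aligned bbox of the footprint for a cheap prefilter.
    reach = half_width + match_radius_px
    corners_s = np.array([s0 - match_radius_px, s1 + match_radius_px])
    fx = origin[0] + corners_s * u[0]
    fy = origin[1] + corners_s * u[1]
    foot_x0, foot_x1 = fx.min() - reach, fx.max() + reach
    foot_y0, foot_y1 = fy.min() - reach, fy.max() + reach
    # Strict: a segment shorter than min_support_frames can never be
    # validated — nothing that brief is distinguishable from noise.
    needed = min_support_frames

    supporters: list[Trajectory] = []
    entries = cache["long"] if needed >= 3 else cache["all"]
    for tr, frames, xy, bbox in entries:
        if len(frames) < needed:
            continue
        if frames[-1] < seg.start_frame or frames[0] > seg.end_frame:
            continue
        if (
            bbox[1] < foot_x0
            or bbox[0] > foot_x1
            or bbox[3] < foot_y0
            or bbox[2] > foot_y1
        ):
            continue
        in_window = (frames >= seg.start_frame) & (frames <= seg.end_frame)
        if not in_window.any():
            continue
        pts = xy[in_window]
        rel = pts - origin
        along = rel @ u
        perp = rel[:, 0] * (-u[1]) + rel[:, 1] * u[0]
        inside = (
            (along >= s0 - match_radius_px)
            & (along <= s1 + match_radius_px)
            & (np.abs(perp) <= half_width + match_radius_px)
        )
        if int(inside.sum()) >= needed:
            supporters.append(tr)

    if len(supporters) == 0:
        return replace(seg, status=STATUS_REJECTED, reason=REASON_UNSUPPORTED)
    if len(supporters) >= 2:
        return replace(
            seg,
            status=STATUS_REJECTED,
            reason=REASON_MERGED,
            support_ids=tuple(t.id for t in supporters),
        )
    tr = supporters[0]
    if (
        abs(tr.start_frame - seg.start_frame) <= agree_frames
        and abs(tr.end_frame - seg.end_frame) <= agree_frames
    ):
        return replace(
            seg, status=STATUS_VALIDATED, reason="", support_ids=(tr.id,)
        )
    return replace(
        seg,
        status=STATUS_REJECTED,
        reason=REASON_UNSUPPORTED,
        support_ids=(tr.id,),
    )


def validate_segments(
    segments: list[DwellSegment],
    kymo: Kymograph,
    trajectories: list[Trajectory],
    match_radius_px: float = 2.0,
    agree_frames: int = 2,
    min_support_frames: int = 3,
    index: list | None = None,
) -> list[DwellSegment]:
    """Validate a batch of segments against one trajectory set.

    ``index`` may carry a prebuilt :func:`build_support_index` of the same
    trajectories, which amortises the per-trajectory array construction when
    many scan lines are validated against one tracking result.
    """
    cache = index if index is not None else _trajectory_cache(trajectories)
    return [
        _validate_cached(
            s, kymo, cache, match_radius_px, agree_frames, min_support_frames
        )
        for s in segments
    ]


#: Public name for precomputing the validation index once per tracking result.
build_support_index = _trajectory_cache


def render_views(
    kymo: Kymograph,
    out_prefix: str | os.PathLike,
    stack: ImageStack | None = None,
) -> list[str]:
    """Write the kymograph and (optionally) orthogonal projections to disk.

    Outputs: ``<prefix>_kymo.tif`` — the raw T x L matrix; ``<prefix>_kymo.png``
    — the kymograph with the time axis annotated in seconds; and, given the
    source stack, ``<prefix>_views.png`` — maximum-intensity projections of
    the 2D+t volume onto xy, xt and yt, the static counterpart of rotating
    the volume in a 3D viewer.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prefix = os.fspath(out_prefix)
    written: list[str] = []

    import tifffile

    tif_path = f"{prefix}_kymo.tif"
    tifffile.imwrite(
        tif_path, kymo.matrix.astype(np.float32), photometric="minisblack"
    )
    written.append(tif_path)

    duration = kymo.n_frames * kymo.frame_interval_s
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(
        kymo.matrix,
        aspect="auto",
        cmap="gray",
        extent=(0, kymo.n_positions, duration, 0),
    )
    ax.set_xlabel("position along line (px)")
    ax.set_ylabel("time (s)")
    png_path = f"{prefix}_kymo.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    written.append(png_path)

    if stack is not None:
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, (proj, title) in zip(
            axes,
            [
                (stack.pixels.max(axis=0), "xy (max over t)"),
                (stack.pixels.max(axis=1), "xt (max over y)"),
                (stack.pixels.max(axis=2), "yt (max over x)"),
            ],
        ):
            ax.imshow(proj, aspect="auto", cmap="gray")
            ax.set_title(title)
        views_path = f"{prefix}_views.png"
        fig.savefig(views_path, dpi=120)
        plt.close(fig)
        written.append(views_path)
    return written
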