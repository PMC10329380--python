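"""Per-frame spot detection and frame-to-frame linking into trajectories.

Diffraction-limited spots are called with a Laplacian-of-Gaussian band-pass at
the PSF scale, thresholded against a robust (MAD-based) noise estimate, and
refined to sub-pixel position by an intensity-weighted centroid.  Detections
are then linked into 2D+t trajectories by greedy nearest-neighbour assignment
with gap closing.

The trajectories are the automated ground for cross-validating kymograph
segments: where the original protocol rotates a 3D (2D+t) volume by hand to
check that one streak really is one particle, here each kymograph segment is
checked against the tracked trajectories (see :mod:`smkymo.kymograph`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .image_io import ImageStack

__all__ = [
    "Localization",
    "Trajectory",
    "detect_spots",
    "detect_stack",
    "link_trajectories",
    "track_stack",
    "default_max_disp_px",
    "trajectories_to_dataframe",
]


@dataclass
class Localization:
    """One sub-pixel spot detection in one frame.

    ``intensity`` is the background-subtracted peak amplitude in camera
    counts; ``snr`` is the band-pass response divided by the robust noise SD
    of the filtered frame.  ``edge`` flags spots whose centroid window was
    clipped by the image border (kept, but excluded from sub-pixel accuracy
    guarantees).
    """

    frame: int
    x: float
    y: float
    intensity: float
    snr: float
    edge: bool = False


@dataclass
class Trajectory:
    """A time-ordered sequence of localizations for one particle.

    Frames are strictly increasing; gaps of up to ``max_gap`` frames may have
    been bridged by the linker.
    """

    id: int
    localizations: list[Localization]
    frame_interval_s: float = 1.0

    @property
    def frames(self) -> np.ndarray:
        return np.array([l.frame for l in self.localizations], dtype=int)

    @property
    def xy(self) -> np.ndarray:
        return np.array([(l.x, l.y) for l in self.localizations], dtype=float)

    @property
    def start_frame(self) -> int:
        return self.localizations[0].frame

    @property
    def end_frame(self) -> int:
        return self.localizations[-1].frame

    @property
    def n_frames(self) -> int:
        """Spanned frames, inclusive of both endpoints."""
        return self.end_frame - self.start_frame + 1

    @property
    def duration_s(self) -> float:
        """Dwell-style duration: one exposure per spanned frame."""
        return self.n_frames * self.frame_interval_s

    def median_position(self) -> tuple[float, float]:
        xy = self.xy
        return float(np.median(xy[:, 0])), float(np.median(xy[:, 1]))

    def position_at(self, frame: int) -> tuple[float, float] | None:
        for l in self.localizations:
            if l.frame == frame:
                return l.x, l.y
        return None


def _robust_sd(values: np.ndarray) -> float:
    """1.4826 * median absolute deviation — robust to bright outliers."""
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def detect_spots(
    image: np.ndarray,
    psf_sigma_px: float,
    threshold_k: float = 3.0,
) -> list[Localization]:
    """Detect diffraction-limited spots in one frame.

    Pipeline: negated Laplacian-of-Gaussian at scale ``psf_sigma_px`` (bright
    blobs become positive peaks) -> local maxima -> keep maxima exceeding the
    filtered median by ``threshold_k`` robust noise SDs -> greedy suppression
    of maxima closer than ~2 sigma -> sub-pixel refinement by an
    intensity-weighted centroid in a ``(2*ceil(3*sigma)+1)^2`` window with the
    window median subtracted.

    A blank or constant frame yields an empty list, not an error.
    """
    if psf_sigma_px <= 0:
        raise ParameterError("psf_sigma_px must be > 0")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ParameterError("detect_spots expects a single 2D frame")
    resp = -ndimage.gaussian_laplace(img, sigma=psf_sigma_px)
    noise = _robust_sd(resp)
    med = float(np.median(resp))
    if noise == 0.0:
        # Noiseless frame: MAD collapses to 0 although real peaks may exist
        # (isolated spots on a constant background).  Fall back to a scale
        # tied to the response range; a truly constant frame stays empty.
        span = float(resp.max() - med)
        if span <= 0.0:
            return []
        noise = span * 1e-9
    threshold = med + threshold_k * noise

    is_max = resp == ndimage.maximum_filter(resp, size=3, mode="nearest")
    cand = np.argwhere(is_max & (resp > threshold))
    if len(cand) == 0:
        return []
    # Strongest-first suppression of near-duplicate maxima (plateaus, lobes).
    order = np.argsort(resp[cand[:, 0], cand[:, 1]])[::-1]
    cand = cand[order]
    min_sep = max(1.0, 2.0 * psf_sigma_px)
    kept: list[tuple[int, int]] = []
    for r, c in cand:
        if all(max(abs(r - kr), abs(c - kc)) >= min_sep for kr, kc in kept):
            kept.append((int(r), int(c)))

    h, w = img.shape
    radius = int(math.ceil(3 * psf_sigma_px))
    locs: list[Localization] = []
    for r, c in kept:
        r0, r1 = r - radius, r + radius + 1
        c0, c1 = c - radius, c + radius + 1
        edge = r0 < 0 or c0 < 0 or r1 > h or c1 > w
        r0, c0 = max(0, r0), max(0, c0)
        r1, c1 = min(h, r1), min(w, c1)
        window = img[r0:r1, c0:c1]
        local_bg = float(np.median(window))
        weights = np.clip(window - local_bg, 0.0, None)
        total = weights.sum()
        if total > 0:
            ys, xs = np.mgrid[r0:r1, c0:c1]
            x = float((weights * xs).sum() / total)
            y = float((weights * ys).sum() / total)
        else:
            x, y = float(c), float(r)
        locs.append(
            Localization(
                frame=0,
                x=x,
                y=y,
                intensity=float(img[r, c] - local_bg),
                snr=float((resp[r, c] - med) / noise),
                edge=edge,
            )
        )
    # Canonical within-frame order, so downstream linking is independent of
    # detection order.
    locs.sort(key=lambda l: (l.y, l.x))
    return locs


def detect_stack(
    stack: ImageStack,
    psf_sigma_px: float,
    threshold_k: float = 3.0,
    first_n_frames: int | None = None,
) -> list[Localization]:
    """Detect spots in every frame of a stack (optionally only the first n,
    mirroring the convention of tracking on the first 100 frames)."""
    n = stack.n_frames if first_n_frames is None else min(
        first_n_frames, stack.n_frames
    )
    out: list[Localization] = []
    for t in range(n):
        for loc in detect_spots(stack.frame(t), psf_sigma_px, threshold_k):
            loc.frame = t
            out.append(loc)
    return out


def default_max_disp_px(
    diffusion_coeff_um2_s: float,
    frame_interval_s: float,
    pixel_size_um: float,
) -> float:
    """3 sigma of the expected Brownian frame-to-frame displacement, with a
    3 px floor for near-immobile particles."""
    step = (
        math.sqrt(2.0 * diffusion_coeff_um2_s * frame_interval_s)
        / pixel_size_um
    )
    return max(3.0, 3.0 * step)


def link_trajectories(
    locs: list[Localization],
    max_disp_px: float,
    max_gap: int = 1,
    frame_interval_s: float = 1.0,
) -> list[Trajectory]:
    """Link per-frame localizations into trajectories.

    Greedy nearest-neighbour assignment: per frame, all (active track,
    new spot) pairs within ``max_disp_px * (gap + 1)`` are sorted globally by
    distance (ties broken by lower track id) and assigned first-come.
    Unassigned spots seed new tracks; a track may bridge up to ``max_gap``
    missing frames.  Each localization ends up in exactly one trajectory.
    """
    if max_disp_px <= 0:
        raise ParameterError("max_disp_px must be > 0")
    if max_gap < 0:
        raise ParameterError("max_gap must be >= 0")

    by_frame: dict[int, list[Localization]] = {}
    for loc in locs:
        by_frame.setdefault(loc.frame, []).append(loc)
    for frame_locs in by_frame.values():
        frame_locs.sort(key=lambda l: (l.y, l.x))

    trajectories: list[Trajectory] = []
    active: list[Trajectory] = []
    next_id = 0
    for frame in sorted(by_frame):
        frame_locs = by_frame[frame]
        # Retire tracks whose gap can no longer be closed.
        still = []
        for tr in active:
            if frame - tr.end_frame - 1 > max_gap:
                trajectories.append(tr)
            else:
                still.append(tr)
        active = still

        pairs: list[tuple[float, int, int]] = []
        for ti, tr in enumerate(active):
            gap = frame - tr.end_frame - 1
            last = tr.localizations[-1]
            limit = max_disp_px * (gap + 1)
            for li, loc in enumerate(frame_locs):
                d = math.hypot(loc.x - last.x, loc.y - last.y)
                if d <= limit:
                    pairs.append((d, ti, li))
        pairs.sort(key=lambda p: (p[0], active[p[1]].id))
        used_tracks: set[int] = set()
        used_locs: set[int] = set()
        for d, ti, li in pairs:
            if ti in used_tracks or li in used_locs:
                continue
            active[ti].localizations.append(frame_locs[li])
            used_tracks.add(ti)
            used_locs.add(li)
        for li, loc in enumerate(frame_locs):
            if li not in used_locs:
                active.append(
                    Trajectory(
                        id=next_id,
                        localizations=[loc],
                        frame_interval_s=frame_interval_s,
                    )
                )
                next_id += 1
    trajectories.extend(active)
    trajectories.sort(key=lambda tr: tr.id)
    return trajectories


def track_stack(
    stack: ImageStack,
    psf_sigma_px: float,
    threshold_k: float = 3.0,
    max_disp_px: float | None = None,
    max_gap: int = 1,
    first_n_frames: int | None = None,
) -> list[Trajectory]:
    """Detect and link in one call; ``max_disp_px`` defaults to the 3 px floor."""
    locs = detect_stack(stack, psf_sigma_px, threshold_k, first_n_frames)
    if max_disp_px is None:
        max_disp_px = 3.0
    return link_trajectories(
        locs,
        max_disp_px=max_disp_px,
        max_gap=max_gap,
        frame_interval_s=stack.frame_interval_s,
    )


def trajectories_to_dataframe(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format export: one row per localization."""
    rows = []
    for tr in trajectories:
        for loc in tr.localizations:
            rows.append(
                (
                    tr.id,
                    loc.frame,
                    loc.x,
                    loc.y,
                    loc.intensity,
                    loc.snr,
                    "edge" if loc.edge else "",
                )
            )
    return pd.DataFrame(
        rows,
        columns=["traj_id", "frame", "x_px", "y_px", "intensity", "snr", "flags"],
    )
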