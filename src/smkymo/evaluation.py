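"""Parameter-recovery experiments against simulated ground truth.

Each function sets up a simulated acquisition in a defined regime, runs the
full analysis chain (detect -> track -> kymograph -> validate, or register ->
colocalize), and scores the result against the simulator's ground truth.
They are the package's own benchmark harness: the tests assert on their
outputs, and the reproduction script reports them.

Problem sizes are chosen to exercise the default acquisition regime (200
frames at 150 ms) at particle densities where scan-line footprints rarely
collide, while keeping each experiment in the tens of seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_coloc import (
    apply_registration,
    colocalize_trajectories,
    estimate_registration,
)
from .detect_track import Trajectory, track_stack
from .kymograph import (
    ScanLine,
    build_support_index,
    detect_segments,
    extract_kymograph,
    mean_dwell,
    validate_segments,
)
from .pipeline import auto_scan_lines
from .simulate import (
    GroundTruth,
    SimParams,
    TwoChannelSimParams,
    render_movie,
    simulate_movie,
    simulate_two_channel,
)

__all__ = [
    "DwellRecovery",
    "CensoringResult",
    "dwell_recovery_experiment",
    "censoring_experiment",
    "merged_rejection_rate",
    "registration_recovery",
    "coloc_recovery",
    "two_particle_fixture",
]


def _match_trajectory_to_particle(
    tr: Trajectory, truth: GroundTruth, radius_px: float = 3.0
) -> int | None:
    """Ground-truth particle most often within ``radius_px`` of the
    trajectory's median position during its lifetime (evaluation only)."""
    x, y = tr.median_position()
    pos = truth.positions
    cands = pos[(pos.frame >= tr.start_frame) & (pos.frame <= tr.end_frame)]
    d = np.hypot(cands.x_px - x, cands.y_px - y)
    near = cands[d < radius_px]
    if near.empty:
        return None
    return int(near.groupby("particle_id").size().idxmax())


@dataclass
class DwellRecovery:
    """Dwell-time recovery scores on one simulated movie."""

    n_validated: int
    n_matched: int
    mean_estimated_s: float
    mean_true_s: float
    relative_error: float
    frac_within_2_frames: float


def dwell_recovery_experiment(
    seed: int = 11,
    n_frames: int = 200,
    frame_interval_s: float = 0.15,
    fov: tuple[int, int] = (256, 256),
    arrival_rate: float = 1.5,
    dwell_mean_s: float = 3.0,
    psf_sigma_px: float = 1.3,
    linewidth: int = 11,
) -> DwellRecovery:
    """Recover exponential membrane dwells from kymograph segments.

    Simulates ~``arrival_rate * n_frames`` particles (the default is ~300
    over a 30 s movie), places one scan line per tracked trajectory, detects
    and validates dwell segments, matches each validated segment's supporting
    trajectory back to its ground-truth particle, and compares the validated
    uncensored dwell estimates with the matched particles' true dwells.
    """
    params = SimParams(
        n_frames=n_frames,
        frame_interval_s=frame_interval_s,
        fov=fov,
        arrival_rate=arrival_rate,
        dwell_law=("exponential", dwell_mean_s),
        psf_sigma_px=psf_sigma_px,
        seed=seed,
    )
    stack, truth = simulate_movie(params)
    trajs = track_stack(stack, psf_sigma_px=psf_sigma_px)
    lines = auto_scan_lines(trajs, stack.frame_shape, psf_sigma_px, linewidth)
    index = build_support_index(trajs)
    tr_by_id = {t.id: t for t in trajs}

    validated: list[tuple[int, object]] = []
    for tid, line in lines:
        kymo = extract_kymograph(stack, line)
        segments = validate_segments(
            detect_segments(kymo), kymo, trajs, index=index
        )
        for seg in segments:
            if seg.status == "validated" and tid in seg.support_ids:
                validated.append((tid, seg))

    particles = truth.particles.set_index("id")
    errors_frames: list[int] = []
    est: list[float] = []
    true: list[float] = []
    for tid, seg in validated:
        pid = _match_trajectory_to_particle(tr_by_id[tid], truth)
        if pid is None:
            continue
        row = particles.loc[pid]
        if row.left_censored or row.right_censored:
            continue
        errors_frames.append(abs(seg.n_frames - int(row.n_frames_alive)))
        est.append(seg.dwell_s)
        true.append(float(row.true_dwell_s))

    est_arr = np.asarray(est)
    true_arr = np.asarray(true)
    err_arr = np.asarray(errors_frames)
    return DwellRecovery(
        n_validated=len(validated),
        n_matched=len(est),
        mean_estimated_s=float(est_arr.mean()),
        mean_true_s=float(true_arr.mean()),
        relative_error=float(
            abs(est_arr.mean() - true_arr.mean()) / true_arr.mean()
        ),
        frac_within_2_frames=float((err_arr <= 2).mean()),
    )


@dataclass
class CensoringResult:
    """Censoring behavior on a stable (long-dwell) population."""

    n_segments: int
    n_censored: int
    n_validated: int
    censored_fraction: float
    mean_dwell_s: float | None


def censoring_experiment(
    seed: int = 5,
    dwell_mean_s: float = 60.0,
    n_initial: int = 20,
    arrival_rate: float = 0.01,
    fov: tuple[int, int] = (64, 64),
) -> CensoringResult:
    """Overlength-trace behavior for a near-immobile resident population.

    Emulates a stable raft-marker protein: a pre-existing population at frame
    0 plus rare new arrivals, with a mean dwell (60 s) far exceeding the 30 s
    movie.  Nearly every particle-supported kymograph trace touches the first
    or last frame, so it must be flagged censored, and no mean dwell should
    be reported.  The censored fraction is computed over particle-supported
    traces (censored + validated); noise blips and grazing fragments rejected
    as unsupported carry no dwell information either way.
    """
    params = SimParams(
        fov=fov,
        arrival_rate=arrival_rate,
        n_initial=n_initial,
        dwell_law=("exponential", dwell_mean_s),
        seed=seed,
    )
    stack, _ = simulate_movie(params)
    trajs = track_stack(stack, psf_sigma_px=params.psf_sigma_px)
    lines = auto_scan_lines(trajs, stack.frame_shape, params.psf_sigma_px)
    index = build_support_index(trajs)
    segments = []
    for _, line in lines:
        kymo = extract_kymograph(stack, line)
        segments += validate_segments(
            detect_segments(kymo), kymo, trajs, index=index
        )
    n_censored = sum(1 for s in segments if s.reason == "censored")
    n_validated = sum(1 for s in segments if s.status == "validated")
    supported = n_censored + n_validated
    return CensoringResult(
        n_segments=len(segments),
        n_censored=n_censored,
        n_validated=n_validated,
        censored_fraction=n_censored / supported if supported else float("nan"),
        mean_dwell_s=mean_dwell(segments),
    )


def two_particle_fixture(
    frame_interval_s: float = 0.15, n_frames: int = 200
) -> GroundTruth:
    """Two immobile particles occupying the same scan-line position in
    succession (perpendicular offsets inside the linewidth), whose kymograph
    runs fuse into a single long line — the merged-trace artifact."""
    rows = []
    pos = []
    for pid, (y, b0, d0) in enumerate([(22.0, 20, 100), (26.0, 101, 180)]):
        rows.append(
            dict(
                id=pid,
                channel="A",
                birth_frame=b0,
                death_frame=d0,
                n_frames_alive=d0 - b0 + 1,
                true_dwell_s=(d0 - b0 + 1) * frame_interval_s,
                death_cause="departure",
                left_censored=False,
                right_censored=False,
                coloc_partner_id=pd.NA,
            )
        )
        for f in range(b0, d0 + 1):
            pos.append((pid, f, 24.0, y))
    particles = pd.DataFrame(rows)
    particles["coloc_partner_id"] = particles["coloc_partner_id"].astype("Int64")
    return GroundTruth(
        particles=particles,
        positions=pd.DataFrame(
            pos, columns=["particle_id", "frame", "x_px", "y_px"]
        ),
        frame_interval_s=frame_interval_s,
    )


def merged_rejection_rate(
    n_replicates: int = 50, seed: int = 0, linewidth: int = 11
) -> float:
    """Fraction of noise replicates in which the fused two-particle line is
    rejected as merged by trajectory cross-validation."""
    truth = two_particle_fixture()
    params = SimParams(
        n_frames=200, fov=(48, 48), arrival_rate=0.0,
        diffusion_coeff_um2_s=0.0, seed=seed,
    )
    line = ScanLine((19.0, 24.0), (29.0, 24.0), linewidth=linewidth)
    hits = 0
    for r in range(n_replicates):
        stack = render_movie(truth, params, rng=seed + r)
        trajs = track_stack(stack, psf_sigma_px=params.psf_sigma_px)
        kymo = extract_kymograph(stack, line)
        segments = validate_segments(detect_segments(kymo), kymo, trajs)
        if any(s.reason == "merged" for s in segments):
            hits += 1
    return hits / n_replicates


def registration_recovery(
    shifts: list[tuple[float, float]] | None = None,
    seed: int = 0,
    upsample: int = 50,
) -> float:
    """Worst-case shift-recovery error (px) over known channel offsets.

    A simulated single-molecule frame is translated by known sub-pixel
    amounts via the Fourier shift theorem (periodic, exact) and the offset is
    re-estimated by phase correlation.
    """
    if shifts is None:
        shifts = [(1.0, 0.0), (3.0, -2.0), (0.5, -1.25), (4.6, 3.3), (-5.0, 2.5)]
    params = SimParams(n_frames=1, fov=(128, 128), arrival_rate=25.0, seed=seed)
    stack, _ = simulate_movie(params)
    a = stack.frame(0).astype(np.float64)
    worst = 0.0
    for dx, dy in shifts:
        fa = np.fft.fft2(a)
        h, w = a.shape
        ky = np.fft.fftfreq(h)[:, None]
        kx = np.fft.fftfreq(w)[None, :]
        b = np.real(np.fft.ifft2(fa * np.exp(-2j * np.pi * (ky * dy + kx * dx))))
        t = estimate_registration(a, np.clip(b, 0, None), upsample=upsample)
        worst = max(worst, abs(t.dx - dx), abs(t.dy - dy))
    return worst


def coloc_recovery(
    fractions: tuple[float, ...] = (0.0, 0.3, 0.6, 1.0),
    seed: int = 1,
    channel_shift_px: tuple[float, float] = (1.6, -2.3),
    dist_thresh_px: float = 2.0,
    min_frames: int = 3,
) -> pd.DataFrame:
    """Recover the colocalized fraction across known ground-truth fractions.

    The channel offset is first calibrated on a fully colocalized acquisition
    (the in-silico analogue of a bead/calibration recording) and that single
    transform is applied to every condition.  A-trajectories shorter than
    ``min_frames + 2`` frames are excluded from the denominator: with a
    3-frame overlap requirement, a single detection dropout in the other
    channel would misclassify them, so the colocalized state of such brief
    tracks is not assessable.  Returns a frame with columns
    ``fraction`` (nominal), ``true_fraction`` (realised), ``estimated``.
    """

    def _simulate(frac: float, s: int):
        base = dict(
            n_frames=200, fov=(128, 128), dwell_law=("exponential", 3.0)
        )
        tc = TwoChannelSimParams(
            params_a=SimParams(**base, arrival_rate=1.0, seed=s),
            params_b=SimParams(**base, arrival_rate=0.5, seed=s),
            coloc_fraction=frac,
            channel_shift_px=channel_shift_px,
        )
        return simulate_two_channel(tc)

    cal_a, cal_b, _ = _simulate(1.0, seed + 90)
    reg = estimate_registration(
        cal_a.pixels.mean(axis=0), cal_b.pixels.mean(axis=0), upsample=20
    )

    min_len_a = min_frames + 2
    rows = []
    for i, frac in enumerate(fractions):
        sa, sb, truth = _simulate(frac, seed + i)
        rb, _ = apply_registration(sb, reg)
        ta = [
            t
            for t in track_stack(sa, 1.3)
            if len(t.localizations) >= min_len_a
        ]
        tb = [
            t for t in track_stack(rb, 1.3) if len(t.localizations) >= 3
        ]
        res = colocalize_trajectories(
            ta, tb, dist_thresh_px=dist_thresh_px, min_frames=min_frames
        )
        a_particles = truth.particles[truth.particles.channel == "A"]
        rows.append(
            (
                frac,
                float(a_particles.coloc_partner_id.notna().mean()),
                res.summary,
            )
        )
    return pd.DataFrame(rows, columns=["fraction", "true_fraction", "estimated"])
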