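"""Config-driven orchestration: simulate/load -> track -> kymograph -> stats.

A single YAML/JSON-style config drives the whole analysis so that every
number in the output tables is regenerable from the run manifest alone
(config + package version + seed).  Stages run in order — input stacks,
detection/tracking, scan lines, kymograph dwell analysis, SCI, two-channel
colocalization — and a failure aborts with the stage name and cause.

Group statistics mirror the field's convention of comparing mean dwell times
between treatments with a two-sample t-test; Welch's flavor is the default,
the classic equal-variance Student's flavor is available via ``flavor``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .cluster_coloc import (
    ColocResult,
    apply_registration,
    colocalize_trajectories,
    compute_sci,
    estimate_registration,
)
from .detect_track import Trajectory, track_stack
from .errors import ParameterError, StageError
from .image_io import ImageStack, read_stack, write_stack
from .kymograph import (
    ScanLine,
    build_support_index,
    detect_segments,
    extract_kymograph,
    mean_dwell,
    validate_segments,
)
from .simulate import SimParams, TwoChannelSimParams, simulate_movie, simulate_two_channel

__all__ = [
    "RunResult",
    "GroupComparison",
    "load_config",
    "run_pipeline",
    "compare_groups",
    "auto_scan_lines",
]


@dataclass
class GroupComparison:
    """Two-sample comparison of dwell-time groups."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    p: float
    flavor: str


def compare_groups(
    dwells_a: list[float],
    dwells_b: list[float],
    flavor: str = "welch",
    label_a: str = "A",
    label_b: str = "B",
) -> GroupComparison:
    """Two-sample t-test on uncensored dwell times (seconds).

    ``flavor='welch'`` (default) does not assume equal variances;
    ``flavor='student'`` is the classic equal-variance test.  Censored values
    (``None``/NaN) are rejected — filter them out first; censored dwells carry
    no duration and must not enter a mean.
    """
    if flavor not in ("welch", "student"):
        raise ParameterError("flavor must be 'welch' or 'student'")
    for name, values in (("A", dwells_a), ("B", dwells_b)):
        if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values):
            raise ParameterError(
                f"group {name} contains censored values; filter censored "
                "dwells before comparing groups"
            )
        if len(values) < 2:
            raise ParameterError(f"group {name} needs >= 2 uncensored values")
    a = np.asarray(dwells_a, dtype=float)
    b = np.asarray(dwells_b, dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=(flavor == "student"))
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t=float(t),
        p=float(p),
        flavor=flavor,
    )


@dataclass
class RunResult:
    """Outputs of one pipeline run."""

    output_dir: Path
    dwell_table: pd.DataFrame
    sci_table: pd.DataFrame
    coloc: ColocResult | None
    mean_dwell_s: float | None
    manifest_path: Path
    counts: dict


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sim_params(d: dict) -> SimParams:
    d = dict(d)
    if "fov" in d:
        d["fov"] = tuple(d["fov"])
    if "dwell_law" in d:
        d["dwell_law"] = tuple(d["dwell_law"])
    return SimParams(**d)


def auto_scan_lines(
    trajectories: list[Trajectory],
    frame_shape: tuple[int, int],
    psf_sigma_px: float,
    linewidth: int = 11,
    min_traj_frames: int = 3,
) -> list[tuple[int, ScanLine]]:
    """One horizontal scan line per trajectory, at its time-median position.

    Line half-length is ``ceil(3 * sigma)`` px (so length 2*ceil(3σ)+1 samples)
    and the center is clamped so that line plus width stays inside the frame;
    trajectories too close to the border for any placement, or shorter than
    ``min_traj_frames`` (likely stray detections), are skipped.
    Deterministic: line order follows trajectory id.
    """
    h, w = frame_shape
    half_len = int(math.ceil(3 * psf_sigma_px))
    half_width = (linewidth - 1) / 2
    lines = []
    for tr in sorted(trajectories, key=lambda t: t.id):
        if len(tr.localizations) < min_traj_frames:
            continue
        x, y = tr.median_position()
        x = float(np.clip(x, half_len, w - 1 - half_len))
        y = float(np.clip(y, half_width, h - 1 - half_width))
        if (
            x - half_len < 0
            or x + half_len > w - 1
            or y - half_width < 0
            or y + half_width > h - 1
        ):
            continue
        lines.append(
            (
                tr.id,
                ScanLine(
                    p0=(x - half_len, y), p1=(x + half_len, y), linewidth=linewidth
                ),
            )
        )
    return lines


def read_scan_lines(path: str | Path) -> list[tuple[int, ScanLine]]:
    """Read scan lines from a CSV with columns x0, y0, x1, y1, linewidth."""
    df = pd.read_csv(path)
    lines = []
    for i, row in df.iterrows():
        lines.append(
            (
                int(i),
                ScanLine(
                    p0=(float(row["x0"]), float(row["y0"])),
                    p1=(float(row["x1"]), float(row["y1"])),
                    linewidth=int(row.get("linewidth", 11)),
                ),
            )
        )
    return lines


def _stage(name: str):
    """Decorator-free stage guard: wrap a callable, rebrand failures."""

    class _Guard:
        def __init__(self, stage_name: str):
            self.stage_name = stage_name

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(self.stage_name, exc) from exc
            return False

    return _Guard(name)


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> RunResult:
    """Run the full analysis described by ``config``; see module docstring.

    Deterministic given the config's seed: running the same config twice
    yields byte-identical CSV outputs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(output_dir or config.get("output_dir", "smkymo_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    counts: dict = {}

    det_cfg = dict(config.get("detect", {}))
    psf_sigma = float(det_cfg.get("psf_sigma_px", 1.3))
    threshold_k = float(det_cfg.get("threshold_k", 3.0))
    max_disp = det_cfg.get("max_disp_px")
    max_gap = int(det_cfg.get("max_gap", 1))
    first_n = det_cfg.get("first_n_frames")

    kymo_cfg = dict(config.get("kymograph", {}))
    reduction = kymo_cfg.get("reduction", "max")
    kymo_k = float(kymo_cfg.get("threshold_k", 3.0))
    seg_gap = int(kymo_cfg.get("max_gap_frames", 1))
    match_radius = float(kymo_cfg.get("match_radius_px", 2.0))
    linewidth = int(config.get("scan_lines", {}).get("linewidth", 11))

    # ---- stage: input -----------------------------------------------------
    truth = None
    stack_b = None
    with _stage("input"):
        if "simulation" in config:
            sim = config["simulation"]
            if sim.get("mode", "single") == "two_channel":
                params = TwoChannelSimParams(
                    params_a=_sim_params({**sim.get("params", {}), "seed": seed}),
                    params_b=_sim_params(
                        {**sim.get("params_b", sim.get("params", {})), "seed": seed}
                    ),
                    coloc_fraction=float(sim.get("coloc_fraction", 0.0)),
                    channel_shift_px=tuple(sim.get("channel_shift_px", (0.0, 0.0))),
                )
                stack_a, stack_b, truth = simulate_two_channel(params)
            else:
                params = _sim_params({**sim.get("params", {}), "seed": seed})
                stack_a, truth = simulate_movie(params)
            psf_sigma = float(sim.get("params", {}).get("psf_sigma_px", psf_sigma))
            truth.to_csv(
                str(out / "ground_truth_particles.csv"),
                str(out / "ground_truth_positions.csv"),
            )
            write_stack(stack_a, str(out / "channel_a.tif"))
            if stack_b is not None:
                write_stack(stack_b, str(out / "channel_b.tif"))
        elif "inputs" in config:
            inp = config["inputs"]
            ca = inp["channel_a"]
            stack_a = read_stack(
                ca["path"],
                float(ca["frame_interval_s"]),
                float(ca["pixel_size_um"]),
                ca.get("label", "A"),
            )
            if "channel_b" in inp:
                cb = inp["channel_b"]
                stack_b = read_stack(
                    cb["path"],
                    float(cb["frame_interval_s"]),
                    float(cb["pixel_size_um"]),
                    cb.get("label", "B"),
                )
        else:
            raise ParameterError("config needs a 'simulation' or 'inputs' section")

    # ---- stage: track -----------------------------------------------------
    with _stage("track"):
        trajs_a = track_stack(
            stack_a,
            psf_sigma_px=psf_sigma,
            threshold_k=threshold_k,
            max_disp_px=max_disp,
            max_gap=max_gap,
            first_n_frames=first_n,
        )
        counts["trajectories_a"] = len(trajs_a)

    # ---- stage: scan_lines ------------------------------------------------
    with _stage("scan_lines"):
        sl_cfg = config.get("scan_lines", {})
        if sl_cfg.get("mode", "auto") == "file":
            lines = read_scan_lines(sl_cfg["path"])
        else:
            lines = auto_scan_lines(
                trajs_a, stack_a.frame_shape, psf_sigma, linewidth=linewidth
            )
        counts["scan_lines"] = len(lines)

    # ---- stage: kymograph -------------------------------------------------
    with _stage("kymograph"):
        rows = []
        rejected_by_reason: dict[str, int] = {}
        support_index = build_support_index(trajs_a)
        for line_id, line in lines:
            kymo = extract_kymograph(stack_a, line, reduction=reduction)
            segments = detect_segments(
                kymo, threshold_k=kymo_k, max_gap_frames=seg_gap
            )
            segments = validate_segments(
                segments,
                kymo,
                trajs_a,
                match_radius_px=match_radius,
                index=support_index,
            )
            for seg in segments:
                if seg.status == "rejected":
                    rejected_by_reason[seg.reason] = (
                        rejected_by_reason.get(seg.reason, 0) + 1
                    )
                rows.append(
                    (
                        stack_a.channel_label or "A",
                        line_id,
                        seg.start_frame,
                        seg.end_frame,
                        seg.censored_left,
                        seg.censored_right,
                        seg.dwell_s if seg.dwell_s is not None else np.nan,
                        seg.status,
                        seg.reason,
                    )
                )
        dwell_table = pd.DataFrame(
            rows,
            columns=[
                "stack",
                "line_id",
                "start_frame",
                "end_frame",
                "censored_l",
                "censored_r",
                "dwell_s",
                "status",
                "reason",
            ],
        )
        dwell_table.to_csv(out / "dwell.csv", index=False)
        validated = dwell_table[dwell_table["status"] == "validated"]
        mean_dwell_s = (
            float(validated["dwell_s"].mean()) if len(validated) else None
        )
        counts["segments_total"] = len(dwell_table)
        counts["segments_validated"] = int(len(validated))
        counts["segments_rejected"] = rejected_by_reason

    # ---- stage: sci -------------------------------------------------------
    with _stage("sci"):
        sci_rows = []
        for label, stk in (("A", stack_a), ("B", stack_b)):
            if stk is None:
                continue
            res = compute_sci(stk)
            sci_rows.append(
                (label, res.value, res.sd if res.sd is not None else np.nan,
                 res.percentile, res.n_top, res.n_roi_pixels)
            )
        sci_table = pd.DataFrame(
            sci_rows,
            columns=["channel", "sci_mean", "sci_sd", "percentile", "n_set", "n_pixels"],
        )
        sci_table.to_csv(out / "sci.csv", index=False)

    # ---- stage: coloc -----------------------------------------------------
    coloc = None
    if stack_b is not None:
        with _stage("coloc"):
            cl_cfg = dict(config.get("coloc", {}))
            reg = estimate_registration(
                stack_a.pixels.mean(axis=0),
                stack_b.pixels.mean(axis=0),
                upsample=int(cl_cfg.get("upsample", 20)),
            )
            registered_b, _ = apply_registration(stack_b, reg)
            trajs_b = track_stack(
                registered_b,
                psf_sigma_px=psf_sigma,
                threshold_k=threshold_k,
                max_disp_px=max_disp,
                max_gap=max_gap,
                first_n_frames=first_n,
            )
            counts["trajectories_b"] = len(trajs_b)
            coloc = colocalize_trajectories(
                trajs_a,
                trajs_b,
                dist_thresh_px=float(cl_cfg.get("dist_thresh_px", 2.0)),
                min_frames=int(cl_cfg.get("min_frames", 3)),
                seed=seed,
            )
            coloc.per_trajectory.to_csv(out / "coloc.csv", index=False)
            counts["registration"] = {
                "dx": reg.dx,
                "dy": reg.dy,
                "score": reg.score,
                "low_confidence": reg.low_confidence,
            }
            counts["coloc_fraction"] = coloc.summary

    # ---- stage: manifest --------------------------------------------------
    with _stage("manifest"):
        manifest = {
            "config": config,
            "version": __version__,
            "seed": seed,
            "counts": counts,
            "mean_dwell_s": mean_dwell_s,
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    return RunResult(
        output_dir=out,
        dwell_table=dwell_table,
        sci_table=sci_table,
        coloc=coloc,
        mean_dwell_s=mean_dwell_s,
        manifest_path=manifest_path,
        counts=counts,
    )
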