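"""Kymograph geometry, segment detection, censoring, and validation."""

import math

import numpy as np
import pytest

from smkymo import (
    DwellSegment,
    ImageStack,
    Kymograph,
    ScanLine,
    SimParams,
    Trajectory,
    detect_segments,
    extract_kymograph,
    measure_dwell,
    render_views,
    sample_line,
    simulate_movie,
    validate_segment,
)
from smkymo.detect_track import Localization
from smkymo.errors import (
    DegenerateThresholdError,
    GeometryError,
    ParameterError,
)


# ---------------------------------------------------------------------------
# Independent brute-force oracle for kymograph extraction
# ---------------------------------------------------------------------------


def bilinear(img, x, y):
    h, w = img.shape
    x0 = min(int(math.floor(x)), w - 2)
    y0 = min(int(math.floor(y)), h - 2)
    x0, y0 = max(x0, 0), max(y0, 0)
    fx, fy = x - x0, y - y0
    return (
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x0 + 1] * fx * (1 - fy)
        + img[y0 + 1, x0] * (1 - fx) * fy
        + img[y0 + 1, x0 + 1] * fx * fy
    )


def kymo_oracle(stack, line, reduction):
    """Nested-loop reference: unit-spaced points, perpendicular width
    samples, explicit bilinear reads."""
    length = math.hypot(
        line.p1[0] - line.p0[0], line.p1[1] - line.p0[1]
    )
    L = int(math.floor(length)) + 1
    ux, uy = (
        (line.p1[0] - line.p0[0]) / length,
        (line.p1[1] - line.p0[1]) / length,
    )
    nx, ny = -uy, ux
    half = (line.linewidth - 1) / 2
    out = np.empty((stack.n_frames, L))
    for t in range(stack.n_frames):
        img = stack.pixels[t].astype(np.float64)
        for j in range(L):
            cx = line.p0[0] + j * ux
            cy = line.p0[1] + j * uy
            vals = []
            for o in range(line.linewidth):
                off = o - half
                vals.append(bilinear(img, cx + off * nx, cy + off * ny))
            out[t, j] = max(vals) if reduction == "max" else np.mean(vals)
    return out


class TestSampleLine:
    def test_axis_aligned_integer_line(self):
        pts = sample_line(ScanLine((0, 0), (4, 0), 1))
        np.testing.assert_allclose(pts[:, 0], [0, 1, 2, 3, 4])
        np.testing.assert_allclose(pts[:, 1], 0)

    def test_pythagorean_diagonal_unit_spacing(self):
        pts = sample_line(ScanLine((0, 0), (3, 4), 1))
        assert len(pts) == 6
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        np.testing.assert_allclose(steps, 1.0)

    def test_fractional_length_endpoint_rule(self):
        pts = sample_line(ScanLine((0, 0), (2.5, 0), 1))
        np.testing.assert_allclose(pts[:, 0], [0, 1, 2])

    def test_degenerate_line_rejected(self):
        with pytest.raises(ParameterError):
            ScanLine((3, 3), (3, 3), 1)


class TestExtract:
    def make_stack(self, pixels):
        return ImageStack(pixels, frame_interval_s=0.15, pixel_size_um=0.1)

    def test_constant_frames_map_to_constant_rows(self):
        pixels = np.stack([np.full((16, 16), float(t)) for t in range(6)])
        stack = self.make_stack(pixels)
        kymo = extract_kymograph(
            stack, ScanLine((3, 8), (12, 8), 1), reduction="max"
        )
        for t in range(6):
            np.testing.assert_allclose(kymo.matrix[t], t)

    @pytest.mark.parametrize("linewidth", [1, 3, 11])
    @pytest.mark.parametrize("reduction", ["max", "mean"])
    def test_matches_brute_force_oracle(self, rng, linewidth, reduction):
        pixels = rng.random((5, 32, 32))
        stack = self.make_stack(pixels)
        line = ScanLine((8.3, 7.2), (24.6, 21.9), linewidth)
        kymo = extract_kymograph(stack, line, reduction=reduction)
        expected = kymo_oracle(stack, line, reduction)
        np.testing.assert_allclose(kymo.matrix, expected, atol=1e-9)

    def test_linewidth_one_integer_line_reads_exact_pixels(self, rng):
        pixels = rng.integers(0, 1000, (4, 16, 16)).astype(np.uint16)
        stack = self.make_stack(pixels)
        kymo = extract_kymograph(stack, ScanLine((2, 5), (12, 5), 1))
        np.testing.assert_array_equal(kymo.matrix, pixels[:, 5, 2:13])

    def test_even_linewidth_rejected(self):
        with pytest.raises(ParameterError, match="odd"):
            ScanLine((0, 0), (5, 0), 4)

    def test_line_outside_bounds_rejected(self, rng):
        stack = self.make_stack(rng.random((2, 16, 16)))
        with pytest.raises(GeometryError):
            extract_kymograph(stack, ScanLine((2, 2), (20, 2), 1))
        # Width pushes the footprint over the border even if the line fits.
        with pytest.raises(GeometryError):
            extract_kymograph(stack, ScanLine((2, 1), (12, 1), 11))


def binary_kymo(signal_rows, n_frames=200, n_cols=5, col_range=(0, 5)):
    m = np.zeros((n_frames, n_cols))
    for r in signal_rows:
        m[r, col_range[0]:col_range[1]] = 1.0
    return Kymograph(
        matrix=m,
        positions=np.column_stack(
            [np.arange(n_cols, dtype=float), np.zeros(n_cols)]
        ),
        line=ScanLine((0.0, 0.0), (float(n_cols - 1), 0.0), 1),
        reduction="max",
        frame_interval_s=0.15,
    )


class TestDetectSegments:
    def test_all_zero_kymograph_has_no_segments(self):
        assert detect_segments(binary_kymo([])) == []

    def test_run_length_grouping_and_gap_bridging(self):
        kymo = binary_kymo(list(range(5, 10)) + list(range(12, 21)))
        segs = detect_segments(kymo, max_gap_frames=0)
        assert [(s.start_frame, s.end_frame) for s in segs] == [(5, 9), (12, 20)]
        merged = detect_segments(kymo, max_gap_frames=2)
        assert [(s.start_frame, s.end_frame) for s in merged] == [(5, 20)]

    def test_full_length_run_censored_both_ends(self):
        segs = detect_segments(binary_kymo(range(200), col_range=(2, 3)))
        assert len(segs) == 1
        assert segs[0].censored_left and segs[0].censored_right
        assert segs[0].dwell_s is None

    def test_run_touching_start_censored_left_only(self):
        segs = detect_segments(binary_kymo(range(0, 50)))
        assert segs[0].censored_left and not segs[0].censored_right

    def test_tiny_components_filtered_as_noise(self):
        kymo = binary_kymo([7], col_range=(2, 3))  # single pixel
        assert detect_segments(kymo) == []
        assert len(detect_segments(kymo, min_area_px=1)) == 1

    def test_saturated_kymograph_rejected(self):
        kymo = binary_kymo([])
        kymo.matrix[:] = 4095.0
        with pytest.raises(DegenerateThresholdError):
            detect_segments(kymo)


class TestMeasureDwell:
    def make(self, start, end, cl=False, cr=False, dt=0.15):
        return DwellSegment(
            start_frame=start,
            end_frame=end,
            col_min=0,
            col_max=4,
            censored_left=cl,
            censored_right=cr,
            frame_interval_s=dt,
        )

    def test_inclusive_frame_count(self):
        assert measure_dwell(self.make(10, 29)) == pytest.approx(3.0)

    def test_single_frame_counts_one_exposure(self):
        assert measure_dwell(self.make(42, 42, dt=0.1)) == pytest.approx(0.1)

    def test_censored_segment_has_no_value(self):
        assert measure_dwell(self.make(0, 199, cl=True, cr=True)) is None
        assert measure_dwell(self.make(150, 199, cr=True)) is None


def traj(tid, frames, x, y):
    return Trajectory(
        id=tid,
        localizations=[
            Localization(frame=f, x=x, y=y, intensity=10, snr=10)
            for f in frames
        ],
        frame_interval_s=0.15,
    )


class TestValidate:
    def setup_method(self):
        self.kymo = binary_kymo(range(10, 31), n_cols=11)
        self.kymo = Kymograph(
            matrix=self.kymo.matrix,
            positions=self.kymo.positions,
            line=ScanLine((5.0, 10.0), (15.0, 10.0), 3),
            reduction="max",
            frame_interval_s=0.15,
        )
        self.seg = DwellSegment(
            start_frame=10, end_frame=30, col_min=2, col_max=6,
            censored_left=False, censored_right=False, frame_interval_s=0.15,
        )

    def test_single_agreeing_trajectory_validates(self):
        tr = traj(0, range(10, 31), 9.0, 10.0)
        out = validate_segment(self.seg, self.kymo, [tr])
        assert out.status == "validated"
        assert out.support_ids == (0,)

    def test_two_supporting_trajectories_reject_as_merged(self):
        trs = [
            traj(0, range(10, 22), 9.0, 10.0),
            traj(1, range(21, 31), 9.5, 11.0),
        ]
        out = validate_segment(self.seg, self.kymo, trs)
        assert out.status == "rejected"
        assert out.reason == "merged"

    def test_no_trajectory_rejects_as_unsupported(self):
        far = traj(0, range(10, 31), 40.0, 40.0)
        out = validate_segment(self.seg, self.kymo, [far])
        assert (out.status, out.reason) == ("rejected", "unsupported")

    def test_endpoint_disagreement_rejects(self):
        tr = traj(0, range(5, 45), 9.0, 10.0)  # much longer than segment
        out = validate_segment(self.seg, self.kymo, [tr])
        assert (out.status, out.reason) == ("rejected", "unsupported")

    def test_censored_segment_rejected_before_support_counting(self):
        seg = DwellSegment(
            start_frame=0, end_frame=30, col_min=2, col_max=6,
            censored_left=True, censored_right=False, frame_interval_s=0.15,
        )
        tr = traj(0, range(0, 31), 9.0, 10.0)
        out = validate_segment(seg, self.kymo, [tr])
        assert (out.status, out.reason) == ("rejected", "censored")

    def test_brief_incursion_does_not_veto(self):
        """A particle crossing the footprint for two frames neither anchors
        nor rejects the segment."""
        trs = [
            traj(0, range(10, 31), 9.0, 10.0),
            traj(1, range(18, 20), 9.0, 10.5),
        ]
        out = validate_segment(self.seg, self.kymo, trs)
        assert out.status == "validated"


class TestRenderViews:
    def test_kymograph_tiff_dimensions_and_time_axis(self, tmp_path, rng):
        kymo = binary_kymo(range(40, 60), n_frames=100, n_cols=7)
        paths = render_views(kymo, tmp_path / "v")
        import tifffile

        raw = tifffile.imread(paths[0])
        assert raw.shape == (100, 7)  # T rows x L columns
        # 2 s of recording covers 2 / dt pixel rows.
        assert 2.0 / kymo.frame_interval_s == pytest.approx(13.333, rel=1e-3)
        assert (tmp_path / "v_kymo.png").exists()

    def test_projections_show_single_particle_as_one_streak(self, tmp_path):
        params = SimParams(
            n_frames=40, fov=(32, 32), arrival_rate=0.0, n_initial=1,
            dwell_law=("fixed", 100.0), diffusion_coeff_um2_s=0.0, seed=1,
        )
        stack, truth = simulate_movie(params)
        x, y = truth.positions.iloc[0][["x_px", "y_px"]]
        line = ScanLine((x - 4, y), (x + 4, y), 3)
        kymo = extract_kymograph(stack, line)
        paths = render_views(kymo, tmp_path / "p", stack=stack)
        assert (tmp_path / "p_views.png").exists()
        from scipy import ndimage

        for axis in (0, 1, 2):
            proj = stack.pixels.max(axis=axis)
            thr = np.median(proj) + 5 * 1.4826 * np.median(
                np.abs(proj - np.median(proj))
            )
            labels, n = ndimage.label(proj > thr)
            big = sum(
                1
                for i in range(1, n + 1)
                if (labels == i).sum() >= 4  # ignore isolated noise pixels
            )
            assert big == 1
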