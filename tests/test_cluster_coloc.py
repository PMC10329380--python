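"""SCI properties, channel registration, and colocalization metrics."""

import numpy as np
import pytest

from smkymo import (
    ImageStack,
    Kymograph,
    RegistrationTransform,
    ScanLine,
    Trajectory,
    apply_registration,
    colocalize_trajectories,
    compute_sci,
    estimate_registration,
    kymograph_overlap,
)
from smkymo.detect_track import Localization
from smkymo.errors import ParameterError, UndefinedSCIError


class TestSCI:
    def test_constant_image_scores_one(self):
        res = compute_sci(np.full((20, 20), 100.0))
        assert res.value == pytest.approx(1.0)

    def test_hand_computed_twenty_pixel_example(self):
        """19 pixels at 10, one at 1000: top set {1000}, bottom {10} -> 100."""
        img = np.full((4, 5), 10.0)
        img[0, 0] = 1000.0
        res = compute_sci(img)
        assert res.n_top == res.n_bottom == 1
        assert res.value == pytest.approx(100.0)

    def test_scale_invariance(self, rng):
        img = rng.random((30, 30)) + 0.5
        a = compute_sci(img).value
        b = compute_sci(img * 37.5).value
        assert a == pytest.approx(b, rel=1e-12)

    def test_concentrating_photons_increases_sci(self):
        """Same photon budget, fewer bright pixels -> strictly higher SCI."""
        n = 400
        budget = 4000.0
        base = np.full(n, 5.0)
        values = []
        # Keep clusters at least as large as the 5% top set (20 px of 400),
        # otherwise the top mean saturates and the ordering plateaus.
        for n_bright in (80, 40, 20):
            img = base.copy()
            img[:n_bright] += budget / n_bright
            values.append(compute_sci(img.reshape(20, 20)).value)
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_stack_reports_per_frame_mean_and_sd(self, rng):
        stack = rng.random((6, 16, 16)) + 0.1
        res = compute_sci(stack)
        assert len(res.per_frame) == 6
        assert res.value == pytest.approx(np.mean(res.per_frame))
        assert res.sd == pytest.approx(np.std(res.per_frame, ddof=1))

    def test_roi_restriction(self):
        img = np.full((10, 10), 10.0)
        img[0, :] = 1000.0
        roi = np.zeros((10, 10), dtype=bool)
        roi[5:, :] = True  # exclude the bright row
        assert compute_sci(img, roi=roi).value == pytest.approx(1.0)

    def test_zero_bottom_mean_is_undefined(self):
        img = np.zeros((10, 10))
        img[0, 0] = 5.0
        with pytest.raises(UndefinedSCIError):
            compute_sci(img)

    def test_tiny_roi_rejected(self):
        roi = np.zeros((5, 5), dtype=bool)
        roi[0, 0] = True
        with pytest.raises(ParameterError):
            compute_sci(np.ones((5, 5)), roi=roi)


def textured_image(rng, shape=(64, 64)):
    from scipy import ndimage

    return ndimage.gaussian_filter(rng.random(shape), 2.0) + 0.1


class TestRegistration:
    def test_identical_images_give_identity(self, rng):
        a = textured_image(rng)
        t = estimate_registration(a, a.copy())
        assert (t.dx, t.dy) == (0.0, 0.0)
        assert not t.low_confidence

    def test_integer_shift_recovered_exactly(self, rng):
        a = textured_image(rng)
        b = np.roll(a, (-2, 3), axis=(0, 1))  # dy=-2, dx=3
        t = estimate_registration(a, b, upsample=20)
        assert t.dx == pytest.approx(3.0)
        assert t.dy == pytest.approx(-2.0)

    def test_subpixel_shift_recovered(self, rng):
        a = textured_image(rng)
        dy, dx = -1.25, 0.5
        fa = np.fft.fft2(a)
        ky = np.fft.fftfreq(a.shape[0])[:, None]
        kx = np.fft.fftfreq(a.shape[1])[None, :]
        b = np.real(np.fft.ifft2(fa * np.exp(-2j * np.pi * (ky * dy + kx * dx))))
        t = estimate_registration(a, b, upsample=20)
        assert abs(t.dx - dx) < 0.1
        assert abs(t.dy - dy) < 0.1

    def test_featureless_images_flagged(self):
        t = estimate_registration(np.ones((32, 32)), np.ones((32, 32)))
        assert t.low_confidence
        assert (t.dx, t.dy) == (0.0, 0.0)

    def test_apply_identity_is_noop(self, rng):
        stack = ImageStack(rng.random((3, 16, 16)), 0.15, 0.1)
        out, valid = apply_registration(
            stack, RegistrationTransform(0.0, 0.0, 1.0)
        )
        np.testing.assert_allclose(out.pixels, stack.pixels)
        assert valid.all()

    def test_apply_integer_shift_relocates_exactly(self, rng):
        frame = rng.random((16, 16))
        stack = ImageStack(frame[None], 0.15, 0.1)
        out, valid = apply_registration(
            stack, RegistrationTransform(dx=3.0, dy=0.0, score=1.0)
        )
        # out[y, x] = frame[y, x + 3] wherever the source is in bounds.
        np.testing.assert_allclose(out.pixels[0][:, :13], frame[:, 3:])
        assert valid[:, :13].all()
        assert not valid[:, 13:].any()

    def test_shift_then_unshift_roundtrip(self, rng):
        from scipy import ndimage as ndi

        a = textured_image(rng, (32, 32))
        stack = ImageStack(a[None], 0.15, 0.1)
        t = RegistrationTransform(dx=1.5, dy=-0.75, score=1.0)
        fwd, valid1 = apply_registration(stack, t)
        back, valid2 = apply_registration(
            fwd, RegistrationTransform(dx=-t.dx, dy=-t.dy, score=1.0)
        )
        interior = ndi.binary_erosion(valid1 & valid2, iterations=3)
        assert np.abs(back.pixels[0] - a)[interior].max() < 0.02


def traj(tid, frames, xy):
    return Trajectory(
        id=tid,
        localizations=[
            Localization(frame=f, x=float(x), y=float(y), intensity=1, snr=5)
            for f, (x, y) in zip(frames, xy)
        ],
        frame_interval_s=0.15,
    )


class TestColocTrajectories:
    def test_identical_trajectories_fully_colocalized(self):
        frames = range(10)
        xy = [(5.0 + 0.1 * f, 7.0) for f in frames]
        res = colocalize_trajectories([traj(0, frames, xy)], [traj(10, frames, xy)])
        row = res.per_trajectory.iloc[0]
        assert row.overlap_fraction == pytest.approx(1.0)
        assert row.colocalized
        assert res.summary == pytest.approx(1.0)

    def test_temporally_disjoint_not_colocalized(self):
        a = traj(0, range(0, 5), [(5, 5)] * 5)
        b = traj(1, range(10, 15), [(5, 5)] * 5)
        res = colocalize_trajectories([a], [b])
        assert res.per_trajectory.iloc[0].overlap_frames == 0
        assert res.summary == pytest.approx(0.0)

    def test_distant_trajectories_not_colocalized(self):
        a = traj(0, range(10), [(5, 5)] * 10)
        b = traj(1, range(10), [(25, 25)] * 10)
        res = colocalize_trajectories([a], [b], dist_thresh_px=2.0)
        assert not res.per_trajectory.iloc[0].colocalized

    def test_best_partner_maximizes_overlap(self):
        a = traj(0, range(10), [(5, 5)] * 10)
        b_short = traj(1, range(3), [(5.1, 5)] * 3)
        b_long = traj(2, range(10), [(5.3, 5)] * 10)
        res = colocalize_trajectories([a], [b_short, b_long])
        assert res.per_trajectory.iloc[0].traj_b == 2

    def test_empty_input_flagged(self):
        res = colocalize_trajectories([], [])
        assert res.flagged_empty
        assert res.summary is None

    def test_bootstrap_ci_brackets_summary(self):
        trajs_a = [
            traj(i, range(10), [(5 + 10 * i, 5)] * 10) for i in range(10)
        ]
        trajs_b = [
            traj(100 + i, range(10), [(5 + 10 * i, 5.2)] * 10)
            for i in range(5)
        ]
        res = colocalize_trajectories(trajs_a, trajs_b, dist_thresh_px=2.0)
        assert res.ci_low <= res.summary <= res.ci_high


class TestKymographOverlap:
    def make_kymo(self, rows, value=100.0, n_frames=50, n_cols=5):
        m = np.zeros((n_frames, n_cols))
        m[rows, 2] = value
        return Kymograph(
            matrix=m,
            positions=np.column_stack(
                [np.arange(n_cols, dtype=float), np.zeros(n_cols)]
            ),
            line=ScanLine((0.0, 0.0), (4.0, 0.0), 1),
            reduction="max",
            frame_interval_s=0.15,
        )

    def test_equal_masks_overlap_one(self):
        a = self.make_kymo(slice(10, 20))
        res = kymograph_overlap(a, self.make_kymo(slice(10, 20)))
        assert res.fraction == pytest.approx(1.0)

    def test_disjoint_masks_overlap_zero(self):
        res = kymograph_overlap(
            self.make_kymo(slice(10, 20)), self.make_kymo(slice(30, 40))
        )
        assert res.fraction == pytest.approx(0.0)

    def test_half_overlap_constructed_masks(self):
        """A+ rows 10-19 vs B+ rows 15-30 at the same position -> 0.5."""
        res = kymograph_overlap(
            self.make_kymo(slice(10, 20)), self.make_kymo(slice(15, 31))
        )
        assert res.fraction == pytest.approx(0.5)

    def test_empty_a_mask_undefined(self):
        res = kymograph_overlap(
            self.make_kymo(slice(0, 0)), self.make_kymo(slice(10, 20))
        )
        assert res.undefined
        assert res.fraction is None

    def test_rgb_merge_shape(self):
        res = kymograph_overlap(
            self.make_kymo(slice(10, 20)), self.make_kymo(slice(15, 31))
        )
        assert res.rgb.shape == (50, 5, 3)
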