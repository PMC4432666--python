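"""Along-tract parameterization: resampling, orientation, profile modes."""

import numpy as np
import pytest

from tractaging import (
    Bundle,
    FAVolume,
    Geometry,
    InvalidParameterError,
    orient_bundle,
    profile_midline_split,
    profile_single_roi,
    profile_two_roi,
    resample_streamline,
)


def _line(x0, x1, n=50, y=9.0, z=5.0):
    return np.stack([np.linspace(x0, x1, n), np.full(n, y), np.full(n, z)], axis=1)


@pytest.fixture()
def ramp_fa():
    """FA ramps linearly 0.2 -> 0.4 along x over a 50-voxel grid (2 mm)."""
    geom = Geometry((50, 10, 6), (2.0, 2.0, 2.0))
    x = (np.arange(50) + 0.5) / 50.0
    data = np.broadcast_to(
        (0.2 + 0.2 * x)[:, None, None], geom.shape
    ).copy()
    return FAVolume(data, geom, np.ones(geom.shape, bool))


class TestResample:
    def test_uniform_spacing_on_straight_segment(self):
        out = resample_streamline(_line(0.0, 99.0, n=12), n=100)
        np.testing.assert_allclose(out[:, 0], np.arange(100.0), atol=1e-9)

    def test_idempotent_on_equidistant_input(self):
        pts = _line(0.0, 30.0, n=100)
        np.testing.assert_allclose(resample_streamline(pts, 100), pts, atol=1e-9)

    def test_endpoints_exact_and_spacing_uniform_on_arc(self):
        r = 24.0
        theta = np.linspace(0, np.pi / 2, 700)
        pts = np.stack([r * np.cos(theta), r * np.sin(theta), 0 * theta], axis=1)
        out = resample_streamline(pts, 100)
        np.testing.assert_array_equal(out[0], pts[0])
        np.testing.assert_array_equal(out[-1], pts[-1])
        gaps = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.ptp(gaps) < 1e-6
        # all resampled points lie within the chord-error bound of the circle
        radii = np.linalg.norm(out[:, :2], axis=1)
        chord_err = r * (1 - np.cos(np.pi / 2 / 699 / 2))
        assert np.max(np.abs(radii - r)) < chord_err + 1e-9

    def test_zero_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            resample_streamline(np.zeros((3, 3)))


class TestOrientBundle:
    def _setup(self):
        geom = Geometry((30, 10, 6), (2.0, 2.0, 2.0))
        seed_mask = np.zeros(geom.shape, bool)
        seed_mask[0:2] = True  # seed at low x
        return geom, seed_mask

    def test_seed_first_unchanged_and_reversed_flipped(self):
        geom, seed_mask = self._setup()
        fwd = _line(2.0, 58.0)
        rev = fwd[::-1]
        bundle = Bundle(1, 2, [fwd, rev])
        out = orient_bundle(bundle, seed_mask, geom)
        for pts in out.streamlines:
            assert pts[0, 0] < pts[-1, 0]

    def test_mixed_bundle_all_seed_first(self):
        geom, seed_mask = self._setup()
        lines = [_line(2.0, 58.0, y=1.0 + k) for k in range(10)]
        lines += [l[::-1] for l in lines]
        out = orient_bundle(Bundle(1, 2, lines), seed_mask, geom)
        assert out.n_fibers == 20
        seed_mm = (np.argwhere(seed_mask) + 0.5) * 2.0
        for pts in out.streamlines:
            d0 = np.min(np.linalg.norm(seed_mm - pts[0], axis=1))
            d1 = np.min(np.linalg.norm(seed_mm - pts[-1], axis=1))
            assert d0 <= d1  # first point is the seed-proximal end

    def test_far_streamline_excluded_with_warning(self):
        geom, seed_mask = self._setup()
        far = _line(40.0, 58.0)
        with pytest.warns(UserWarning):
            out = orient_bundle(Bundle(1, 2, [far]), seed_mask, geom)
        assert out.n_fibers == 0


class TestProfileTwoRoi:
    def test_constant_field_flat_profile_zero_se(self):
        geom = Geometry((30, 10, 6), (2.0, 2.0, 2.0))
        fa = FAVolume(np.full(geom.shape, 0.37), geom, np.ones(geom.shape, bool))
        bundle = Bundle(1, 2, [_line(4.0, 56.0, y=7.0 + k) for k in range(5)])
        prof = profile_two_roi(bundle, fa)
        np.testing.assert_allclose(prof.mean_fa, 0.37, atol=1e-9)
        np.testing.assert_allclose(prof.se, 0.0, atol=1e-9)

    def test_linear_ramp_monotone_profile_with_matching_endpoints(self, ramp_fa):
        bundle = Bundle(1, 2, [_line(1.0, 99.0, y=9.0, z=5.0)])
        prof = profile_two_roi(bundle, ramp_fa)
        diffs = np.diff(prof.mean_fa)
        assert np.all(diffs >= -1e-9)
        assert abs(prof.mean_fa[0] - 0.2) < 0.02
        assert abs(prof.mean_fa[-1] - 0.4) < 0.02

    def test_single_streamline_se_zero(self, ramp_fa):
        prof = profile_two_roi(Bundle(1, 2, [_line(1.0, 99.0)]), ramp_fa)
        assert prof.n_streamlines == 1
        np.testing.assert_array_equal(prof.se, 0.0)

    def test_empty_bundle_all_missing(self, ramp_fa):
        prof = profile_two_roi(Bundle(1, 2, []), ramp_fa)
        assert np.all(np.isnan(prof.mean_fa))

    def test_reversing_bundle_reverses_profile(self, ramp_fa):
        fwd = Bundle(1, 2, [_line(1.0, 99.0)])
        rev = Bundle(2, 1, [_line(1.0, 99.0)[::-1]])
        p_fwd = profile_two_roi(fwd, ramp_fa)
        p_rev = profile_two_roi(rev, ramp_fa)
        np.testing.assert_allclose(p_rev.mean_fa, p_fwd.mean_fa[::-1], atol=1e-12)


class TestProfileSingleRoi:
    def test_roi_at_end_matches_two_roi_profile(self, ramp_fa):
        geom = ramp_fa.geometry
        roi = np.zeros(geom.shape, bool)
        roi[0, 4, 2] = True  # at the low-x end of the lines
        lines = [_line(1.0, 99.0, y=9.0, z=5.0) for _ in range(3)]
        bundle = Bundle(1, 2, lines)
        single = profile_single_roi(bundle, ramp_fa, roi)
        two = profile_two_roi(bundle, ramp_fa)
        np.testing.assert_allclose(single.mean_fa, two.mean_fa, atol=0.01)

    def test_roi_mid_bundle_anchors_segment_one(self, ramp_fa):
        geom = ramp_fa.geometry
        roi = np.zeros(geom.shape, bool)
        roi[24:26, 4, 2] = True  # middle of the grid, x ~ 50 mm
        bundle = Bundle(1, 2, [_line(1.0, 99.0, y=9.0, z=5.0)])
        prof = profile_single_roi(bundle, ramp_fa, roi)
        # segment 1 anchored mid-bundle: FA there ~ 0.3 (the ramp midpoint)
        assert abs(prof.mean_fa[0] - 0.3) < 0.02

    def test_step_change_located_at_segment_30(self):
        """An FA step 30% of the way from the ROI lands at segment ~30."""
        geom = Geometry((50, 10, 6), (2.0, 2.0, 2.0))
        data = np.full(geom.shape, 0.45)
        step_x_mm = 1.0 + 0.30 * 98.0  # streamline spans 1..99 mm
        data[int(step_x_mm / 2.0):, :, :] = 0.25
        fa = FAVolume(data, geom, np.ones(geom.shape, bool))
        roi = np.zeros(geom.shape, bool)
        roi[0, 4, 2] = True
        bundle = Bundle(1, 2, [_line(1.0, 99.0, y=9.0, z=5.0) for _ in range(4)])
        prof = profile_single_roi(bundle, fa, roi)
        mid = (0.45 + 0.25) / 2
        crossing = int(np.argmax(prof.mean_fa < mid)) + 1  # 1-based segment
        assert abs(crossing - 30) <= 2

    def test_streamline_missing_roi_excluded(self, ramp_fa):
        geom = ramp_fa.geometry
        roi = np.zeros(geom.shape, bool)
        roi[0, 0, 0] = True
        ok = _line(1.0, 99.0, y=1.0, z=1.0)
        miss = _line(1.0, 99.0, y=9.0, z=5.0)
        with pytest.warns(UserWarning):
            prof = profile_single_roi(Bundle(1, 2, [ok, miss]), ramp_fa, roi)
        assert prof.n_streamlines == 1


class TestProfileMidlineSplit:
    def _u_bundle(self, geom, depress_midline=False):
        """U-shaped bundle symmetric about the x = 50 mm midline."""
        data = np.full(geom.shape, 0.45)
        if depress_midline:
            data[23:27, :, :] = 0.25
        fa = FAVolume(data, geom, np.ones(geom.shape, bool))
        theta = np.linspace(-np.pi / 2, np.pi / 2, 300)
        lines = []
        for k in range(6):
            r = 16.0 + 0.5 * k
            pts = np.stack(
                [50.0 + r * np.sin(theta), 20.0 + r * np.cos(theta),
                 np.full_like(theta, 6.0)], axis=1)
            lines.append(pts)
        return fa, Bundle(1, 2, lines)

    def test_symmetric_u_gives_equal_sides(self):
        geom = Geometry((50, 20, 6), (2.0, 2.0, 2.0))
        fa, bundle = self._u_bundle(geom)
        left, right = profile_midline_split(bundle, fa)
        assert left.side == "left" and right.side == "right"
        np.testing.assert_allclose(left.mean_fa, right.mean_fa, atol=0.02)

    def test_midline_depression_minimum_at_segment_one(self):
        geom = Geometry((50, 20, 6), (2.0, 2.0, 2.0))
        fa, bundle = self._u_bundle(geom, depress_midline=True)
        left, right = profile_midline_split(bundle, fa)
        for prof in (left, right):
            assert np.nanargmin(prof.mean_fa) < 10  # minimum near the midline
            assert prof.mean_fa[0] < 0.3

    def test_non_crossing_streamlines_excluded_empty_side_missing(self):
        geom = Geometry((50, 20, 6), (2.0, 2.0, 2.0))
        fa = FAVolume(np.full(geom.shape, 0.45), geom, np.ones(geom.shape, bool))
        only_left = [_line(4.0, 40.0, y=20.0, z=6.0)]  # never crosses x = 50
        left, right = profile_midline_split(Bundle(1, 2, only_left), fa)
        assert left.n_streamlines == 0 and right.n_streamlines == 0
        assert np.all(np.isnan(left.mean_fa))
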