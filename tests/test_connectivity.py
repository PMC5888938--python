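"""Unit and property tests for the connectivity processing chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hubreserve._types import BoldRun, FdSeries, GmMask, MotionTrace, RoiSpec
from hubreserve.connectivity import (
    R_CLIP,
    bandpass_filter,
    build_censor_mask,
    build_group_gm_mask,
    compute_framewise_displacement,
    denoise_run,
    global_connectivity,
    make_sphere_roi,
    smooth_volumes,
)


def _motion(n, trans=None, rot=None):
    t = np.zeros((n, 3)) if trans is None else trans
    r = np.zeros((n, 3)) if rot is None else rot
    return MotionTrace(t, r)


class TestFramewiseDisplacement:
    def test_constant_parameters_give_zero_fd(self):
        fd = compute_framewise_displacement(_motion(10))
        assert np.all(fd.fd == 0)

    def test_single_axis_translation_step(self):
        trans = np.zeros((8, 3))
        trans[5:, 0] = 0.6  # x steps by 0.6 mm between volumes 4 and 5
        fd = compute_framewise_displacement(_motion(8, trans=trans))
        expected = np.zeros(8)
        expected[5] = 0.6
        np.testing.assert_allclose(fd.fd, expected)

    def test_rotation_converted_on_50mm_sphere(self):
        rot = np.zeros((6, 3))
        rot[3:, 1] = 0.01  # radians
        fd = compute_framewise_displacement(_motion(6, rot=rot))
        assert fd.fd[3] == pytest.approx(0.5)  # 50 mm * 0.01 rad
        assert fd.fd[0] == 0

    def test_combines_translation_and_rotation_sums(self):
        trans = np.zeros((4, 3))
        rot = np.zeros((4, 3))
        trans[2:] = [0.1, -0.2, 0.3]
        rot[2:] = [0.002, 0.0, -0.001]
        fd = compute_framewise_displacement(MotionTrace(trans, rot))
        assert fd.fd[2] == pytest.approx(0.6 + 50 * 0.003)

    def test_single_volume_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_framewise_displacement(_motion(1))


class TestCensorMask:
    def test_quiet_run_fully_retained(self):
        mask = build_censor_mask(np.array([0, 0.1, 0.1, 0.1]))
        assert mask.retained.all() and not mask.excluded

    def test_hand_trace_with_exclusion(self):
        # spike at index 1: censor {0,1,2,3}; 4/6 > 30% -> excluded
        mask = build_censor_mask(np.array([0.1, 0.6, 0.1, 0.1, 0.1, 0.1]))
        assert set(np.flatnonzero(~mask.retained)) == {0, 1, 2, 3}
        assert mask.censored_fraction == pytest.approx(4 / 6)
        assert mask.excluded

    def test_overlapping_windows_union(self):
        fd = np.zeros(12)
        fd[[3, 5]] = 0.7
        mask = build_censor_mask(fd)
        assert set(np.flatnonzero(~mask.retained)) == set(range(2, 8))

    def test_threshold_is_strict(self):
        mask = build_censor_mask(np.array([0.0, 0.5, 0.5]))
        assert mask.retained.all()

    def test_exclusion_boundary_is_strict(self):
        # exactly 30% censored must NOT exclude
        fd = np.zeros(10)
        fd[1] = 0.9  # censors {0,1,2,3} = 40% -> excluded
        assert build_censor_mask(fd).excluded
        fd20 = np.zeros(20)
        fd20[2] = 0.9  # censors {1,2,3,4} = 20%
        assert not build_censor_mask(fd20).excluded
        fd_exact = np.zeros(10)
        fd_exact[5] = 0.9  # censors {4,5,6,7} = 3/10? -> 4/10
        mask = build_censor_mask(fd_exact, n_pre=1, n_post=1)  # censors {4,5,6} = 30%
        assert mask.censored_fraction == pytest.approx(0.30)
        assert not mask.excluded

    def test_rebuilding_is_idempotent(self):
        fd = np.array([0.0, 0.6, 0.1, 0.2, 0.8, 0.1, 0.0, 0.0])
        m1 = build_censor_mask(fd)
        m2 = build_censor_mask(fd)
        np.testing.assert_array_equal(m1.retained, m2.retained)

    @settings(deadline=None, max_examples=50)
    @given(
        fd=st.lists(st.floats(0, 2, allow_nan=False), min_size=2, max_size=40),
        thr_lo=st.floats(0.1, 0.45),
    )
    def test_lowering_threshold_never_uncensors(self, fd, thr_lo):
        fd = np.asarray(fd)
        high = build_censor_mask(fd, threshold_mm=0.5)
        low = build_censor_mask(fd, threshold_mm=thr_lo)
        censored_high = ~high.retained
        censored_low = ~low.retained
        assert np.all(censored_low[censored_high])


class TestSphereRoi:
    affine = np.diag([2.0, 2.0, 2.0, 1.0])

    def test_tiny_radius_hits_single_voxel(self):
        spec = RoiSpec("LFC", (10.0, 10.0, 10.0), radius=0.1)
        mask = make_sphere_roi(spec, self.affine, (20, 20, 20))
        assert mask.sum() == 1
        assert mask[5, 5, 5]

    def test_8mm_sphere_on_2mm_grid_has_257_voxels(self):
        # lattice enumeration of i^2+j^2+k^2 <= 16 gives 257 points
        spec = RoiSpec("LFC", (20.0, 20.0, 20.0), radius=8.0)
        mask = make_sphere_roi(spec, self.affine, (21, 21, 21))
        assert mask.sum() == 257

    def test_translation_by_whole_voxel_preserves_count(self):
        a = make_sphere_roi(RoiSpec("LFC", (20, 20, 20), 8.0), self.affine, (25, 25, 25))
        b = make_sphere_roi(RoiSpec("LFC", (22, 20, 20), 8.0), self.affine, (25, 25, 25))
        assert a.sum() == b.sum()
        np.testing.assert_array_equal(np.roll(a, 1, axis=0), b)

    def test_sphere_outside_grid_raises_with_seed_name(self):
        spec = RoiSpec("OCC", (-500.0, 0.0, 0.0), radius=8.0)
        with pytest.raises(ValueError, match="OCC"):
            make_sphere_roi(spec, self.affine, (10, 10, 10))


class TestGroupGmMask:
    def test_all_ones_gives_full_mask(self):
        gm = build_group_gm_mask([np.ones((4, 4, 4))] * 3)
        assert gm.mask.all()

    def test_mean_exactly_at_threshold_is_excluded(self):
        maps = [np.full((3, 3, 3), 0.30), np.full((3, 3, 3), 0.30)]
        maps[0][0, 0, 0] = 0.9
        gm = build_group_gm_mask(maps)
        assert gm.mask.sum() == 1  # only the voxel strictly above 0.3

    def test_mean_above_threshold_included(self):
        a = np.full((2, 2, 2), 0.2)
        b = np.full((2, 2, 2), 0.5)
        assert build_group_gm_mask([a, b]).mask.all()  # mean 0.35

    @pytest.mark.parametrize(
        "maps,err",
        [([], "at least one"), ([np.ones((2, 2, 2)), np.ones((3, 3, 3))], "shape")],
    )
    def test_degenerate_inputs(self, maps, err):
        with pytest.raises(ValueError, match=err):
            build_group_gm_mask(maps)


class TestSmoothing:
    def _run(self, data, voxel=2.0):
        return BoldRun(data, tr=2.0, affine=np.diag([voxel, voxel, voxel, 1.0]))

    def test_constant_volume_unchanged(self):
        run = self._run(np.full((8, 8, 8, 3), 7.0))
        out = smooth_volumes(run, 8.0)
        np.testing.assert_allclose(out.data, run.data, atol=1e-10)

    def test_zero_fwhm_is_identity(self):
        data = np.random.default_rng(0).standard_normal((6, 6, 6, 4))
        out = smooth_volumes(self._run(data), 0.0)
        assert np.array_equal(out.data, data)

    def test_impulse_matches_gaussian_profile(self):
        # fine 1 mm grid; sigma = 8 / 2.3548 ~ 3.397 mm
        data = np.zeros((41, 41, 41, 2))
        data[20, 20, 20, :] = 1.0
        out = smooth_volumes(self._run(data, voxel=1.0), 8.0)
        sigma = 8.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        profile = out.data[20:31, 20, 20, 0]
        expected = profile[0] * np.exp(-np.arange(11) ** 2 / (2 * sigma**2))
        np.testing.assert_allclose(profile, expected, rtol=1e-3)

    def test_anisotropic_voxels_use_world_sigma(self):
        data = np.zeros((31, 31, 31, 2))
        data[15, 15, 15, :] = 1.0
        run = BoldRun(data, tr=2.0, affine=np.diag([1.0, 2.0, 1.0, 1.0]))
        out = smooth_volumes(run, 8.0)
        # world-space profile along y (2 mm steps) matches x at same mm offsets
        x_profile = out.data[15:20, 15, 15, 0]
        y_profile = out.data[15, 15:20, 15, 0]
        np.testing.assert_allclose(y_profile[1], x_profile[2], rtol=1e-3)


class TestDenoise:
    tr = 2.23

    def _run(self, data):
        return BoldRun(data, tr=self.tr, affine=np.eye(4))

    def _masks(self, shape):
        wm = np.zeros(shape, dtype=bool)
        csf = np.zeros(shape, dtype=bool)
        wm[0, 0, 0] = True
        csf[-1, -1, -1] = True
        return wm, csf

    def test_pure_linear_trend_removed(self):
        t = np.arange(80, dtype=float)
        data = np.tile(3.0 + 0.5 * t, (3, 3, 3, 1))
        run = self._run(data)
        wm, csf = self._masks((3, 3, 3))
        cleaned = denoise_run(run, _motion(80), wm, csf)
        assert np.abs(cleaned).max() < 1e-8

    def test_passband_and_stopband_gains(self):
        t = np.arange(400) * self.tr
        core = slice(50, -50)
        for freq, lo, hi in [(0.04, 0.95, 1.05), (0.2, 0.0, 0.1)]:
            x = np.sin(2 * np.pi * freq * t)
            y = bandpass_filter(x, self.tr)
            gain = y[core].std() / x[core].std()
            assert lo <= gain <= hi, f"{freq} Hz gain {gain}"

    def test_motion_regressor_removed(self):
        rng = np.random.default_rng(1)
        n = 120
        trans = np.zeros((n, 3))
        trans[:, 0] = np.cumsum(0.01 * rng.standard_normal(n))
        motion = _motion(n, trans=trans)
        data = np.tile(trans[:, 0], (3, 3, 3, 1)) + 100.0
        run = self._run(data)
        wm, csf = self._masks((3, 3, 3))
        cleaned = denoise_run(run, motion, wm, csf)
        assert np.abs(cleaned).max() < 1e-8

    def test_output_mean_near_zero(self, toy_run):
        cleaned = denoise_run(
            toy_run["run"], toy_run["motion"], toy_run["wm"], toy_run["csf"]
        )
        assert np.abs(cleaned.mean(axis=1)).max() < 1e-6

    def test_invalid_band_rejected(self):
        run = self._run(np.random.default_rng(0).standard_normal((3, 3, 3, 20)))
        wm, csf = self._masks((3, 3, 3))
        with pytest.raises(ValueError, match="Nyquist"):
            denoise_run(run, _motion(20), wm, csf, band_hz=(0.01, 0.5))

    def test_mismatched_motion_length_rejected(self):
        run = self._run(np.zeros((3, 3, 3, 20)) + np.arange(20))
        wm, csf = self._masks((3, 3, 3))
        with pytest.raises(ValueError, match="does not match"):
            denoise_run(run, _motion(19), wm, csf)


def _retained(n):
    from hubreserve._types import CensorMask

    return CensorMask(np.ones(n, dtype=bool), 0.0, False)


class TestGlobalConnectivity:
    def _gm(self, shape, seed_mask):
        mask = np.ones(shape, dtype=bool)
        return GmMask(mask)

    def test_orthogonal_series_score_near_zero(self):
        t = np.linspace(0, 8 * np.pi, 64, endpoint=False)
        shape = (4, 4, 4)
        seed_mask = np.zeros(shape, dtype=bool)
        seed_mask[0, 0, 0] = True
        cleaned = np.tile(np.cos(t), (64, 1))
        cleaned[0] = np.sin(t)
        res = global_connectivity(cleaned, seed_mask, self._gm(shape, seed_mask), _retained(64))
        assert abs(res.score) < 1e-8

    def test_perfect_correlation_clipped(self):
        t = np.linspace(0, 4 * np.pi, 40)
        shape = (3, 3, 3)
        seed_mask = np.zeros(shape, dtype=bool)
        seed_mask[0, 0, 0] = True
        base = np.sin(t)
        scales = np.arange(1, 28, dtype=float)
        cleaned = np.outer(scales, base)
        res = global_connectivity(cleaned, seed_mask, self._gm(shape, seed_mask), _retained(40))
        assert res.score == pytest.approx(np.arctanh(R_CLIP))
        assert res.n_positive_voxels == res.n_gm_voxels == 26

    def test_matches_brute_force_oracle(self, toy_run):
        run, motion = toy_run["run"], toy_run["motion"]
        cleaned = denoise_run(run, motion, toy_run["wm"], toy_run["csf"])
        roi = make_sphere_roi(toy_run["params"].seed_roi, run.affine, run.shape3d)
        gm = toy_run["gm"]
        censor = build_censor_mask(compute_framewise_displacement(motion))
        res = global_connectivity(cleaned, roi, gm, censor)
        seed_ts = cleaned[(roi & gm.mask).ravel()][:, censor.retained].mean(axis=0)
        zs = []
        for i in np.flatnonzero(gm.mask.ravel() & ~roi.ravel()):
            v = cleaned[i, censor.retained]
            r = 0.0 if v.std() == 0 else np.corrcoef(seed_ts, v)[0, 1]
            if r > 0:
                zs.append(np.arctanh(min(r, R_CLIP)))
        assert res.score == pytest.approx(np.mean(zs), abs=1e-10)

    def test_voxel_permutation_and_positive_scaling_invariance(self, rng):
        shape = (4, 4, 4)
        seed_mask = np.zeros(shape, dtype=bool)
        seed_mask[1, 1, 1] = True
        cleaned = rng.standard_normal((64, 50))
        gm = self._gm(shape, seed_mask)
        base = global_connectivity(cleaned, seed_mask, gm, _retained(50)).score
        # scale every non-seed voxel by a positive constant
        scaled = cleaned * rng.uniform(0.5, 5.0, size=(64, 1))
        seed_idx = np.flatnonzero(seed_mask.ravel())[0]
        scaled[seed_idx] = cleaned[seed_idx]
        assert global_connectivity(scaled, seed_mask, gm, _retained(50)).score == pytest.approx(base, abs=1e-12)

    def test_score_bounds(self, rng):
        shape = (4, 4, 4)
        seed_mask = np.zeros(shape, dtype=bool)
        seed_mask[0, 0, 0] = True
        for _ in range(5):
            cleaned = rng.standard_normal((64, 30))
            s = global_connectivity(cleaned, seed_mask, self._gm(shape, seed_mask), _retained(30)).score
            assert 0 <= s <= np.arctanh(R_CLIP)

    def test_no_positive_voxel_warns_and_scores_zero(self):
        t = np.linspace(0, 4 * np.pi, 40)
        shape = (2, 2, 2)
        seed_mask = np.zeros(shape, dtype=bool)
        seed_mask[0, 0, 0] = True
        cleaned = np.tile(-np.sin(t), (8, 1))
        cleaned[0] = np.sin(t)
        with pytest.warns(RuntimeWarning, match="no positively"):
            res = global_connectivity(cleaned, seed_mask, self._gm(shape, seed_mask), _retained(40))
        assert res.score == 0.0 and res.no_positive_warning

    def test_excluded_subject_refused(self):
        from hubreserve._types import CensorMask

        censor = CensorMask(np.zeros(40, dtype=bool), 1.0, True)
        shape = (2, 2, 2)
        seed_mask = np.zeros(shape, dtype=bool)
        seed_mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="excluded"):
            global_connectivity(np.ones((8, 40)), seed_mask, self._gm(shape, seed_mask), censor)

    def test_zero_variance_seed_rejected(self):
        shape = (2, 2, 2)
        seed_mask = np.zeros(shape, dtype=bool)
        seed_mask[0, 0, 0] = True
        cleaned = np.random.default_rng(0).standard_normal((8, 40))
        cleaned[0] = 5.0
        with pytest.raises(ValueError, match="zero variance"):
            global_connectivity(cleaned, seed_mask, self._gm(shape, seed_mask), _retained(40))

    def test_too_few_retained_volumes_rejected(self):
        from hubreserve._types import CensorMask

        retained = np.zeros(40, dtype=bool)
        retained[:5] = True
        censor = CensorMask(retained, 1 - 5 / 40, False)
        shape = (2, 2, 2)
        seed_mask = np.zeros(shape, dtype=bool)
        seed_mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="retained"):
            global_connectivity(np.random.default_rng(0).standard_normal((8, 40)), seed_mask, self._gm(shape, seed_mask), censor)
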