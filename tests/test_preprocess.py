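"""Preprocessing stages: tcat, outliers, slice timing, motion, resampling,
blur, mask, scale and multi-echo combination."""

import numpy as np
import pytest

from fmripipe import preprocess as pre
from fmripipe.types import EchoSet, Grid, MotionParams, Volume4D


class TestRemoveInitialVolumes:
    def test_zero_is_identity(self, random_vol):
        out = pre.remove_initial_volumes(random_vol, 0)
        assert np.array_equal(out.data, random_vol.data)

    def test_removes_per_run(self, small_grid, rng):
        v = Volume4D(
            grid=small_grid, data=rng.random((8, 8, 6, 20)), run_lengths=[10, 10]
        )
        out = pre.remove_initial_volumes(v, 4)
        assert out.n_volumes == 12
        assert out.run_lengths == [6, 6]
        assert np.array_equal(out.data[..., 0], v.data[..., 4])
        assert np.array_equal(out.data[..., 6], v.data[..., 14])

    def test_removing_everything_is_an_error(self, random_vol):
        with pytest.raises(ValueError):
            pre.remove_initial_volumes(random_vol, random_vol.n_volumes)


class TestTemporalOutliers:
    def test_constant_series_have_zero_fraction(self, small_grid):
        v = Volume4D(grid=small_grid, data=np.full((8, 8, 6, 20), 50.0))
        frac = pre.temporal_outlier_fraction(v, np.ones((8, 8, 6), bool))
        assert np.allclose(frac, 0.0)

    def test_planted_spike_fraction_recovered(self, rng):
        g = Grid.isotropic((12, 12, 8), 3.0)
        data = 100.0 + rng.standard_normal((12, 12, 8, 40))
        mask = np.ones((12, 12, 8), bool)
        vox = np.argwhere(mask)
        picked = vox[rng.choice(len(vox), int(0.10 * len(vox)), replace=False)]
        data[picked[:, 0], picked[:, 1], picked[:, 2], 17] += 10.0
        v = Volume4D(grid=g, data=data)
        frac = pre.temporal_outlier_fraction(v, mask)
        assert frac[17] == pytest.approx(0.10, abs=0.02)
        assert np.all(frac >= 0) and np.all(frac <= 1)

    def test_empty_mask_rejected(self, random_vol):
        with pytest.raises(ValueError):
            pre.temporal_outlier_fraction(random_vol, np.zeros((8, 8, 6), bool))


class TestPreSteadyState:
    def test_scaled_leading_volumes_detected(self, rng):
        g = Grid.isotropic((10, 10, 6), 3.0)
        data = 100.0 + 0.5 * rng.standard_normal((10, 10, 6, 30))
        data[..., :2] *= 1.10
        v = Volume4D(grid=g, data=data)
        assert pre.detect_pre_steady_state(v, np.ones((10, 10, 6), bool)) == 2

    def test_stationary_series_flag_zero(self, rng):
        g = Grid.isotropic((10, 10, 6), 3.0)
        data = 100.0 + 0.5 * rng.standard_normal((10, 10, 6, 30))
        v = Volume4D(grid=g, data=data)
        assert pre.detect_pre_steady_state(v, np.ones((10, 10, 6), bool)) == 0


class TestSliceTimeCorrect:
    def test_aligned_slices_unchanged(self, small_grid):
        data = np.random.default_rng(1).random((8, 8, 6, 20))
        v = Volume4D(grid=small_grid, data=data, tr=2.0, slice_times=np.zeros(6))
        out = pre.slice_time_correct(v, align_to=0.0)
        assert np.allclose(out.data, data, atol=1e-10)

    def test_constant_series_exactly_unchanged(self, small_grid):
        v = Volume4D(
            grid=small_grid,
            data=np.full((8, 8, 6, 20), 7.0),
            tr=2.0,
            slice_times=np.linspace(0, 1.5, 6),
        )
        out = pre.slice_time_correct(v)
        assert np.allclose(out.data, 7.0, atol=1e-8)
        assert np.allclose(out.slice_times, 0.0)

    def test_sinc_kernel_phase_accuracy_on_sinusoid(self):
        """Half-TR offset slice: corrected series must match the analytic
        sinusoid mid-series with sub-degree phase error."""
        tr, nt, f = 2.0, 60, 0.05
        g = Grid.isotropic((4, 4, 2), 3.0)
        t = np.arange(nt) * tr
        data = np.zeros((4, 4, 2, nt))
        data[:, :, 0, :] = np.sin(2 * np.pi * f * t)
        data[:, :, 1, :] = np.sin(2 * np.pi * f * (t + tr / 2))
        v = Volume4D(grid=g, data=data, tr=tr, slice_times=np.array([0.0, tr / 2]))
        out = pre.slice_time_correct(v, method="wsinc9", align_to=0.0)
        ideal = np.sin(2 * np.pi * f * t)
        mid = slice(15, 45)
        # worst-case amplitude error bounds the phase error: 1 deg ~ 0.0175 rad
        max_phase_err = np.abs(out.data[0, 0, 1, mid] - ideal[mid]).max() / (
            2 * np.pi * f * tr
        )
        assert np.degrees(max_phase_err * 2 * np.pi * f * tr) < 1.0

    def test_missing_slice_times_rejected(self, small_grid):
        v = Volume4D(grid=small_grid, data=np.zeros((8, 8, 6, 10)))
        with pytest.raises(ValueError):
            pre.slice_time_correct(v)


class TestMinOutlierReference:
    def test_argmin_with_tie_break(self):
        frac = np.array([0.02, 0.01, 0.05])
        assert int(np.argmin(frac)) == 1
        assert int(np.argmin(np.zeros(5))) == 0

    def test_spiked_volume_never_selected(self, rng):
        g = Grid.isotropic((10, 10, 6), 3.0)
        data = 100.0 + rng.standard_normal((10, 10, 6, 20))
        data[..., 9] += 15.0 * (rng.random((10, 10, 6)) < 0.3)
        v = Volume4D(grid=g, data=data)
        assert pre.select_min_outlier_reference(v, np.ones((10, 10, 6), bool)) != 9


class TestRigidMotion:
    def test_duplicate_volumes_give_zero_parameters(self, ellipsoid_phantom):
        vol, _ = ellipsoid_phantom
        frame = vol.data[..., 0]
        v = Volume4D(grid=vol.grid, data=np.stack([frame] * 3, axis=-1))
        mp = pre.estimate_rigid_motion(v, 0)
        assert np.all(np.abs(mp.params) < 1e-3)

    def test_injected_translation_and_rotation_recovered(self):
        from fmripipe.synth import make_phantom

        vol, _ = make_phantom(
            dims=(32, 32, 20), n_volumes=1, noise_tsnr=0, drift_percent=0,
            texture=0.15, seed=4,
        )
        base = pre.gaussian_blur(vol, 5.0).data[..., 0]
        truth = np.array([[0, 0, 0, 0, 2.0, 0], [3.0, 0, 0, 0, 0, 0]])
        frames = [base] + [pre.apply_rigid(base, vol.grid, p) for p in truth]
        v = Volume4D(grid=vol.grid, data=np.stack(frames, axis=-1))
        mp = pre.estimate_rigid_motion(v, 0)
        assert mp.params[1, 4] == pytest.approx(2.0, abs=0.1)
        assert mp.params[2, 0] == pytest.approx(3.0, abs=0.2)

    def test_all_zero_reference_rejected(self, small_grid):
        v = Volume4D(grid=small_grid, data=np.zeros((8, 8, 6, 3)))
        with pytest.raises(ValueError):
            pre.estimate_rigid_motion(v, 0)


class TestConcatenatedTransform:
    def test_identity_chain_is_exact(self, random_vol):
        mp = MotionParams(np.zeros((random_vol.n_volumes, 6)))
        out = pre.apply_concatenated_transform(random_vol, mp, kernel="trilinear")
        assert np.allclose(out.data, random_vol.data, atol=1e-12)

    def test_translations_compose_additively(self, ellipsoid_phantom):
        vol, _ = ellipsoid_phantom
        v1 = Volume4D(grid=vol.grid, data=vol.data[..., :1])
        a = np.eye(4)
        a[:3, 3] = [3.0, 0, 0]
        b = np.eye(4)
        b[:3, 3] = [0, -3.0, 0]
        ab = b @ a
        one = pre.apply_concatenated_transform(v1, None, epi2anat=a, anat2final=b)
        direct = pre.apply_concatenated_transform(v1, None, epi2anat=ab)
        assert np.allclose(one.data, direct.data, atol=1e-6)

    def test_single_resample_beats_sequential_on_delta(self):
        """One composed interpolation smooths less than two chained ones."""
        g = Grid.isotropic((16, 16, 10), 3.0)
        delta = np.zeros((16, 16, 10))
        delta[8, 8, 5] = 1.0
        v = Volume4D(grid=g, data=delta[..., np.newaxis])
        half = MotionParams(np.array([[0, 0, 0, 0, -1.5, 0]]))
        full = MotionParams(np.array([[0, 0, 0, 0, -3.0, 0]]))
        one_step = pre.apply_concatenated_transform(v, full)
        two_step = pre.apply_concatenated_transform(
            pre.apply_concatenated_transform(v, half), half
        )
        assert one_step.data.max() >= two_step.data.max()
        assert one_step.data.max() == pytest.approx(1.0, abs=1e-9)

    def test_wsinc_exact_on_integer_voxel_shift(self, ellipsoid_phantom):
        """Windowed-sinc weights collapse to a delta at integer shifts, so a
        whole-voxel translation must reproduce the rolled image."""
        vol, _ = ellipsoid_phantom
        v1 = Volume4D(grid=vol.grid, data=pre.gaussian_blur(vol, 4.0).data[..., :1])
        vs = vol.grid.voxel_size[0]
        mp = MotionParams(np.array([[0, 0, 0, 0, vs, 0]]))  # dL: one voxel left
        ws = pre.apply_concatenated_transform(v1, mp, kernel="wsinc5")
        expected = np.roll(v1.data[..., 0], 1, axis=0)
        inner = (slice(6, -6),) * 2 + (slice(3, -3),)
        assert np.allclose(ws.data[..., 0][inner], expected[inner], atol=1e-6)


class TestGaussianBlur:
    def test_zero_fwhm_identity(self, random_vol):
        assert pre.gaussian_blur(random_vol, 0.0) is random_vol

    def test_total_intensity_conserved(self, random_vol):
        out = pre.gaussian_blur(random_vol, 6.0)
        assert out.data.sum() == pytest.approx(random_vol.data.sum(), rel=1e-6)

    def test_delta_peak_matches_separable_kernel(self):
        g = Grid.isotropic((16, 16, 10), 3.0)
        delta = np.zeros((16, 16, 10))
        delta[8, 8, 5] = 1.0
        out = pre.gaussian_blur(Volume4D(grid=g, data=delta[..., None]), 6.0)
        sigma_vox = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        k = np.exp(-np.arange(-8, 9) ** 2 / (2 * sigma_vox**2))
        k /= k.sum()
        assert out.data.max() == pytest.approx(k.max() ** 3, rel=0.02)

    def test_negative_fwhm_rejected(self, random_vol):
        with pytest.raises(ValueError):
            pre.gaussian_blur(random_vol, -1.0)


class TestAutomask:
    def test_dice_against_phantom_truth(self, ellipsoid_phantom):
        vol, truth = ellipsoid_phantom
        mask = pre.compute_epi_automask(vol)
        inter = np.logical_and(mask, truth.brain_mask).sum()
        dice = 2 * inter / (mask.sum() + truth.brain_mask.sum())
        assert dice >= 0.95

    def test_anat_subset_intersection(self, ellipsoid_phantom):
        vol, truth = ellipsoid_phantom
        sub = truth.brain_mask.copy()
        sub[: vol.grid.dims[0] // 2] = False
        out = pre.compute_epi_automask(vol, anat_mask=sub)
        assert np.array_equal(out, np.logical_and(out, sub))

    def test_all_zero_volume_rejected(self, small_grid):
        v = Volume4D(grid=small_grid, data=np.zeros((8, 8, 6, 4)))
        with pytest.raises(ValueError):
            pre.compute_epi_automask(v)


class TestScalePercent:
    def test_formula_on_simple_series(self, small_grid):
        v = Volume4D(grid=small_grid, data=np.tile([1.0, 2.0, 3.0], (8, 8, 6, 1)))
        out = pre.scale_percent(v)
        assert np.allclose(out.data[0, 0, 0], [50, 100, 150])
        assert out.units_tag == "percent"

    def test_cap_at_200(self, small_grid):
        v = Volume4D(grid=small_grid, data=np.tile([1.0, 9.0], (8, 8, 6, 1)))
        out = pre.scale_percent(v)
        assert np.allclose(out.data[0, 0, 0], [20.0, 180.0])
        v2 = Volume4D(grid=small_grid, data=np.tile([1.0, 1.0, 10.0], (8, 8, 6, 1)))
        assert pre.scale_percent(v2).data[..., 2].max() == 200.0

    def test_positive_mean_voxels_scale_to_mean_100(self, rng, small_grid):
        data = 80.0 + 10.0 * rng.standard_normal((8, 8, 6, 30))
        out = pre.scale_percent(Volume4D(grid=small_grid, data=data))
        means = out.data.mean(axis=3)
        assert np.allclose(means, 100.0, atol=1e-9)

    def test_idempotent(self, rng, small_grid):
        data = 80.0 + 10.0 * rng.standard_normal((8, 8, 6, 30))
        once = pre.scale_percent(Volume4D(grid=small_grid, data=data))
        twice = pre.scale_percent(once)
        assert np.allclose(once.data, twice.data, atol=1e-9)

    def test_nonpositive_mean_voxels_zeroed(self, small_grid):
        v = Volume4D(grid=small_grid, data=np.full((8, 8, 6, 4), -5.0))
        assert np.all(pre.scale_percent(v).data == 0)


class TestOptimalCombination:
    def test_exact_t2star_from_noiseless_decay(self, small_grid):
        t2 = 20.0
        tes = [10.0, 30.0]
        echoes = [
            Volume4D(grid=small_grid, data=np.full((8, 8, 6, 5), 1000 * np.exp(-te / t2)))
            for te in tes
        ]
        _, w = pre.fit_t2star_and_combine(EchoSet(echoes=echoes, echo_times=tes))
        assert np.allclose(w.t2star, t2, atol=1e-6)

    def test_weights_closed_form(self, small_grid):
        tes = [10.0, 30.0]
        echoes = [
            Volume4D(grid=small_grid, data=np.full((8, 8, 6, 5), 1000 * np.exp(-te / 20.0)))
            for te in tes
        ]
        _, w = pre.fit_t2star_and_combine(EchoSet(echoes=echoes, echo_times=tes))
        expect = np.array([10 * np.exp(-0.5), 30 * np.exp(-1.5)])
        expect /= expect.sum()
        assert np.allclose(w.weights[0, 0, 0], expect, atol=1e-4)
        assert w.weights[0, 0, 0] == pytest.approx([0.4754, 0.5246], abs=1e-3)

    def test_identical_echoes_pass_through(self, rng, small_grid):
        data = 100 + rng.random((8, 8, 6, 5))
        echoes = [Volume4D(grid=small_grid, data=data.copy()) for _ in range(3)]
        combined, w = pre.fit_t2star_and_combine(
            EchoSet(echoes=echoes, echo_times=[10, 20, 30])
        )
        assert np.allclose(combined.data, data, rtol=1e-9)
        assert np.allclose(w.weights.sum(axis=-1), 1.0)

    def test_single_echo_rejected(self, small_grid):
        e = Volume4D(grid=small_grid, data=np.ones((8, 8, 6, 5)))
        with pytest.raises(ValueError):
            pre.fit_t2star_and_combine(EchoSet(echoes=[e], echo_times=[30.0]))

    def test_oc_cnr_not_worse_than_best_echo(self):
        """Optimal combination should match or beat every single echo's
        contrast-to-noise for matched noise (fixed seed)."""
        from fmripipe.synth import make_phantom

        rng = np.random.default_rng(77)
        es, truth = make_phantom(
            dims=(14, 14, 10), n_volumes=40, echo_times=(12.5, 27.6, 42.7),
            noise_tsnr=0, drift_percent=0, seed=8,
        )
        # plant a common 1% fluctuation and equal absolute noise per echo
        sig = np.sin(2 * np.pi * np.arange(40) / 10.0)
        base_gm = es.echoes[0].data[truth.tissue_mask == 2].mean()
        noisy = []
        for e in es.echoes:
            d = e.data * (1.0 + 0.01 * sig)
            d = d + rng.normal(0, 0.005 * base_gm, d.shape)
            noisy.append(e.with_data(d))
        es2 = EchoSet(echoes=noisy, echo_times=list(es.echo_times))
        combined, _ = pre.fit_t2star_and_combine(es2)

        def cnr(vol):
            series = vol.data[truth.tissue_mask == 2]
            amp = np.abs((series * sig).sum(axis=1) / (sig**2).sum())
            resid = series - series.mean(axis=1, keepdims=True)
            resid = resid - np.outer(
                (resid * sig).sum(axis=1) / (sig**2).sum(), sig
            )
            return float(np.median(amp / resid.std(axis=1)))

        assert cnr(combined) >= max(cnr(e) for e in noisy) * 0.999


class TestDespike:
    def test_large_spike_reduced_small_signal_kept(self, rng, small_grid):
        data = 100.0 + rng.standard_normal((8, 8, 6, 40))
        data[4, 4, 3, 20] += 50.0
        v = Volume4D(grid=small_grid, data=data)
        out = pre.despike(v)
        assert out.data[4, 4, 3, 20] < data[4, 4, 3, 20] - 30
        untouched = np.abs(out.data - data) < 1e-9
        assert untouched.mean() > 0.9
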