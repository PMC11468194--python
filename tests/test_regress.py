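"""Regression block: bases, event/nuisance regressors, censoring, GLM, DF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmripipe import regress as reg
from fmripipe.types import (
    CensorSeries,
    Event,
    Grid,
    MotionParams,
    ROILabelVolume,
    StimClass,
    TimingSet,
    Volume4D,
)


class TestSampleBasis:
    def test_dmublock_unit_duration_peaks_at_one(self):
        s = reg.sample_basis(reg.BasisSpec(name="dmUBLOCK", duration=1.0), 0.01, 30.0)
        assert s.max() == pytest.approx(1.0, abs=1e-6)

    def test_gam_peaks_at_one_at_pq(self):
        spec = reg.BasisSpec(name="GAM")
        s = reg.sample_basis(spec, 0.001, 20.0)
        assert s.max() == pytest.approx(1.0, abs=1e-6)
        assert np.argmax(s) * 0.001 == pytest.approx(spec.gam_p * spec.gam_q, abs=0.01)

    def test_tent_partition_of_unity(self):
        s = reg.sample_basis(reg.BasisSpec(name="TENT", tent_b=0, tent_c=12, tent_n=7), 0.1, 12.0)
        assert s.shape[0] == 7
        interior = slice(1, -1)
        assert np.allclose(s.sum(axis=0)[interior], 1.0, atol=1e-9)

    def test_block_amplitude_grows_with_duration(self):
        peaks = [
            reg.sample_basis(reg.BasisSpec(name="BLOCK", duration=d), 0.02, 60.0).max()
            for d in (1, 2, 5, 20)
        ]
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))
        assert peaks[3] > peaks[1]

    def test_csplin_is_tent_alias_and_unknown_rejected(self):
        assert reg.BasisSpec(name="CSPLIN").name == "TENT"
        with pytest.raises(ValueError):
            reg.BasisSpec(name="WAV")


def one_class_timing(events, label="task", n_runs=1):
    runs = [[] for _ in range(n_runs)]
    runs[0] = events
    return TimingSet(stim_classes=[StimClass(label=label, runs=runs)])


class TestEventRegressors:
    def test_im_gives_one_column_per_event(self):
        ts = one_class_timing([Event(onset=10.0 * k) for k in range(5)])
        cols, labels = reg.event_regressors(
            ts, "task", reg.BasisSpec(name="GAM"), "IM", run_lengths=[60], tr=2.0
        )
        assert cols.shape[1] == 5
        assert len(labels) == 5

    def test_am2_equal_modulators_give_zero_column(self):
        ts = one_class_timing([Event(onset=10.0 * k, modulators=[3.0]) for k in range(4)])
        with pytest.warns(UserWarning, match="zero variance"):
            cols, labels = reg.event_regressors(
                ts, "task", reg.BasisSpec(name="GAM"), "AM2", run_lengths=[60], tr=2.0
            )
        assert cols.shape[1] == 2
        assert np.allclose(cols[:, 1], 0.0)

    def test_am1_scales_by_modulator(self):
        ts1 = one_class_timing([Event(onset=8.0, modulators=[2.0])])
        ts2 = one_class_timing([Event(onset=8.0, modulators=[1.0])])
        c2, _ = reg.event_regressors(ts1, "task", reg.BasisSpec(name="GAM"), "AM1",
                                     run_lengths=[40], tr=2.0)
        c1, _ = reg.event_regressors(ts2, "task", reg.BasisSpec(name="GAM"), "AM1",
                                     run_lengths=[40], tr=2.0)
        assert np.allclose(c2, 2.0 * c1)

    def test_dmublock_single_event_peak_near_one(self):
        ts = one_class_timing([Event(onset=0.0, duration=1.0)])
        cols, _ = reg.event_regressors(
            ts, "task", reg.BasisSpec(name="dmUBLOCK"), "time", run_lengths=[30], tr=2.0
        )
        # sampled on the TR=2 volume grid the 4.5 s response peak falls
        # between samples; the sampled maximum sits just below 1
        assert cols.max() == pytest.approx(1.0, abs=0.05)

    def test_duration_modulation_larger_for_longer_events(self):
        long_ts = one_class_timing([Event(onset=0.0, duration=10.0)])
        short_ts = one_class_timing([Event(onset=0.0, duration=1.0)])
        cl, _ = reg.event_regressors(long_ts, "task", reg.BasisSpec(name="dmUBLOCK"),
                                     "time", run_lengths=[40], tr=2.0)
        cs, _ = reg.event_regressors(short_ts, "task", reg.BasisSpec(name="dmUBLOCK"),
                                     "time", run_lengths=[40], tr=2.0)
        assert cl.max() > 1.5 * cs.max()

    def test_event_after_run_end_dropped_with_warning(self):
        ts = one_class_timing([Event(onset=5.0), Event(onset=500.0)])
        with pytest.warns(UserWarning, match="after run end"):
            cols, _ = reg.event_regressors(
                ts, "task", reg.BasisSpec(name="GAM"), "time", run_lengths=[40], tr=2.0
            )
        assert cols.shape == (40, 1)

    def test_am_requires_modulators(self):
        ts = one_class_timing([Event(onset=5.0)])
        with pytest.raises(ValueError, match="modulator"):
            reg.event_regressors(ts, "task", reg.BasisSpec(name="GAM"), "AM1",
                                 run_lengths=[40], tr=2.0)


class TestBandpass:
    def test_predicted_df_loss_standard_bands(self):
        assert reg.bandpass_df_loss(2.0, 0.1) == pytest.approx(0.60)
        assert reg.bandpass_df_loss(1.0, 0.1) == pytest.approx(0.80)

    def test_enumerated_column_count_n200(self):
        cols, labels, loss = reg.bandpass_regressors(200, 2.0, 0.01, 0.1)
        assert cols.shape[1] == 125
        assert loss == pytest.approx(1 - 2 * 2.0 * 0.09)

    def test_column_count_brute_force_any_n(self):
        """Library column count must match direct enumeration of DFT
        frequencies outside the keep band."""
        for n, tr in ((100, 2.0), (137, 1.5), (200, 1.0)):
            cols, _, _ = reg.bandpass_regressors(n, tr, 0.01, 0.1)
            count = 0
            for k in range(1, n // 2 + 1):
                f = k / (n * tr)
                if 0.01 - 1e-12 <= f <= 0.1 + 1e-12:
                    continue
                count += 1 if 2 * k == n else 2
            assert cols.shape[1] == count

    def test_eq1a_agreement_across_lengths(self):
        for n in (100, 200, 500):
            cols, _, loss = reg.bandpass_regressors(n, 2.0, 0.01, 0.1)
            assert abs(cols.shape[1] / n - loss) < 0.05

    def test_regression_equals_fft_band_rejection(self):
        """Projecting out the nuisance sinusoids must equal zeroing the
        out-of-band DFT coefficients — the single-step consistency claim."""
        rng = np.random.default_rng(3)
        n, tr = 120, 2.0
        y = rng.standard_normal(n)
        cols, _, _ = reg.bandpass_regressors(n, tr, 0.01, 0.1)
        x = np.column_stack([np.ones(n), cols])
        resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        spec = np.fft.rfft(y)
        freqs = np.fft.rfftfreq(n, d=tr)
        keep = (freqs >= 0.01 - 1e-12) & (freqs <= 0.1 + 1e-12)
        spec[~keep] = 0.0
        fft_filtered = np.fft.irfft(spec, n)
        assert np.sqrt(np.mean((resid - fft_filtered) ** 2)) < 1e-8

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            reg.bandpass_regressors(100, 2.0, 0.2, 0.1)
        with pytest.raises(ValueError):
            reg.bandpass_regressors(100, 2.0, 0.0, 0.5)  # above Nyquist


class TestMotionRegressors:
    def test_demean_plus_deriv_is_twelve_columns(self):
        mp = MotionParams(np.random.default_rng(0).random((30, 6)))
        cols, labels = reg.motion_regressors(mp)
        assert cols.shape[1] == 12

    def test_per_run_two_runs_gives_24(self):
        mp = MotionParams(np.random.default_rng(0).random((30, 6)))
        cols, _ = reg.motion_regressors(mp, per_run=True, run_lengths=[15, 15])
        assert cols.shape[1] == 24
        # block-diagonal: first-run columns vanish in run 2
        assert np.allclose(cols[15:, :6], 0.0)

    def test_zero_motion_gives_zero_columns(self):
        mp = MotionParams(np.zeros((20, 6)))
        cols, _ = reg.motion_regressors(mp)
        assert np.allclose(cols, 0.0)

    def test_deriv_first_volume_of_each_run_zero(self):
        mp = MotionParams(np.random.default_rng(1).random((20, 6)))
        cols, _ = reg.motion_regressors(mp, types=("deriv",), run_lengths=[10, 10])
        assert np.allclose(cols[0], 0) and np.allclose(cols[10], 0)


class TestBaseline:
    def test_polort_zero_single_constant(self):
        cols, _ = reg.baseline_regressors([20], 2.0, 0)
        assert cols.shape == (20, 1)
        assert np.allclose(cols, 1.0)

    def test_auto_rule_300s_run(self):
        cols, _ = reg.baseline_regressors([150], 2.0, "auto")  # 300 s -> polort 3
        assert cols.shape[1] == 4

    def test_within_run_orthogonality(self):
        cols, _ = reg.baseline_regressors([101], 2.0, 3)
        gram = cols.T @ cols
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-10


class TestRoiPC:
    def test_planted_component_recovered(self, rng):
        g = Grid.isotropic((10, 10, 8), 3.0)
        labels = np.zeros((10, 10, 8), int)
        labels[2:8, 2:8, 2:6] = 1
        roi = ROILabelVolume(grid=g, labels=labels, label_table={1: "wm"})
        planted = np.sin(np.arange(40) / 3.0)
        data = 0.01 * rng.standard_normal((10, 10, 8, 40))
        data[labels == 1] += np.outer(rng.random((labels == 1).sum()), planted)
        vol = Volume4D(grid=g, data=data)
        cols, _ = reg.roi_pc_regressors(vol, roi, 1, k=1)
        corr = np.corrcoef(cols[:, 0], planted)[0, 1]
        assert abs(corr) > 0.99

    def test_columns_orthonormal(self, rng):
        g = Grid.isotropic((10, 10, 8), 3.0)
        labels = np.zeros((10, 10, 8), int)
        labels[2:8, 2:8, 2:6] = 1
        roi = ROILabelVolume(grid=g, labels=labels)
        vol = Volume4D(grid=g, data=rng.standard_normal((10, 10, 8, 30)))
        cols, _ = reg.roi_pc_regressors(vol, roi, 1, k=3)
        assert np.allclose(cols.T @ cols, np.eye(3), atol=1e-8)

    def test_roi_vanishing_under_erosion_rejected(self, rng):
        g = Grid.isotropic((10, 10, 8), 3.0)
        labels = np.zeros((10, 10, 8), int)
        labels[5, 5, 4] = 2  # single voxel erodes away
        roi = ROILabelVolume(grid=g, labels=labels, label_table={2: "thin"})
        vol = Volume4D(grid=g, data=rng.standard_normal((10, 10, 8, 30)))
        with pytest.raises(ValueError, match="thin|2"):
            reg.roi_pc_regressors(vol, roi, 2, k=1)


class TestEnormAndCensor:
    def test_constant_parameters_zero(self):
        assert np.allclose(reg.enorm_series(MotionParams(np.ones((10, 6)))), 0.0)

    def test_single_parameter_step(self):
        p = np.zeros((6, 6))
        p[3:, 1] = 0.3
        e = reg.enorm_series(MotionParams(p))
        assert e[3] == pytest.approx(0.3)
        assert np.allclose(np.delete(e, 3), 0.0)

    def test_mixed_step_norm(self):
        p = np.zeros((4, 6))
        p[2:] = [0.1, 0.2, 0.2, 0, 0, 0]
        e = reg.enorm_series(MotionParams(p))
        assert e[2] == pytest.approx(0.3)

    def test_cross_run_difference_suppressed(self):
        p = np.zeros((8, 6))
        p[4:, 3] = 5.0  # jump exactly at the run boundary
        e = reg.enorm_series(MotionParams(p), run_lengths=[4, 4])
        assert e[4] == 0.0

    def test_both_time_points_censored_for_motion(self):
        enorm = np.array([0, 0, 0, 0.35, 0, 0], dtype=float)
        c = reg.build_censor(enorm, np.zeros(6), 0.3, 0.05)
        assert list(np.flatnonzero(~c.keep)) == [2, 3]

    def test_outlier_censors_single_volume(self):
        c = reg.build_censor(np.zeros(3), np.array([0.01, 0.06, 0.02]), 0.3, 0.05)
        assert list(np.flatnonzero(~c.keep)) == [1]

    def test_no_suprathreshold_keeps_all(self):
        c = reg.build_censor(np.full(5, 0.1), np.full(5, 0.01), 0.3, 0.05)
        assert c.keep.all()


class TestDesignAndGLM:
    def _toy_design(self, n=40, censor=None):
        rng = np.random.default_rng(9)
        base, bl = reg.baseline_regressors([n], 2.0, 1)
        stim = rng.standard_normal((n, 1))
        return reg.assemble_design(
            [(base, bl, "baseline"), (stim, ["task"], "stim:task")], censor=censor
        )

    def test_total_columns_conserved(self):
        X = self._toy_design()
        assert X.columns.shape[1] == 3

    def test_censored_rows_removed_from_solve(self):
        keep = np.ones(220, bool)
        keep[[50, 51]] = False
        censor = CensorSeries(keep, np.zeros(220), np.zeros(220))
        base, bl = reg.baseline_regressors([220], 2.0, 1)
        X = reg.assemble_design([(base, bl, "baseline")], censor=censor)
        g = Grid.isotropic((4, 4, 3), 3.0)
        vol = Volume4D(grid=g, data=np.random.default_rng(0).random((4, 4, 3, 220)))
        res = reg.fit_glm(vol, X)
        assert res.df == 218 - 2  # 218 rows minus 2 baseline columns

    def test_duplicate_labels_rejected(self):
        base, bl = reg.baseline_regressors([20], 2.0, 0)
        with pytest.raises(ValueError, match="duplicate"):
            reg.assemble_design(
                [(base, bl, "baseline"), (base, bl, "baseline2")]
            )

    def test_noiseless_recovery_and_residual_orthogonality(self):
        rng = np.random.default_rng(4)
        n = 60
        g = Grid.isotropic((4, 4, 3), 3.0)
        base, bl = reg.baseline_regressors([n], 2.0, 1)
        stim = rng.standard_normal((n, 1))
        X = reg.assemble_design([(base, bl, "baseline"), (stim, ["task"], "stim:task")])
        true_beta = np.array([100.0, 2.0, 1.2])
        y = X.columns @ true_beta
        vol = Volume4D(grid=g, data=np.broadcast_to(y, (4, 4, 3, n)).copy())
        res = reg.fit_glm(vol, X)
        assert np.allclose(res.betas[0, 0, 0], true_beta, atol=1e-8)
        r = res.errts.data[0, 0, 0]
        assert np.abs(X.columns.T @ r).max() < 1e-6 * np.linalg.norm(y)

    def test_ar1_on_white_noise_matches_ols(self):
        rng = np.random.default_rng(5)
        n = 200
        g = Grid.isotropic((5, 5, 4), 3.0)
        base, bl = reg.baseline_regressors([n], 2.0, 1)
        stim = rng.standard_normal((n, 1))
        X = reg.assemble_design([(base, bl, "baseline"), (stim, ["task"], "stim:task")])
        data = 1.0 * rng.standard_normal((5, 5, 4, n))
        vol = Volume4D(grid=g, data=data)
        ols = reg.fit_glm(vol, X, whiten="none")
        gls = reg.fit_glm(vol, X, whiten="ar1")
        assert abs(gls.rho) < 0.05
        assert np.allclose(gls.betas, ols.betas, atol=0.02)

    def test_ar1_reduces_sigma_for_correlated_noise(self):
        rng = np.random.default_rng(6)
        n, rho = 300, 0.6
        g = Grid.isotropic((4, 4, 2), 3.0)
        noise = np.zeros((32, n))
        e = rng.standard_normal((32, n))
        for t in range(1, n):
            noise[:, t] = rho * noise[:, t - 1] + e[:, t]
        base, bl = reg.baseline_regressors([n], 2.0, 0)
        X = reg.assemble_design([(base, bl, "baseline")])
        vol = Volume4D(grid=g, data=noise.reshape(4, 4, 2, n))
        gls = reg.fit_glm(vol, X, whiten="ar1")
        assert gls.rho == pytest.approx(rho, abs=0.1)

    def test_rank_deficiency_names_columns(self):
        n = 30
        base, bl = reg.baseline_regressors([n], 2.0, 0)
        col = np.arange(n, dtype=float)[:, None]
        X = reg.assemble_design(
            [(base, bl, "baseline"), (col, ["a"], "stim:a"), (col.copy(), ["b"], "stim:b")]
        )
        g = Grid.isotropic((2, 2, 2), 3.0)
        vol = Volume4D(grid=g, data=np.zeros((2, 2, 2, n)))
        with pytest.raises(ValueError, match="rank deficient"):
            reg.fit_glm(vol, X)

    def test_slicewise_columns_solved_per_slice(self):
        """Each slice must be solved with its own physio columns."""
        rng = np.random.default_rng(8)
        n, nz = 80, 3
        g = Grid.isotropic((4, 4, nz), 3.0)
        sw = np.zeros((n, 1, nz))
        for z in range(nz):
            sw[:, 0, z] = np.sin(np.arange(n) / 5.0 + z * 2.0)
        data = 0.01 * rng.standard_normal((4, 4, nz, n))
        for z in range(nz):
            data[:, :, z, :] += 3.0 * sw[:, 0, z]
        base, bl = reg.baseline_regressors([n], 2.0, 0)
        X = reg.assemble_design(
            [(base, bl, "baseline")], slicewise=sw, slicewise_labels=["card1"]
        )
        vol = Volume4D(grid=g, data=data)
        res = reg.fit_glm(vol, X)
        # slicewise beta ~ 3 in every slice, residuals tiny
        assert np.allclose(res.betas[..., -1], 3.0, atol=0.05)
        assert res.errts.data.std() < 0.05


class TestLinearTest:
    def _fit(self):
        rng = np.random.default_rng(11)
        n = 80
        g = Grid.isotropic((3, 3, 2), 3.0)
        base, bl = reg.baseline_regressors([n], 2.0, 0)
        s1 = rng.standard_normal((n, 1))
        s2 = rng.standard_normal((n, 1))
        X = reg.assemble_design(
            [(base, bl, "baseline"), (s1, ["task"], "stim:task"), (s2, ["control"], "stim:control")]
        )
        y = 10.0 + 3.0 * s1[:, 0] + 1.0 * s2[:, 0]
        vol = Volume4D(grid=g, data=np.broadcast_to(y, (3, 3, 2, n)).copy())
        return reg.fit_glm(vol, X)

    def test_difference_and_mean_contrasts(self):
        res = self._fit()
        diff = reg.linear_test(res, {"task": 1.0, "control": -1.0}, "task-control")
        mean = reg.linear_test(res, {"task": 0.5, "control": 0.5}, "mean")
        assert diff["estimate"][0, 0, 0] == pytest.approx(2.0, abs=1e-8)
        assert mean["estimate"][0, 0, 0] == pytest.approx(2.0, abs=1e-8)

    def test_multi_row_gives_f(self):
        res = self._fit()
        out = reg.linear_test(res, [{"task": 1.0}, {"control": 1.0}], "both")
        assert out["kind"] == "F"
        assert np.all(out["stat"] >= 0)

    def test_unknown_label_and_zero_weights_rejected(self):
        res = self._fit()
        with pytest.raises(KeyError):
            reg.linear_test(res, {"nope": 1.0}, "bad")
        with pytest.raises(ValueError):
            reg.linear_test(res, {"task": 0.0}, "zero")


class TestDFLedger:
    def test_bookkeeping_example(self):
        n = 220
        keep = np.ones(n, bool)
        keep[:2] = False
        censor = CensorSeries(keep, np.zeros(n), np.zeros(n))
        rng = np.random.default_rng(0)
        parts = [
            (rng.random((n, 4)), [f"b{i}" for i in range(4)], "baseline"),
            (rng.random((n, 12)), [f"m{i}" for i in range(12)], "motion"),
            (rng.random((n, 13)), [f"p{i}" for i in range(13)], "physio"),
        ]
        led = reg.compute_df_ledger(reg.assemble_design(parts, censor=censor))
        assert led.df_remaining == 220 - 2 - 4 - 12 - 13
        assert led.df_remaining == 189
        assert led.n_total == led.n_censored + sum(led.df_used.values()) + led.df_remaining

    def test_bandpass_plus_nuisance_triggers_df_warning(self):
        """Standard-band bandpassing at TR = 2 s consumes ~60% of the DFs;
        with the usual motion and physio regressors on top, the ledger must
        raise its low-remaining-DF warning."""
        n = 200
        rng = np.random.default_rng(1)
        cols, labels, _ = reg.bandpass_regressors(n, 2.0, 0.01, 0.1)
        base, bl = reg.baseline_regressors([n], 2.0, 1)
        X = reg.assemble_design([
            (base, bl, "baseline"),
            (cols, labels, "bandpass"),
            (rng.random((n, 12)), [f"m{i}" for i in range(12)], "motion"),
            (rng.random((n, 13)), [f"p{i}" for i in range(13)], "physio"),
        ])
        led = reg.compute_df_ledger(X)
        assert led.df_used["bandpass"] == pytest.approx(0.60 * n, rel=0.1)
        assert led.warn_level in ("medium", "severe")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(30, 300),
        n_cens=st.integers(0, 10),
        n_mot=st.integers(0, 12),
    )
    def test_ledger_identity_property(self, n, n_cens, n_mot):
        keep = np.ones(n, bool)
        keep[:n_cens] = False
        censor = CensorSeries(keep, np.zeros(n), np.zeros(n))
        rng = np.random.default_rng(0)
        parts = [(np.ones((n, 1)), ["b0"], "baseline")]
        if n_mot:
            parts.append((rng.random((n, n_mot)), [f"m{i}" for i in range(n_mot)], "motion"))
        led = reg.compute_df_ledger(reg.assemble_design(parts, censor=censor))
        assert led.n_total == led.n_censored + sum(led.df_used.values()) + led.df_remaining
        assert sum(led.fractions.values()) == pytest.approx(1.0)


class TestDesignWarnings:
    def test_duplicated_stim_column_flags_severe(self):
        n = 50
        rng = np.random.default_rng(2)
        col = rng.standard_normal((n, 1))
        base, bl = reg.baseline_regressors([n], 2.0, 0)
        X = reg.assemble_design(
            [(base, bl, "baseline"), (col, ["a"], "stim:a"), (col.copy(), ["b"], "stim:b")]
        )
        warns = reg.design_warnings(X)
        assert any(w.check == "collinearity" and w.level == "severe" for w in warns)

    def test_censoring_inside_one_class_flagged(self):
        n, tr = 100, 2.0
        events = [Event(onset=20.0), Event(onset=60.0), Event(onset=120.0)]
        ts = one_class_timing(events)
        keep = np.ones(n, bool)
        for ev in events:  # censor right on top of every event response
            lo = int(ev.onset / tr)
            keep[lo : lo + 3] = False
        censor = CensorSeries(keep, np.zeros(n), np.zeros(n))
        base, bl = reg.baseline_regressors([n], tr, 0)
        cols, labels = reg.event_regressors(ts, "task", reg.BasisSpec(name="GAM"),
                                            "time", run_lengths=[n], tr=tr)
        X = reg.assemble_design(
            [(base, bl, "baseline"), (cols, labels, "stim:task")], censor=censor
        )
        warns = reg.design_warnings(X, ts, tr=tr)
        assert any(w.check == "stim_censor_overlap" for w in warns)

    def test_clean_design_has_no_warnings(self):
        n = 100
        rng = np.random.default_rng(3)
        base, bl = reg.baseline_regressors([n], 2.0, 1)
        s1 = rng.standard_normal((n, 1))
        X = reg.assemble_design([(base, bl, "baseline"), (s1, ["a"], "stim:a")])
        assert reg.design_warnings(X) == []
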