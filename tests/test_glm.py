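"""HRF, drift basis, design construction, AR(1) fitting, slope extraction,
second-level tests and subsidiary models."""

import numpy as np
import pandas as pd
import pytest

import stressrl as s
from stressrl.cohort import EffectSpec, cohort_bold, generate_cohort, n_scans_for_run
from stressrl.glm import (
    DesignMatrix,
    GLMFit,
    boundary_comparison,
    build_design,
    canonical_hrf,
    first_level_slopes,
    fit_ar1_glm,
    highpass_dct,
    quartile_bins,
    responsivity_correlation,
    second_level_tests,
    sign_split_anova,
    subsidiary_bins,
    subsidiary_sign,
)


class TestCanonicalHrf:
    def test_peak_near_five_seconds_on_dense_grid(self):
        h = canonical_hrf(0.1)
        assert abs(0.1 * np.argmax(h) - 5.0) < 0.5

    def test_zero_at_origin_and_unit_peak(self):
        h = canonical_hrf(2.0)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_has_post_peak_undershoot(self):
        h = canonical_hrf(0.5)
        assert h.min() < 0
        assert 0.5 * np.argmin(h) > 5.0

    def test_matches_nilearn_spm_shape(self):
        nilearn_glm = pytest.importorskip("nilearn.glm.first_level")
        ref = nilearn_glm.spm_hrf(0.1, oversampling=1)
        h = canonical_hrf(0.1)
        n = min(len(h), len(ref))
        r = np.corrcoef(h[:n], ref[:n])[0, 1]
        assert r > 0.999

    def test_unit_stick_reproduces_shifted_kernel(self):
        h = canonical_hrf(2.0)
        stick = np.zeros(40)
        stick[7] = 1.0
        conv = np.convolve(stick, h)[:40]
        np.testing.assert_allclose(conv[7 : 7 + len(h)], h[: 40 - 7])
        assert np.all(conv[:7] == 0)

    def test_invalid_tr_rejected(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestHighpassDct:
    def test_linear_drift_removed(self):
        n, tr = 200, 2.0
        basis = highpass_dct(n, tr)
        drift = np.linspace(0, 5, n)
        X = np.column_stack([np.ones(n), basis])
        resid = drift - X @ np.linalg.lstsq(X, drift, rcond=None)[0]
        assert resid.var() < 0.01 * drift.var()

    def test_fast_sinusoid_preserved(self):
        n, tr = 200, 2.0
        basis = highpass_dct(n, tr)
        t = np.arange(n) * tr
        sig = np.sin(2 * np.pi * t / 20.0)
        X = np.column_stack([np.ones(n), basis])
        resid = sig - X @ np.linalg.lstsq(X, sig, rcond=None)[0]
        assert resid.var() > 0.95 * sig.var()

    def test_constant_fully_captured_by_intercept(self):
        n = 100
        basis = highpass_dct(n, 2.0)
        X = np.column_stack([np.ones(n), basis])
        const = np.full(n, 3.7)
        resid = const - X @ np.linalg.lstsq(X, const, rcond=None)[0]
        assert np.abs(resid).max() < 1e-10

    def test_order_scales_with_duration(self):
        assert highpass_dct(64, 2.0).shape[1] == 2  # 128 s of data
        assert highpass_dct(256, 2.0).shape[1] == 8

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            highpass_dct(1, 2.0)


@pytest.fixture(scope="module")
def one_participant(small_cohort):
    coh, bold = small_cohort
    p = coh.participants[0]
    return p, bold[p.participant_id]


class TestBuildDesign:
    def test_expected_columns_present(self, one_participant):
        p, bold = one_participant
        trials = p.trials[p.trials.run == 1]
        trace = p.trace[p.trace.run == 1]
        d = build_design(trials, trace, 2.0, len(bold[1]))
        names = set(d.frame.columns)
        for cond in ("stress", "control"):
            for val in ("gain", "loss"):
                assert {f"stim:{cond}:{val}", f"out:{cond}:{val}",
                        f"q:{cond}:{val}", f"pe:{cond}:{val}"} <= names
            assert f"stim:{cond}:neutral" in names
        assert "const" in names and "drift:1" in names

    def test_single_cell_run_omits_absent_columns(self):
        from conftest import toy_trials

        trials = toy_trials(
            [("p1", "gain", "correct", 0.5), ("p1", "gain", "incorrect", 0.0)]
        )
        trace = s.trace_from_choices(trials, s.RLParams(0.5, 0.5, 2.0))
        d = build_design(trials, trace, 2.0, 40)
        assert "stim:control:gain" in d.frame.columns
        assert "pe:control:gain" in d.frame.columns
        assert "stim:stress:gain" in d.omitted
        assert "out:control:loss" in d.omitted

    def test_constant_modulator_flagged_and_left_out(self):
        from conftest import toy_trials

        # zero learning rate keeps Q at 0 -> Q modulator constant
        trials = toy_trials(
            [("p1", "gain", "correct", 0.5)] * 4
        )
        trace = s.trace_from_choices(trials, s.RLParams(0.0, 0.0, 2.0))
        d = build_design(trials, trace, 2.0, 40)
        assert "q:control:gain" in d.flagged
        assert "q:control:gain" not in d.frame.columns

    def test_event_beyond_run_end_rejected(self, one_participant):
        p, bold = one_participant
        trials = p.trials[p.trials.run == 1]
        trace = p.trace[p.trace.run == 1]
        with pytest.raises(ValueError, match="outside"):
            build_design(trials, trace, 2.0, 10)

    def test_trace_mismatch_rejected(self, one_participant):
        p, bold = one_participant
        trials = p.trials[p.trials.run == 1]
        trace = p.trace[p.trace.run == 1].iloc[:-2]
        with pytest.raises(ValueError, match="trace length"):
            build_design(trials, trace, 2.0, len(bold[1]))

    def test_known_coefficients_recovered_within_three_se(self, one_participant):
        p, _ = one_participant
        trials = p.trials[p.trials.run == 1]
        trace = p.trace[p.trace.run == 1]
        n_scans = n_scans_for_run(trials)
        d = build_design(trials, trace, 2.0, n_scans)
        rng = np.random.default_rng(0)
        b_true = rng.normal(0, 1, d.frame.shape[1])
        y = d.frame.to_numpy() @ b_true + rng.normal(0, 1, n_scans)
        fit = fit_ar1_glm(y, d)
        z = (fit.beta.to_numpy() - b_true) / np.sqrt(fit.beta_var.to_numpy())
        assert np.abs(z).max() < 3.5


class TestAr1Glm:
    def _simple_design(self, n):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(
            {"x1": rng.normal(size=n), "x2": rng.normal(size=n), "const": 1.0}
        )
        return DesignMatrix(frame=frame, tr=2.0)

    def test_white_noise_gives_near_zero_rho_and_ols_betas(self):
        n = 400
        d = self._simple_design(n)
        rng = np.random.default_rng(2)
        y = d.frame.to_numpy() @ np.array([1.0, -2.0, 5.0]) + rng.normal(size=n)
        fit = fit_ar1_glm(y, d)
        ols = np.linalg.lstsq(d.frame.to_numpy(), y, rcond=None)[0]
        assert abs(fit.rho) < 0.1
        np.testing.assert_allclose(fit.beta.to_numpy(), ols, atol=0.05)

    def test_ar1_coefficient_recovered(self):
        n, rho = 400, 0.4
        d = self._simple_design(n)
        rng = np.random.default_rng(3)
        eps = rng.normal(0, np.sqrt(1 - rho**2), n)
        noise = np.empty(n)
        acc = rng.normal()
        for i in range(n):
            acc = rho * acc + eps[i]
            noise[i] = acc
        y = d.frame.to_numpy() @ np.array([1.0, 1.0, 0.0]) + noise
        fit = fit_ar1_glm(y, d)
        assert abs(fit.rho - rho) < 0.1
        assert abs(fit.whitened_lag1) < 0.05

    def test_whitened_residuals_decorrelated_on_roi_fixture(self, one_participant):
        p, bold = one_participant
        trials = p.trials[p.trials.run == 1]
        trace = p.trace[p.trace.run == 1]
        d = build_design(trials, trace, 2.0, len(bold[1]))
        fit = fit_ar1_glm(bold[1], d)
        assert fit.rho > 0.05  # generator injects rho = 0.3
        assert abs(fit.whitened_lag1) < 0.05

    def test_rank_deficient_design_names_columns(self):
        n = 100
        rng = np.random.default_rng(4)
        x = rng.normal(size=n)
        frame = pd.DataFrame({"a": x, "b": 2 * x, "const": 1.0})
        d = DesignMatrix(frame=frame, tr=2.0)
        with pytest.raises(ValueError, match="collinear"):
            fit_ar1_glm(rng.normal(size=n), d)

    def test_noise_free_data_fits_exactly(self):
        n = 120
        d = self._simple_design(n)
        y = d.frame.to_numpy() @ np.array([0.5, 1.5, -1.0])
        fit = fit_ar1_glm(y, d)
        np.testing.assert_allclose(
            fit.beta.to_numpy(), [0.5, 1.5, -1.0], atol=1e-8
        )
        assert fit.rho == 0.0


class TestSlopesAndSecondLevel:
    @staticmethod
    def _fake_fit(pe_values, var=1.0):
        names = [f"pe:{c}:{v}" for c, v in
                 (("stress", "gain"), ("stress", "loss"),
                  ("control", "gain"), ("control", "loss"))]
        return GLMFit(
            beta=pd.Series(pe_values, index=names),
            beta_var=pd.Series(var, index=names),
            rho=0.0, sigma2=1.0, dof=10, whitened_lag1=0.0,
        )

    def test_equal_variances_reduce_to_simple_mean(self):
        fits = {1: self._fake_fit([1.0, 2.0, 3.0, 4.0]),
                2: self._fake_fit([3.0, 4.0, 5.0, 6.0])}
        slopes = first_level_slopes(fits, participant=7)
        got = slopes.set_index(["condition", "valence"])["slope"]
        assert got[("stress", "gain")] == pytest.approx(2.0)
        assert got[("control", "loss")] == pytest.approx(5.0)

    def test_inverse_variance_weighting(self):
        fits = {1: self._fake_fit([0.0] * 4, var=1.0),
                2: self._fake_fit([1.0] * 4, var=3.0)}
        slopes = first_level_slopes(fits, participant=0)
        # weights 1 and 1/3 -> weighted mean 0.25
        assert slopes["slope"].iloc[0] == pytest.approx(0.25)

    def test_cell_absent_from_all_runs_flagged(self):
        fit = GLMFit(
            beta=pd.Series({"pe:control:gain": 1.0}),
            beta_var=pd.Series({"pe:control:gain": 1.0}),
            rho=0.0, sigma2=1.0, dof=10, whitened_lag1=0.0,
        )
        slopes = first_level_slopes({1: fit}, participant=0)
        row = slopes.set_index(["condition", "valence"]).loc[("stress", "gain")]
        assert bool(row["absent"]) and np.isnan(row["slope"])

    def test_second_level_detects_constructed_blunting(self):
        rng = np.random.default_rng(5)
        rows = []
        for pid in range(20):
            base = rng.normal(1.0, 0.2)
            for cond, scale in (("control", 1.0), ("stress", 0.3)):
                for val in ("gain", "loss"):
                    rows.append(
                        {
                            "participant": pid,
                            "condition": cond,
                            "valence": val,
                            "slope": base * scale + rng.normal(0, 0.1),
                        }
                    )
        tests = second_level_tests(pd.DataFrame(rows)).set_index("test")
        main = tests.loc["main_effect_control_gt_stress"]
        assert main["estimate"] > 0 and main["p"] < 1e-6
        assert tests.loc["condition_x_valence_interaction", "p"] > 0.01
        assert tests.loc["one_sample:control:gain", "p"] < 1e-6

    def test_too_few_participants_rejected(self):
        rows = [
            {"participant": p, "condition": c, "valence": v, "slope": 1.0}
            for p in range(2)
            for c in ("stress", "control")
            for v in ("gain", "loss")
        ]
        with pytest.raises(ValueError, match=">= 3 participants"):
            second_level_tests(pd.DataFrame(rows))


class TestQuartileBins:
    def test_eight_distinct_values_split_two_per_bin(self):
        delta = np.array([0.4, -0.2, 0.1, 0.3, -0.4, 0.2, -0.1, -0.3])
        labels, bounds = quartile_bins(delta)
        assert sorted(np.bincount(labels)[1:]) == [2, 2, 2, 2]
        # lowest two deltas end in bin 1, highest two in bin 4
        assert set(labels[np.argsort(delta)[:2]]) == {1}
        assert set(labels[np.argsort(delta)[-2:]]) == {4}
        assert bounds[0] < bounds[1] < bounds[2]

    def test_ties_never_empty_a_bin(self):
        delta = np.array([0.5] * 10 + [-0.5] * 2)
        labels, _ = quartile_bins(delta)
        assert set(labels) == {1, 2, 3, 4}
        sizes = np.bincount(labels)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_fewer_than_four_trials_rejected(self):
        with pytest.raises(ValueError):
            quartile_bins(np.array([0.1, 0.2, 0.3]))


class TestSubsidiaryModels:
    def test_bin_estimates_track_linear_modulation(self, small_cohort):
        # in the control condition the generator couples BOLD linearly to
        # delta with slope ~1, so group-mean bin estimates must increase
        coh, bold = small_cohort
        frames = []
        for p in coh.participants:
            est, _ = subsidiary_bins(
                p.trials, p.trace, bold[p.participant_id], 2.0,
                p.participant_id,
            )
            frames.append(est)
        est = pd.concat(frames)
        means = (
            est[est.condition == "control"]
            .groupby("bin")["estimate"]
            .mean()
        )
        assert means.is_monotonic_increasing

    def test_boundary_comparison_flags_degenerate_and_runs_paired_t(self):
        rows = []
        for pid in range(6):
            for cond in ("stress", "control"):
                for val in ("gain", "loss"):
                    rows.append(
                        {
                            "participant": pid,
                            "condition": cond,
                            "valence": val,
                            "q25": -0.2 if val == "gain" else -0.2,
                            "q50": 0.0,
                            "q75": 0.2 + (0.05 * pid if cond == "stress" and val == "gain" else 0),
                        }
                    )
        out = boundary_comparison(pd.DataFrame(rows))
        gain_q25 = out[(out.valence == "gain") & (out.boundary == "q25")].iloc[0]
        assert bool(gain_q25["degenerate"])  # identical in both conditions
        gain_q75 = out[(out.valence == "gain") & (out.boundary == "q75")].iloc[0]
        assert not gain_q75["degenerate"] and gain_q75["mean_diff"] > 0

    def test_sign_split_interaction_under_positive_only_blunting(self):
        spec = EffectSpec(
            n_participants=8, seed=11, blunt_positive_only=True, blunting=0.0
        )
        coh = generate_cohort(spec)
        bold = cohort_bold(coh)
        frames = [
            subsidiary_sign(
                p.trials, p.trace, bold[p.participant_id], 2.0,
                p.participant_id,
            )
            for p in coh.participants
        ]
        res = sign_split_anova(pd.concat(frames))
        aov = res["anova"].set_index("effect")
        assert aov.loc["condition:pe_sign", "p"] < 0.05
        paired = res["paired"].set_index(["valence", "pe_sign"])
        assert paired.loc[("gain", "pos"), "mean_diff"] < 0

    def test_identical_paired_samples_flag_degenerate_d(self):
        rows = []
        for pid in range(5):
            for cond in ("stress", "control"):
                for val in ("gain", "loss"):
                    for sign in ("pos", "neg"):
                        rows.append(
                            {
                                "participant": pid,
                                "condition": cond,
                                "valence": val,
                                "pe_sign": sign,
                                "estimate": float(pid),  # no condition diff
                            }
                        )
        res = sign_split_anova(pd.DataFrame(rows))
        assert res["paired"]["degenerate"].all()
        assert np.isnan(res["paired"]["cohens_d"]).all()


class TestResponsivity:
    def test_perfect_monotone_decreasing_gives_minus_one(self):
        slopes = pd.DataFrame(
            {
                "participant": range(6),
                "condition": "stress",
                "valence": "gain",
                "slope": [6, 5, 4, 3, 2, 1],
            }
        )
        delta = pd.Series([1, 2, 3, 4, 5, 6], index=range(6))
        res = responsivity_correlation(slopes, delta)
        assert res["rho"] == pytest.approx(-1.0)

    def test_independent_inputs_near_zero_over_seeds(self):
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            slopes = pd.DataFrame(
                {
                    "participant": range(30),
                    "condition": "stress",
                    "valence": "gain",
                    "slope": rng.normal(size=30),
                }
            )
            delta = pd.Series(rng.normal(size=30), index=range(30))
            rhos.append(responsivity_correlation(slopes, delta)["rho"])
        assert abs(np.mean(rhos)) < 0.15

    def test_constant_input_flagged(self):
        slopes = pd.DataFrame(
            {
                "participant": range(5),
                "condition": "stress",
                "valence": "gain",
                "slope": 1.0,
            }
        )
        delta = pd.Series(np.arange(5.0), index=range(5))
        res = responsivity_correlation(slopes, delta)
        assert res["constant_input"] and np.isnan(res["rho"])

    def test_too_few_pairs_rejected(self):
        slopes = pd.DataFrame(
            {
                "participant": range(3),
                "condition": "stress",
                "valence": "gain",
                "slope": [1.0, 2.0, 3.0],
            }
        )
        delta = pd.Series([1.0, 2.0, 3.0], index=range(3))
        with pytest.raises(ValueError):
            responsivity_correlation(slopes, delta)
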