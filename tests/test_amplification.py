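"""Unit and property tests of the amplification-curve analysis."""

import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ampliquant import (
    AmpSimParams,
    AnalysisConfig,
    PlatePlan,
    WellPlan,
    analyze_amplification,
    call_cq,
    classify_reaction,
    compute_n0,
    detect_amplification,
    detect_efficiency_outliers,
    estimate_baseline,
    find_exponential_phase,
    fit_log_linear,
    generate_synthetic_run,
    iterate_assay,
    optimize_window_of_linearity,
    set_common_threshold,
    simulate_amplification_curve,
)
from ampliquant.amplification import (
    ExponentialPhase,
    PreparedReaction,
    _ols,
    _smooth3,
)
from ampliquant.data import AmplificationCurve
from ampliquant.errors import (
    AnalysisError,
    InsufficientDataError,
    NoAmplificationError,
    UndefinedEfficiencyError,
    WindowInvalidError,
)


def _curve(fluor, well="A1"):
    f = np.asarray(fluor, float)
    return AmplificationCurve(well, "s", "t", np.arange(1, f.size + 1), f)


def _sim_curve(**kwargs):
    curve, truth = simulate_amplification_curve(AmpSimParams(**kwargs))
    return curve, truth


class TestDetectAmplification:
    def test_flat_noise_only_is_not_amplified(self):
        rng = np.random.default_rng(0)
        f = 50.0 * (1.0 + rng.normal(0, 0.01, 40))
        assert detect_amplification(_curve(f)) == "not_amplified"

    def test_full_sigmoid_is_amplified(self):
        curve, _ = _sim_curve(n_cycles=45)
        assert detect_amplification(curve) == "amplified"

    def test_truncation_at_sdm_gives_no_plateau(self):
        curve, truth = _sim_curve(n_cycles=45)
        # brute-force SDM of the noiseless signal
        d2 = np.diff(truth.signal, 2)
        sdm = int(np.argmax(d2)) + 1
        cut = _curve(curve.fluorescence[: sdm + 1])
        assert detect_amplification(cut) == "no_plateau"

    def test_too_few_cycles_raises(self):
        with pytest.raises(InsufficientDataError):
            detect_amplification(_curve(np.ones(9)))


class TestEstimateBaseline:
    def test_recovers_known_baseline_within_half_percent(self):
        c = np.arange(1, 41)
        f = 50.0 + np.minimum(0.01 * 1.9**c, 5000.0)
        fit = estimate_baseline(_curve(f))
        assert fit.status == "ok"
        assert fit.baseline == pytest.approx(50.0, rel=0.005)

    def test_agrees_with_grid_search_oracle(self):
        """Independent oracle: dense scan over baseline candidates maximizing
        the R^2 of the log-linear fit over the exponential window."""
        curve, truth = _sim_curve(n0_true=5e-3, efficiency_true=1.85,
                                  baseline_true=80.0, plateau=6000.0,
                                  n_cycles=45)
        f = curve.fluorescence
        window = truth.signal < truth.plateau / 20.0
        window &= truth.signal > truth.n0_true * 2
        best_b, best_r2 = None, -np.inf
        for b in np.linspace(0.0, f.min() * 0.999, 4000):
            corr = f[window] - b
            if np.any(corr <= 0):
                continue
            _, _, r2 = _ols(curve.cycles[window], np.log10(corr))
            if r2 > best_r2:
                best_b, best_r2 = b, r2
        fit = estimate_baseline(curve)
        assert fit.status == "ok"
        assert fit.baseline == pytest.approx(best_b, abs=max(0.5, 0.005 * best_b))
        assert fit.baseline == pytest.approx(80.0, rel=0.005)

    def test_zero_baseline_curve(self):
        c = np.arange(1, 41)
        f = np.minimum(0.01 * 1.9**c, 5000.0)
        fit = estimate_baseline(_curve(f))
        assert fit.status == "ok"
        assert abs(fit.baseline) < 0.05

    def test_linear_drift_reports_baseline_error(self):
        fit = estimate_baseline(_curve(10.0 + np.arange(1, 41) * 1.0))
        assert fit.status == "baseline_error"


class TestFindExponentialPhase:
    def test_sdm_matches_brute_force_second_differences(self):
        curve, truth = _sim_curve(n_cycles=45)
        corr = curve.fluorescence - truth.baseline
        phase = find_exponential_phase(corr, curve.cycles)
        # brute force on the 3-point smoothed series (cycle = index + 1)
        s = _smooth3(corr)
        d2 = s[2:] - 2 * s[1:-1] + s[:-2]
        assert phase.sdm_cycle == int(np.argmax(d2)) + 2
        assert phase.start_cycle < phase.sdm_cycle
        assert phase.start_cycle <= phase.centre_cycle <= phase.sdm_cycle

    def test_no_plateau_phase_extends_to_last_cycle(self):
        c = np.arange(1, 31)
        corr = 0.01 * 1.9**c
        phase = find_exponential_phase(corr, c, no_plateau=True)
        assert phase.sdm_cycle == 30

    def test_noise_only_raises_no_amplification(self):
        rng = np.random.default_rng(1)
        corr = rng.normal(0, 1.0, 40)
        with pytest.raises(NoAmplificationError):
            find_exponential_phase(corr, np.arange(1, 41))

    def test_centre_lies_on_fitted_line(self):
        curve, truth = _sim_curve(n_cycles=45)
        corr = curve.fluorescence - truth.baseline
        phase = find_exponential_phase(corr, curve.cycles)
        sel = (curve.cycles >= phase.start_cycle) & (curve.cycles <= phase.sdm_cycle)
        slope, intercept, _ = _ols(curve.cycles[sel], np.log10(corr[sel]))
        assert (slope * phase.centre_cycle + intercept
                == pytest.approx(math.log10(phase.centre_fluor), abs=1e-9))


class TestFitLogLinear:
    def test_exact_exponential_recovers_efficiency_exactly(self):
        c = np.arange(1, 41)
        corr = 0.02 * 1.9**c
        for window in [(5, 8), (10, 20), (1, 40)]:
            _, _, eff = fit_log_linear(corr, c, window)
            assert eff == pytest.approx(1.9, rel=1e-12)

    def test_two_cycle_window_rejected(self):
        c = np.arange(1, 41)
        with pytest.raises(WindowInvalidError):
            fit_log_linear(0.02 * 1.9**c, c, (5, 6))

    def test_window_with_zero_value_rejected(self):
        c = np.arange(1, 41)
        corr = 0.02 * 1.9**c
        corr[6] = 0.0
        with pytest.raises(WindowInvalidError):
            fit_log_linear(corr, c, (5, 10))


def _prepared_assay(e, n0s, **kwargs):
    """Simulate one assay and prepare its reactions for W-o-L fitting."""
    prep = {}
    for i, n0 in enumerate(n0s):
        curve, truth = _sim_curve(n0_true=n0, efficiency_true=e,
                                  seed=100 + i, **kwargs)
        fit = estimate_baseline(curve)
        phase = find_exponential_phase(fit.corrected, curve.cycles)
        well = f"W{i:02d}"
        prep[well] = PreparedReaction(well, curve.cycles, fit.corrected, phase)
    return prep


class TestWindowOfLinearity:
    def test_noiseless_replicates_recover_common_efficiency(self):
        prep = _prepared_assay(1.85, [1e-2] * 8, n_cycles=45)
        res = optimize_window_of_linearity(prep, target_id="T")
        assert res.cv < 1e-6
        for e in res.efficiencies.values():
            assert e == pytest.approx(1.85, abs=0.01)

    def test_single_reaction_assay_is_flagged(self):
        prep = _prepared_assay(1.85, [1e-2], n_cycles=45)
        res = optimize_window_of_linearity(prep, target_id="T")
        assert "single_reaction" in res.flags
        assert res.e_tar == pytest.approx(1.85, abs=0.02)

    def test_result_independent_of_well_order(self):
        prep = _prepared_assay(1.8, [1e-2, 1e-4, 1e-6], n_cycles=45)
        res1 = optimize_window_of_linearity(dict(sorted(prep.items())),
                                            target_id="T")
        res2 = optimize_window_of_linearity(
            dict(sorted(prep.items(), reverse=True)), target_id="T")
        assert res1.window == res2.window
        assert res1.efficiencies == res2.efficiencies


class TestEfficiencyOutliers:
    def test_all_equal_all_included(self):
        mask = detect_efficiency_outliers([1.80] * 12)
        assert mask.all()

    def test_grubbs_excludes_planted_high_value(self):
        vals = [1.80] * 11 + [1.95]
        mask = detect_efficiency_outliers(vals, alpha=0.05)
        # independent check of the Grubbs decision for the first pass
        x = np.asarray(vals)
        g = (x.max() - x.mean()) / x.std(ddof=1)
        n = x.size
        t = stats.t.ppf(1 - 0.05 / n, n - 2)
        crit = (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))
        assert g > crit
        assert list(mask) == [True] * 11 + [False]

    def test_fixed_band_excludes_outside_median_band(self):
        vals = [1.70, 1.80, 1.82, 1.84, 1.95]
        mask = detect_efficiency_outliers(vals, mode="fixed_band",
                                          halfwidth=0.05)
        assert list(mask) == [False, True, True, True, False]

    def test_mode_none_includes_everything(self):
        mask = detect_efficiency_outliers([1.0, 1.5, 2.0], mode="none")
        assert mask.all()


class TestIterateAssay:
    def test_no_outliers_is_a_fixed_point(self):
        prep = _prepared_assay(1.85, [1e-2, 1e-3, 1e-4, 1e-5], n_cycles=45)
        res = iterate_assay(prep, target_id="T")
        assert all(res.included.values())

    def test_planted_low_efficiency_reaction_is_excluded(self):
        prep = _prepared_assay(1.85, [1e-2, 1e-3, 1e-4, 1e-5, 1e-2, 1e-3, 1e-4],
                               n_cycles=45)
        bad_curve, _ = simulate_amplification_curve(
            AmpSimParams(n0_true=1e-3, efficiency_true=1.5, n_cycles=45))
        fit = estimate_baseline(bad_curve)
        phase = find_exponential_phase(fit.corrected, bad_curve.cycles)
        prep["W99"] = PreparedReaction("W99", bad_curve.cycles, fit.corrected,
                                       phase)
        res = iterate_assay(prep, target_id="T")
        assert res.included["W99"] is False
        assert res.e_tar == pytest.approx(1.85, abs=0.005)

    def test_outlier_mode_none_keeps_spread(self):
        prep = _prepared_assay(1.85, [1e-2, 1e-3, 1e-4], n_cycles=45)
        cfg = AnalysisConfig(outlier_mode="none")
        res = iterate_assay(prep, cfg, target_id="T")
        assert all(res.included.values())


class TestCommonThreshold:
    def _phase(self, lo, hi):
        return ExponentialPhase(1, 10, 5.0, math.sqrt(lo * hi), lo, hi)

    def test_single_reaction_uses_geometric_mean_of_bounds(self):
        thr, flagged = set_common_threshold({"A1": self._phase(1.0, 100.0)})
        assert thr.nq == pytest.approx(10.0)
        assert not flagged

    def test_identical_duplicates_match_single(self):
        thr, _ = set_common_threshold(
            {"A1": self._phase(1.0, 100.0), "A2": self._phase(1.0, 100.0)})
        assert thr.nq == pytest.approx(10.0)

    def test_threshold_inside_every_phase_on_heterogeneous_plate(
            self, noiseless_analysis):
        _, _, amp = noiseless_analysis
        nq = amp.threshold.nq
        for rr in amp.reactions.values():
            if rr.phase is not None:
                assert rr.phase.lower_fluor <= nq <= rr.phase.upper_fluor

    def test_empty_intersection_falls_back_to_centres(self):
        thr, flagged = set_common_threshold(
            {"A1": self._phase(1.0, 10.0), "A2": self._phase(100.0, 1000.0)})
        assert thr.nq == pytest.approx(math.sqrt(math.sqrt(10) * math.sqrt(1e5)))
        assert flagged == {"A1", "A2"}


class TestCqAndN0:
    def _phase(self, centre_cycle=20.0, centre_fluor=10.0):
        return ExponentialPhase(10, 30, centre_cycle, centre_fluor, 1.0, 100.0)

    def test_threshold_at_centre_returns_centre_cycle(self):
        assert call_cq(self._phase(), 1.9, 10.0) == pytest.approx(20.0)

    def test_two_doublings_above_centre(self):
        assert call_cq(self._phase(), 2.0, 40.0) == pytest.approx(22.0)

    def test_efficiency_at_or_below_one_rejected(self):
        with pytest.raises(UndefinedEfficiencyError):
            call_cq(self._phase(), 1.0, 10.0)

    def test_called_cq_matches_simulator_truth(self):
        curve, truth = _sim_curve(n0_true=1e-2, efficiency_true=1.9,
                                  n_cycles=45)
        fit = estimate_baseline(curve)
        phase = find_exponential_phase(fit.corrected, curve.cycles)
        nq = math.sqrt(phase.lower_fluor * phase.upper_fluor)
        cq = call_cq(phase, 1.9, nq)
        assert cq == pytest.approx(truth.cq_at(nq), abs=0.05)

    def test_compute_n0_closed_forms(self):
        assert compute_n0(1.0, 2.0, 20.0) == pytest.approx(2.0**-20)
        assert compute_n0(5.0, 1.9, 0.0) == pytest.approx(5.0)

    @given(st.floats(1.05, 2.0), st.floats(0.0, 40.0), st.floats(0.1, 30.0))
    def test_n0_ratio_invariance(self, e_tar, cq, delta):
        n0a = compute_n0(7.5, e_tar, cq)
        n0b = compute_n0(7.5, e_tar, cq + delta)
        assert n0a / n0b == pytest.approx(e_tar**delta, rel=1e-9)


class TestClassifyReaction:
    @pytest.mark.parametrize("status,flags,stype,expect_flag,expect_suppress", [
        ("amplified", set(), "negative_control", "control_error", True),
        ("not_amplified", {"no_amplification"}, "positive_control",
         "control_error", False),
        ("amplified", set(), "unknown", None, False),
        ("not_amplified", {"no_amplification"}, "unknown",
         "no_amplification", False),
        ("amplified", {"baseline_error"}, "unknown", "baseline_error", True),
        ("no_plateau", {"no_plateau"}, "unknown", "no_plateau", False),
    ])
    def test_flag_matrix(self, status, flags, stype, expect_flag,
                         expect_suppress):
        out_flags, msgs, suppress = classify_reaction(status, flags, stype)
        if expect_flag:
            assert expect_flag in out_flags
        else:
            assert not out_flags
        if stype == "unknown":
            assert "control_error" not in out_flags
        assert suppress is expect_suppress


class TestAnalyzeAmplification:
    def test_noiseless_efficiency_recovery(self, noiseless_analysis):
        _, _, amp = noiseless_analysis
        true_e = {"T1": 1.7, "T2": 1.8, "T3": 1.9, "T4": 2.0}
        for target, e in true_e.items():
            assert amp.assays[target].e_tar == pytest.approx(e, abs=0.01)

    def test_shuffling_wells_leaves_results_unchanged(self, noiseless_plate):
        run, _ = noiseless_plate
        amp1 = analyze_amplification(run)
        import copy
        shuffled = copy.deepcopy(run)
        random.Random(4).shuffle(shuffled.reactions)
        amp2 = analyze_amplification(shuffled)
        assert amp1.threshold.nq == amp2.threshold.nq
        for w, rr in amp1.reactions.items():
            assert amp2.reactions[w].cq == rr.cq
            assert amp2.reactions[w].n0 == rr.n0

    def test_plate_of_flat_wells_is_a_run_level_error(self):
        plan = PlatePlan(wells=[
            WellPlan(f"A{i}", f"S{i}", "unknown", "T1",
                     amp=AmpSimParams(n0_true=0.0, noise_sd=1e-4))
            for i in range(1, 5)])
        run, _ = generate_synthetic_run(plan, seed=0)
        with pytest.raises(AnalysisError):
            analyze_amplification(run)

    def test_n0_identity_holds_to_machine_precision(self, noiseless_analysis):
        _, _, amp = noiseless_analysis
        for rr in amp.reactions.values():
            if rr.n0 is not None:
                e = amp.assays[rr.target_id].e_tar
                assert rr.n0 == pytest.approx(
                    amp.threshold.nq / e**rr.cq, rel=1e-12)

    def test_cq_decreases_by_k_when_input_scaled_by_e_to_k(self):
        e = 1.9
        ks = [0, 3, 6, 9]
        plan = PlatePlan(wells=[
            WellPlan(f"A{k}", f"S{k}", "unknown", "T1",
                     amp=AmpSimParams(n0_true=1e-2 * e**-k, efficiency_true=e,
                                      n_cycles=45))
            for k in ks])
        run, _ = generate_synthetic_run(plan, seed=0)
        amp = analyze_amplification(run)
        cqs = {k: amp.reactions[f"A{k}"].cq for k in ks}
        for k in ks[1:]:
            assert cqs[k] - cqs[0] == pytest.approx(k, abs=0.1)

    def test_noisy_efficiency_recovery(self, noisy_analysis):
        _, _, amp = noisy_analysis
        true_e = {"T1": 1.7, "T2": 1.8, "T3": 1.9, "T4": 2.0}
        for target, e in true_e.items():
            assert amp.assays[target].e_tar == pytest.approx(e, abs=0.03)

    def test_noiseless_n0_recovery_within_ten_percent(self, noiseless_analysis):
        _, truth, amp = noiseless_analysis
        checked = 0
        for well, rr in amp.reactions.items():
            if rr.n0 is None or truth.loc[well, "n0"] <= 0:
                continue
            assert rr.n0 == pytest.approx(truth.loc[well, "n0"], rel=0.10)
            checked += 1
        assert checked >= 10


class TestSlopeToleranceSemantics:
    def test_slope_tolerance_translates_to_efficiency_difference(self):
        """A log10-slope change of 1e-4 at E = 1.8 is an efficiency change of
        ln(10) * 1.8 * 1e-4 ~ 4e-4, analytically and by finite difference."""
        analytic = math.log(10.0) * 1.8 * 1e-4
        slope = math.log10(1.8)
        empirical = 10.0 ** (slope + 1e-4) - 10.0**slope
        assert analytic == pytest.approx(4e-4, rel=0.05)
        assert empirical == pytest.approx(analytic, rel=1e-3)
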