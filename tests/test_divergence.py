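"""Residuals, posterior probabilities, Bonferroni thresholds, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from earlyonset import (
    McmcSettings,
    MedianPair,
    ScenarioConfig,
    TestingPlan,
    bonferroni_threshold,
    classify_unit,
    eligible_units,
    expected_onset,
    fit_standard_curve,
    generate_null_study_pairs,
    generate_reference_pairs,
    generate_study_pairs,
    posterior_probability,
    residual_summary,
    run_divergence_analysis,
)
from earlyonset.divergence import CATEGORIES

from conftest import SHORT, make_degenerate_curve


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, n, expected",
        [(0.05, 40, 0.00125), (0.05, 35, 0.05 / 35), (0.05, 1, 0.05)],
    )
    def test_threshold_values(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, abs=1e-15)

    def test_women_threshold_prints_as_published(self):
        # 0.05/35 = 0.0014285..., reported rounded to 0.00143
        assert f"{bonferroni_threshold(0.05, 35):.5f}" == "0.00143"

    def test_no_eligible_units_is_an_error(self):
        with pytest.raises(ValueError, match="no eligible units"):
            bonferroni_threshold(0.05, 0)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestEligibility:
    def make(self, n_cases, y=70.0):
        return MedianPair("U", "male", 44.0, y, n_cases, 1000)

    def test_single_case_excluded(self):
        eligible, excluded = eligible_units([self.make(1)])
        assert not eligible and len(excluded) == 1

    def test_two_cases_with_median_eligible(self):
        eligible, excluded = eligible_units([self.make(2)])
        assert len(eligible) == 1 and not excluded

    def test_undefined_median_excluded_despite_cases(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="earlyonset.divergence"):
            eligible, excluded = eligible_units([self.make(50, y=None)])
        assert not eligible and len(excluded) == 1
        assert any("undefined onset median" in rec.message for rec in caplog.records)


class TestResidualSummary:
    def test_noiseless_limit(self):
        curve = make_degenerate_curve(alpha=50.0, beta=0.5, sigma=0.0)
        pair = MedianPair("U", "male", 40.0, 66.0, 30, 1000)
        residual, ci = residual_summary(curve, pair, mode="predictive")
        assert residual == pytest.approx(-4.0, abs=1e-9)
        assert ci[0] == pytest.approx(-4.0) and ci[1] == pytest.approx(-4.0)

    def test_point_on_the_line_is_symmetric(self, fitted_curve):
        x = float(fitted_curve.x_ref.mean())
        pair = MedianPair("U", "male", x, float(expected_onset(fitted_curve, x)), 30, 1000)
        residual, ci = residual_summary(fitted_curve, pair)
        assert residual == pytest.approx(0.0, abs=0.1)
        assert ci[0] == pytest.approx(-ci[1], abs=0.2)

    def test_predictive_halfwidth_near_normal_quantile(self, fitted_curve):
        # at the reference mean the leverage term is minimal, so the
        # predictive CI half-width approaches 1.96 * median(sigma draws)
        x = float(fitted_curve.x_ref.mean())
        pair = MedianPair("U", "male", x, float(expected_onset(fitted_curve, x)), 30, 1000)
        _, ci = residual_summary(fitted_curve, pair, mode="predictive")
        half = (ci[1] - ci[0]) / 2
        sigma_med = float(np.median(fitted_curve.sigma_flat))
        assert half == pytest.approx(1.96 * sigma_med, rel=0.12)

    def test_undefined_median_is_an_error(self, fitted_curve):
        with pytest.raises(ValueError, match="undefined onset median"):
            residual_summary(fitted_curve, MedianPair("U", "male", 44.0, None, 30, 1000))


class TestPosteriorProbability:
    def test_point_on_line_has_central_pp(self, fitted_curve):
        x = 45.0
        pair = MedianPair("U", "male", x, float(expected_onset(fitted_curve, x)), 30, 1000)
        assert posterior_probability(fitted_curve, pair) == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("mode", ["parameter", "predictive"])
    def test_tail_monotone_and_limits(self, fitted_curve, mode):
        x = 45.0
        ys = np.linspace(20.0, 130.0, 23)
        pps = [
            posterior_probability(fitted_curve, MedianPair("U", "male", x, y, 30, 1000), mode)
            for y in ys
        ]
        assert pps[0] < 1e-6 and pps[-1] > 1 - 1e-6
        assert np.all(np.diff(pps) >= 0)

    def test_parameter_mode_is_more_extreme(self, fitted_curve):
        # line-only draws have strictly smaller spread than predictive draws
        for y_off in (-4.0, -2.0, 2.0, 4.0):
            x = 45.0
            pair = MedianPair(
                "U", "male", x, float(expected_onset(fitted_curve, x)) + y_off, 30, 1000
            )
            pp_pred = posterior_probability(fitted_curve, pair, "predictive")
            pp_param = posterior_probability(fitted_curve, pair, "parameter")
            if y_off < 0:
                assert pp_param <= pp_pred
            else:
                assert pp_param >= pp_pred

    def test_null_pp_is_approximately_uniform(self):
        """Study units drawn from the reference generative model produce
        PP values indistinguishable from Uniform(0,1) at n ~ 2000."""
        cfg = ScenarioConfig(seed=0, study_case_counts=tuple([30] * 41))
        pps = []
        for rep in range(50):
            c = cfg.with_seed(3000 + rep)
            ref, _ = generate_reference_pairs(c)
            curve = fit_standard_curve(
                ref, settings=McmcSettings(chains=2, burn_in=300, samples=1200, seed=rep)
            )
            study, _ = generate_null_study_pairs(c)
            pps.extend(posterior_probability(curve, p) for p in study if p.y is not None)
        stat = kstest(np.array(pps), "uniform").statistic
        assert stat < 0.045  # ~2x the 1% critical value at n=2050


class TestClassification:
    @pytest.mark.parametrize(
        "residual, pp, threshold, early, late, category",
        [
            # published worked rows: men 200-399 m ring; women industrial area
            (-4.5, 0.0002, 0.00125, True, False, "early_4_6"),
            (-5.3, 0.0013, 0.05 / 35, True, False, "early_4_6"),
            (0.0, 0.5, 0.00125, False, False, "neutral"),
            (2.0, 0.9999, 0.00125, False, True, "postpone_ge2"),
            (-8.1, 1e-6, 0.00125, True, False, "early_ge6"),
        ],
    )
    def test_flags_and_bands(self, residual, pp, threshold, early, late, category):
        plan = TestingPlan(alpha=0.05, n_eligible=round(0.05 / threshold))
        assert plan.threshold == pytest.approx(threshold, rel=1e-9)
        got_early, got_late, got_cat = classify_unit(residual, pp, plan)
        assert (got_early, got_late, got_cat) == (early, late, category)

    def test_threshold_comparison_is_inclusive(self):
        plan = TestingPlan(alpha=0.05, n_eligible=35)
        early, _, _ = classify_unit(-5.3, plan.threshold, plan)
        assert early

    @settings(deadline=None, max_examples=300)
    @given(st.floats(-50.0, 50.0, allow_nan=False), st.floats(0.0, 1.0, allow_nan=False))
    def test_bands_partition_the_line(self, residual, pp):
        plan = TestingPlan(alpha=0.05, n_eligible=40)
        _, _, category = classify_unit(residual, pp, plan)
        assert category in CATEGORIES and category != "no_data"
        # exactly one band matches
        in_band = [
            residual >= 2.0,
            -2.0 < residual < 2.0,
            -4.0 < residual <= -2.0,
            -6.0 < residual <= -4.0,
            residual <= -6.0,
        ]
        assert sum(in_band) == 1


class TestEndToEnd:
    def test_injected_early_unit_is_flagged(self):
        shifts = tuple([-8.0] + [0.0] * 40)
        cfg = ScenarioConfig(seed=5, shifts=shifts, study_case_counts=tuple([30] * 41))
        ref, _ = generate_reference_pairs(cfg)
        study, _ = generate_study_pairs(cfg)
        out = run_divergence_analysis(ref, study, settings=SHORT)
        flagged = {r.unit_id for r in out.results if r.significant_early}
        assert "AREA00" in flagged
        by_id = {r.unit_id: r for r in out.results}
        assert by_id["AREA00"].category in ("early_ge6", "early_4_6")
        assert out.plans["male"].n_eligible == 41
        assert out.plans["male"].threshold == pytest.approx(0.05 / 41)

    def test_empty_study_returns_curve_only(self, reference_pairs):
        out = run_divergence_analysis(reference_pairs, [], settings=SHORT)
        assert out.results == []
        assert "male" in out.curves

    def test_sexes_are_analysed_separately(self):
        cfg_m = ScenarioConfig(seed=2, sex="male", n_study=10,
                               study_case_counts=tuple([30] * 10))
        cfg_f = ScenarioConfig(seed=3, sex="female", n_study=8, true_alpha=37.4,
                               true_beta=0.76, study_case_counts=tuple([30] * 8))
        ref = generate_reference_pairs(cfg_m)[0] + generate_reference_pairs(cfg_f)[0]
        study = generate_study_pairs(cfg_m)[0] + generate_study_pairs(cfg_f)[0]
        out = run_divergence_analysis(ref, study, settings=SHORT)
        assert set(out.curves) == {"male", "female"}
        assert out.plans["male"].n_eligible == 10
        assert out.plans["female"].n_eligible == 8
        for r in out.results:
            curve = out.curves[r.sex]
            assert r.expected == pytest.approx(float(expected_onset(curve, r.x)))

    def test_study_sex_without_reference_is_an_error(self, reference_pairs):
        study = [MedianPair("S", "female", 44.0, 70.0, 30, 1000)]
        with pytest.raises(ValueError, match="without reference"):
            run_divergence_analysis(reference_pairs, study, settings=SHORT)

    def test_excluded_units_carry_no_data_category(self, reference_pairs, fitted_curve):
        study = [
            MedianPair("S0", "male", 44.0, 70.0, 30, 1000),
            MedianPair("S1", "male", 44.0, None, 0, 75),
            MedianPair("S2", "male", 44.0, 71.0, 1, 120),
        ]
        out = run_divergence_analysis(reference_pairs, study, settings=SHORT)
        by_id = {r.unit_id: r for r in out.results}
        assert by_id["S0"].eligible
        assert by_id["S1"].category == "no_data" and by_id["S1"].pp is None
        assert by_id["S2"].category == "no_data" and not by_id["S2"].eligible
        assert out.plans["male"].n_eligible == 1

    def test_power_increases_with_shift_magnitude(self):
        """Early-flag probability grows with the injected anticipation."""
        rates = []
        for shift in (0.0, -4.0, -8.0):
            flags = 0
            for rep in range(15):
                cfg = ScenarioConfig(
                    seed=100 * rep + 17, n_study=1, shifts=(shift,),
                    study_case_counts=(30,),
                )
                ref, _ = generate_reference_pairs(cfg)
                study, _ = generate_study_pairs(cfg)
                out = run_divergence_analysis(
                    ref, study,
                    settings=McmcSettings(chains=2, burn_in=300, samples=1200, seed=rep),
                    alpha=0.05,
                )
                flags += int(out.results[0].significant_early)
            rates.append(flags / 15)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.8
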