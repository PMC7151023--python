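"""Validation statistics: efficiency, probit LOD, LOQ, precision, agreement."""

import math

import numpy as np
import pytest
from scipy import stats

from asqpcr import (
    DetectionTable,
    LoqLevel,
    ProbitConvergenceError,
    compare_slopes,
    efficiency_from_slope,
    fit_standard_curve,
    loq_assessment,
    method_comparison,
    method_comparison_subgroups,
    one_sample_t_from_summary,
    precision_analysis,
    probit_lod,
    qualitative_agreement,
)


class TestStandardCurve:
    def test_perfect_doubling_line(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        pts = list(zip(x, -math.log2(10.0) * x + 40.0))
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(-3.321928, abs=1e-5)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)

    def test_calibration_line_efficiency(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        pts = list(zip(x, -3.26 * x + 29.75))
        curve = fit_standard_curve(pts)
        assert 100.0 * curve.efficiency == pytest.approx(102.66, abs=0.01)

    def test_contracts(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(0.0, 30.0), (-1.0, 33.0)])
        with pytest.raises(ValueError):  # no concentration span
            fit_standard_curve([(0.0, 30.0), (0.0, 31.0), (0.0, 32.0)])
        with pytest.raises(ValueError):  # span below one decade
            fit_standard_curve([(0.0, 30.0), (-0.3, 31.0), (-0.6, 32.0)])

    @pytest.mark.parametrize(
        "slope, eff",
        [(-3.3219, 1.000), (-3.5, 0.931), (-3.26, 1.027)],
    )
    def test_efficiency_from_slope(self, slope, eff):
        assert efficiency_from_slope(slope) == pytest.approx(eff, abs=5e-4)

    def test_efficiency_rejects_nonnegative_slope(self):
        with pytest.raises(ValueError):
            efficiency_from_slope(0.5)


class TestCompareSlopes:
    def noisy_series(self, slope, intercept, rng, n=5, sd=0.1):
        x = np.linspace(0, -2, n)
        return list(zip(x, slope * x + intercept + rng.normal(0, sd, n)))

    def test_identical_series_p_one(self):
        pts = [(0.0, 40.0), (-1.0, 43.3), (-2.0, 46.7), (-3.0, 50.0)]
        res = compare_slopes([pts, pts])
        assert res.global_p == 1.0

    def test_exactly_parallel_noiseless_series(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        a = list(zip(x, -3.3 * x + 40.0))
        b = list(zip(x, -3.3 * x + 42.0))
        res = compare_slopes([a, b])
        assert res.slopes[0] == pytest.approx(res.slopes[1], abs=1e-12)
        assert res.global_p == 1.0

    def test_clearly_unequal_slopes_detected(self, rng):
        a = self.noisy_series(-3.3, 40.0, rng)
        b = self.noisy_series(-5.0, 40.0, rng)
        res = compare_slopes([a, b])
        assert res.global_p < 0.001
        assert res.pairwise_p[(0, 1)] < 0.001

    def test_global_f_matches_statsmodels_oracle(self, rng):
        """Extra-sum-of-squares F against an independently built OLS
        model comparison (dummy-coded separate-slopes vs common-slope)."""
        import statsmodels.api as sm

        series = [
            self.noisy_series(-3.3, 40.0, rng),
            self.noisy_series(-3.6, 41.0, rng),
            self.noisy_series(-3.1, 39.0, rng),
        ]
        res = compare_slopes(series)

        rows = [(i, x, y) for i, pts in enumerate(series) for x, y in pts]
        group = np.array([r[0] for r in rows])
        x = np.array([r[1] for r in rows])
        y = np.array([r[2] for r in rows])
        dummies = np.column_stack([(group == g).astype(float) for g in range(3)])
        common = sm.OLS(y, np.column_stack([dummies, x])).fit()
        separate = sm.OLS(
            y, np.column_stack([dummies, dummies * x[:, None]])
        ).fit()
        f, p, df = separate.compare_f_test(common)
        assert res.global_f == pytest.approx(f, rel=1e-9)
        assert res.global_p == pytest.approx(p, rel=1e-9)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            compare_slopes([[(0.0, 1.0), (0.0, 2.0), (0.0, 3.0)]] * 2)


class TestProbitLod:
    def test_monotone_fitted_probabilities(self, detection_panel):
        fit = probit_lod(detection_panel)
        probs = list(fit.fitted_probabilities)
        assert probs == sorted(probs, reverse=True)  # levels decrease

    def test_lod_between_all_miss_and_all_hit(self, detection_panel):
        fit = probit_lod(detection_panel)
        highest_all_miss = 0.036
        lowest_all_hit = 0.290
        assert highest_all_miss < fit.lod < lowest_all_hit

    def test_fitted_probability_at_lod_equals_target(self, detection_panel):
        fit = probit_lod(detection_panel, target_probability=0.95)
        assert fit.predict(fit.lod) == pytest.approx(0.95, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        """On a small table the MLE must agree with brute-force
        likelihood maximisation over (intercept, slope) to 3 decimals
        in the LOD."""
        table = DetectionTable(
            levels_percent=[1.16, 0.29, 0.073, 0.018],
            n_tested=[9, 9, 9, 9],
            n_detected=[9, 8, 4, 1],
        )
        fit = probit_lod(table)

        levels = np.asarray(table.levels_percent)
        det = np.asarray(table.n_detected)
        n = np.asarray(table.n_tested)

        def negloglik(a, b):
            p = np.clip(stats.norm.cdf(a + b * levels), 1e-12, 1 - 1e-12)
            return -(det * np.log(p) + (n - det) * np.log(1 - p)).sum()

        a_lo, a_hi, b_lo, b_hi = -10.0, 5.0, 0.1, 60.0
        for _ in range(6):  # nested grid refinement
            aa = np.linspace(a_lo, a_hi, 61)
            bb = np.linspace(b_lo, b_hi, 61)
            nll = np.array([[negloglik(a, b) for b in bb] for a in aa])
            i, j = np.unravel_index(nll.argmin(), nll.shape)
            a_best, b_best = aa[i], bb[j]
            da, db = (a_hi - a_lo) / 10, (b_hi - b_lo) / 10
            a_lo, a_hi = a_best - da, a_best + da
            b_lo, b_hi = b_best - db, b_best + db
        lod_grid = (stats.norm.ppf(0.95) - a_best) / b_best
        assert fit.lod == pytest.approx(lod_grid, abs=1e-3)

    def test_complete_separation_raises(self):
        table = DetectionTable(
            levels_percent=[1.16, 0.58, 0.29, 0.145],
            n_tested=[9, 9, 9, 9],
            n_detected=[9, 9, 0, 0],
        )
        with pytest.raises(ProbitConvergenceError):
            probit_lod(table)

    def test_parameter_recovery_within_ci(self, rng):
        """Simulating panels from a known probit curve, the true LOD
        falls inside the delta-method 95% CI in at least 90% of runs."""
        a_true, b_true = -2.7, 29.0
        levels = np.array([1.16, 0.58, 0.29, 0.145, 0.073, 0.036])
        p_true = stats.norm.cdf(a_true + b_true * levels)
        lod_true = (stats.norm.ppf(0.95) - a_true) / b_true
        n = 200
        hits = 0
        runs = 20
        for _ in range(runs):
            detected = rng.binomial(n, p_true)
            table = DetectionTable(levels, [n] * len(levels), detected)
            fit = probit_lod(table)
            lo, hi = fit.lod_ci
            hits += lo <= lod_true <= hi
        assert hits >= int(0.9 * runs)

    def test_log10_dose_scale_option(self, detection_panel):
        fit = probit_lod(detection_panel, dose_scale="log10")
        assert fit.dose_scale == "log10"
        assert 0.1 < fit.lod < 0.3  # same ballpark, different metameter

    def test_table_validation(self):
        with pytest.raises(ValueError):  # levels must decrease
            DetectionTable([0.1, 0.2], [9, 9], [1, 2])
        with pytest.raises(ValueError):  # detected > tested
            DetectionTable([0.2, 0.1], [9, 9], [10, 2])


class TestOneSampleT:
    def test_mean_equals_expected(self):
        t, p = one_sample_t_from_summary(1.16, 0.25, 9, 1.16)
        assert t == 0.0 and p == 1.0

    def test_observed_vs_expected_at_loq(self):
        t, p = one_sample_t_from_summary(1.03, 0.25, 9, 1.16)
        assert t == pytest.approx(-1.56, abs=0.01)
        assert p == pytest.approx(0.157, abs=0.005)

    def test_strongly_biased_level(self):
        _, p = one_sample_t_from_summary(0.19, 0.06, 9, 0.58)
        assert p < 1e-4

    def test_degenerate_sd(self):
        assert one_sample_t_from_summary(1.0, 0.0, 5, 1.0)[1] == 1.0
        assert one_sample_t_from_summary(1.0, 0.0, 5, 2.0)[1] == 0.0

    def test_matches_scipy_from_raw_data(self, rng):
        obs = rng.normal(1.1, 0.2, 9)
        t_ref, p_ref = stats.ttest_1samp(obs, 1.16)
        t, p = one_sample_t_from_summary(
            obs.mean(), obs.std(ddof=1), obs.size, 1.16
        )
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)


class TestLoqAssessment:
    def printed_levels(self):
        return [
            LoqLevel(1.16, mean=1.03, sd=0.25, n=9, n_detected=9, n_tested=9),
            LoqLevel(0.58, mean=0.19, sd=0.06, n=9, n_detected=9, n_tested=9),
            LoqLevel(0.29, mean=0.048, sd=0.037, n=9, n_detected=9, n_tested=9),
            LoqLevel(0.15, mean=0.0098, sd=0.0053, n=9, n_detected=8, n_tested=9),
        ]

    def test_published_summaries_give_top_level(self):
        result = loq_assessment(self.printed_levels())
        assert result.loq_percent == 1.16
        assert result.table["quantifiable"].tolist() == [True, False, False, False]

    def test_unbiased_everywhere_gives_lowest_level(self):
        levels = [
            LoqLevel(l, observations=(l * 0.98, l * 1.0, l * 1.02, l * 1.01))
            for l in (1.16, 0.58, 0.29)
        ]
        assert loq_assessment(levels).loq_percent == 0.29

    def test_no_passing_level_is_explicitly_undefined(self):
        levels = [
            LoqLevel(l, observations=(l * 0.1, l * 0.12, l * 0.11))
            for l in (1.16, 0.58)
        ]
        result = loq_assessment(levels, min_detected_fraction=0.5)
        assert not result.defined
        assert result.loq_percent is None

    def test_detection_prerequisite_binds(self):
        # accurate but rarely detected level cannot be the LOQ
        levels = [
            LoqLevel(1.16, mean=1.1, sd=0.2, n=9, n_detected=9, n_tested=9),
            LoqLevel(0.58, mean=0.57, sd=0.1, n=5, n_detected=5, n_tested=9),
        ]
        assert loq_assessment(levels).loq_percent == 1.16

    def test_simulated_dilution_series(self):
        """LOQ machinery on a simulated replicate dilution series: the
        generator is unbiased at every level, so any level failing to
        qualify does so through the detection prerequisite, not the
        accuracy t test."""
        from asqpcr import (
            SimulationConfig,
            is_undetermined,
            mutant_percent_simple,
            simulate_reaction_pair,
        )

        config = SimulationConfig(seed=19)
        rng = config.rng()
        levels = []
        for k in range(6):
            frac = 0.0116 / 2**k
            from dataclasses import replace as _replace

            level_cfg = _replace(config, true_mutant_fraction=frac)
            observed, detected = [], 0
            for _ in range(9):
                r = simulate_reaction_pair(level_cfg, rng=rng)
                if not is_undetermined(r.cq_mut) and float(r.cq_mut) < 42.0:
                    detected += 1
                    observed.append(mutant_percent_simple(r.cq_wt, r.cq_mut))
            if len(observed) >= 2:
                levels.append(
                    LoqLevel(
                        100.0 * frac,
                        observations=tuple(observed),
                        n_detected=detected,
                        n_tested=9,
                    )
                )
        result = loq_assessment(levels)
        assert result.defined
        assert result.loq_percent in [lv.level_percent for lv in levels]
        below = result.table[result.table["level_percent"] < result.loq_percent]
        assert (~below["quantifiable"]).all()

    def test_levels_must_decrease(self):
        with pytest.raises(ValueError):
            loq_assessment(
                [LoqLevel(0.5, mean=0.5, sd=0.1, n=9),
                 LoqLevel(1.0, mean=1.0, sd=0.1, n=9)]
            )


class TestPrecision:
    def test_identical_values_zero_cv(self):
        res = precision_analysis(np.full((9, 2), 54.1))
        assert res.cv_total == res.cv_between_day == res.cv_within_run == 0.0

    def test_hand_computed_two_day_design(self):
        res = precision_analysis([[10.0, 12.0], [14.0, 16.0]])
        assert res.mean == pytest.approx(13.0)
        assert res.var_within == pytest.approx(2.0)
        assert res.var_between == pytest.approx(7.0)
        assert res.cv_within_run == pytest.approx(10.88, abs=0.01)
        assert res.cv_between_day == pytest.approx(20.35, abs=0.01)
        assert res.cv_total == pytest.approx(23.08, abs=0.01)

    def test_total_variance_dominates_components(self, rng):
        data = rng.normal(50, 3, size=(9, 2)) + rng.normal(0, 2, size=(9, 1))
        res = precision_analysis(data)
        assert res.cv_total**2 >= res.cv_between_day**2 - 1e-9
        assert res.cv_total**2 >= res.cv_within_run**2 - 1e-9

    def test_matches_definitional_sums_of_squares(self, rng):
        """Variance components equal a brute-force two-pass computation
        from definitional sums of squares on random designs."""
        for _ in range(10):
            days = int(rng.integers(2, 12))
            reps = int(rng.integers(2, 6))
            data = rng.normal(40, 4, size=(days, reps))
            res = precision_analysis(data)

            grand = sum(sum(row) for row in data) / (days * reps)
            day_means = [sum(row) / reps for row in data]
            ssw = sum(
                (data[i][j] - day_means[i]) ** 2
                for i in range(days)
                for j in range(reps)
            )
            ssb = reps * sum((m - grand) ** 2 for m in day_means)
            msw = ssw / (days * (reps - 1))
            msb = ssb / (days - 1)
            assert res.var_within == pytest.approx(msw, rel=1e-10)
            assert res.var_between == pytest.approx(
                max(0.0, (msb - msw) / reps), rel=1e-10, abs=1e-12
            )

    def test_recovers_generating_variances(self, rng):
        sigma_day, sigma_rep, mu = 2.0, 1.0, 50.0
        days, reps = 400, 4
        data = (
            mu
            + rng.normal(0, sigma_day, size=(days, 1))
            + rng.normal(0, sigma_rep, size=(days, reps))
        )
        res = precision_analysis(data)
        assert res.cv_within_run == pytest.approx(100 * sigma_rep / mu, rel=0.10)
        assert res.cv_between_day == pytest.approx(100 * sigma_day / mu, rel=0.10)

    def test_rejects_bad_designs(self):
        with pytest.raises(ValueError):
            precision_analysis([[1.0, 2.0]])  # one day
        with pytest.raises(ValueError):
            precision_analysis([[1.0], [2.0]])  # one replicate
        with pytest.raises(ValueError):
            precision_analysis(np.array([1.0, 2.0, 3.0]))  # not day x rep


class TestMethodComparison:
    def test_identity_comparison(self):
        x = [1.5, 20.0, 50.0, 99.9]
        res = method_comparison(x, x)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.bias == 0.0
        assert res.loa == (0.0, 0.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_hand_computed_bias_and_loa(self):
        res = method_comparison([10.0, 20.0, 30.0], [12.0, 21.0, 33.0])
        assert res.bias == pytest.approx(2.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa[0] == pytest.approx(0.04)
        assert res.loa[1] == pytest.approx(3.96)

    def test_constant_offset(self):
        x = np.array([5.0, 15.0, 40.0, 80.0])
        res = method_comparison(x, x + 3.0)
        assert res.bias == pytest.approx(3.0)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-12)
        assert res.pearson_r == pytest.approx(1.0)

    def test_loa_cover_95_percent_of_large_normal_cohort(self, rng):
        ref = rng.uniform(5, 95, 4000)
        test = ref + rng.normal(2.0, 3.0, 4000)
        res = method_comparison(ref, test)
        d = test - ref
        coverage = 100.0 * np.mean((d >= res.loa[0]) & (d <= res.loa[1]))
        assert coverage == pytest.approx(95.0, abs=2.0)

    def test_zero_variance_is_explicit_state(self):
        res = method_comparison([10.0, 10.0, 10.0], [11.0, 12.0, 13.0])
        assert not res.correlation_defined
        assert math.isnan(res.pearson_r)
        assert res.bias == pytest.approx(2.0)  # Bland-Altman still defined

    def test_subgroup_split(self):
        ref = np.array([2.0, 5.0, 10.0, 30.0, 50.0, 80.0])
        test = ref + np.array([0.5, 0.4, 0.6, 4.0, 5.0, 6.0])
        groups = method_comparison_subgroups(ref, test, threshold=20.0)
        assert groups["below"].n == 3 and groups["above"].n == 3
        assert groups["above"].bias > groups["below"].bias

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            method_comparison([1.0, 2.0], [1.0, 2.0])


class TestQualitativeAgreement:
    def test_full_concordance(self):
        calls = [(True, True)] * 23 + [(False, False)] * 19
        res = qualitative_agreement(calls)
        assert res.total_agreement == 100.0
        assert res.positive_agreement == 100.0
        assert res.negative_agreement == 100.0
        assert res.n == 42

    def test_mixed_table(self):
        calls = (
            [(True, True)] * 8
            + [(True, False)] * 2
            + [(False, True)] * 1
            + [(False, False)] * 9
        )
        res = qualitative_agreement(calls)
        assert res.total_agreement == pytest.approx(85.0)
        assert res.positive_agreement == pytest.approx(80.0)
        assert res.negative_agreement == pytest.approx(90.0)

    def test_empty_stratum_is_undefined(self):
        res = qualitative_agreement([(True, True), (True, False)])
        assert res.negative_agreement is None
        assert res.positive_agreement == pytest.approx(50.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qualitative_agreement([])
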