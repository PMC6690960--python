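"""Ingrowth fitting, back-extrapolation, ratio statistic and group tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from recoilkit import (CountingSeries, Classification, compare_groups,
                       extrapolate_A0, fit_cohort, fit_ingrowth, free_ratio,
                       group_summary, ingrowth_activity, read_counting_csv)
from recoilkit import BI213
from recoilkit.ingrowth import ConditioningError, IngrowthFit

LAM2 = BI213.lam_per_min


class TestFitIngrowth:
    def test_exact_recovery_spleen_like(self, make_series):
        fit = fit_ingrowth(make_series(86.0, 58.0))
        assert fit.A_eq_hat == pytest.approx(86.0, rel=1e-9)
        assert fit.A0_hat == pytest.approx(58.0, rel=1e-9)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_constant_series_gives_equal_amplitudes(self, schedule):
        s = CountingSeries("a", "o", schedule, np.full_like(schedule, 12.5))
        fit = fit_ingrowth(s)
        assert fit.A_eq_hat == pytest.approx(12.5, rel=1e-9)
        assert fit.A0_hat == pytest.approx(12.5, rel=1e-9)

    def test_too_few_points(self, lam2):
        s = CountingSeries("a", "o", [0.0, 10.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="3 points"):
            fit_ingrowth(s, lam2)

    def test_short_span_warns(self, lam2):
        t = np.array([0.0, 5.0, 10.0, 15.0])
        s = CountingSeries("a", "o", t, ingrowth_activity(10, 2, lam2, t))
        with pytest.warns(UserWarning, match="span"):
            fit_ingrowth(s, lam2)

    def test_singular_design_all_late(self, lam2):
        # every point far beyond 1/lambda2: A0 column vanishes
        t = np.array([5000.0, 5100.0, 5200.0, 5300.0])
        s = CountingSeries("a", "o", t, np.full(4, 9.0))
        with pytest.raises(ConditioningError):
            fit_ingrowth(s, lam2)

    def test_poisson_weighting_unbiased_mean(self, lam2, schedule):
        # kidney-like amplitudes, counts ~1e4 at equilibrium, 500 replicates
        rng = np.random.default_rng(7)
        scale = 2500.0
        mu = ingrowth_activity(4.7, 36.0, lam2, schedule) * scale
        a0_hats = []
        for _ in range(500):
            y = rng.poisson(mu).astype(float)
            fit = fit_ingrowth(CountingSeries("a", "kidney", schedule, y),
                               lam2, weighting="poisson")
            a0_hats.append(fit.A0_hat / scale)
        assert np.mean(a0_hats) == pytest.approx(36.0, rel=0.01)

    def test_matches_brute_force_minimiser(self, lam2, schedule):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a_eq, a0 = rng.uniform(1, 100, 2)
            y = rng.poisson(ingrowth_activity(a_eq, a0, lam2, schedule) * 50) / 50
            s = CountingSeries("a", "o", schedule, y)
            fit = fit_ingrowth(s, lam2)

            def sse(p):
                return np.sum((y - ingrowth_activity(max(p[0], 0), max(p[1], 0),
                                                     lam2, schedule)) ** 2)

            res = optimize.minimize(sse, x0=[np.max(y), y[0]], method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-14,
                                             "maxiter": 10000})
            assert fit.A_eq_hat == pytest.approx(res.x[0], rel=1e-6)
            assert fit.A0_hat == pytest.approx(res.x[1], rel=1e-6)

    @given(k=st.floats(1e-3, 1e3))
    @settings(deadline=None, max_examples=40)
    def test_scale_invariance_of_ratio(self, k):
        lam2 = LAM2
        t = np.arange(0.0, 1081.0, 30.0)
        base = ingrowth_activity(86.0, 58.0, lam2, t)
        fit = fit_ingrowth(CountingSeries("a", "o", t, base * k), lam2)
        assert fit.A_eq_hat == pytest.approx(86.0 * k, rel=1e-8)
        assert free_ratio(fit).ratio == pytest.approx(58.0 / 86.0, rel=1e-8)

    def test_time_origin_shift_consistency(self, lam2, schedule):
        # fit counts that started δ minutes late, then evolve back to t=0
        a_eq, a0, delta = 17.9, 1.1, 37.0
        t_shifted = schedule + delta
        y = ingrowth_activity(a_eq, a0, lam2, t_shifted)
        fit = fit_ingrowth(CountingSeries("a", "o", schedule, y), lam2)
        e = np.exp(-lam2 * delta)
        recovered_a0 = (fit.A0_hat - fit.A_eq_hat * (1 - e)) / e
        assert recovered_a0 == pytest.approx(a0, rel=1e-8)


class TestExtrapolateA0:
    def test_identity_accessor(self):
        fit = IngrowthFit(86.0, 58.0, 1.0, 1.0, 0.0, 0.0, 10, 0.0152)
        a0, se = extrapolate_A0(fit)
        assert a0 == 58.0 and se == 1.0

    def test_late_start_series_extrapolates_exactly(self, lam2):
        t = np.arange(300.0, 1081.0, 10.0)
        y = ingrowth_activity(17.9, 1.1, lam2, t)
        fit = fit_ingrowth(CountingSeries("a", "blood", t, y), lam2)
        a0, _ = extrapolate_A0(fit)
        assert a0 == pytest.approx(1.1, abs=1e-6)

    def test_negative_a0_warns(self):
        fit = IngrowthFit(10.0, -0.5, 1.0, 1.0, 0.0, 0.0, 10, 0.0152)
        with pytest.warns(UserWarning, match="negative"):
            extrapolate_A0(fit)


class TestFreeRatio:
    @pytest.mark.parametrize("a0, a_eq, expected, cls", [
        (58.0, 86.0, 0.67, Classification.RELEASING),
        (36.0, 4.7, 7.66, Classification.ACCUMULATING),
        (5.0, 5.0, 1.0, Classification.NEUTRAL),
    ])
    def test_ratio_and_classification(self, a0, a_eq, expected, cls):
        fit = IngrowthFit(a_eq, a0, 0.1, 0.1, 0.0, 0.0, 109, 0.0152)
        rr = free_ratio(fit)
        assert round(rr.ratio, 2) == pytest.approx(expected, abs=5e-3)
        assert rr.classification is cls

    def test_nonpositive_equilibrium_rejected(self):
        fit = IngrowthFit(0.0, 1.0, 0.1, 0.1, 0.0, 0.0, 10, 0.0152)
        with pytest.raises(ValueError, match="undefined"):
            free_ratio(fit)

    def test_error_propagation_matches_monte_carlo(self, lam2, schedule):
        rng = np.random.default_rng(3)
        scale = 300.0
        mu = ingrowth_activity(86.0, 58.0, lam2, schedule) * scale
        ratios, ses = [], []
        for _ in range(300):
            y = rng.poisson(mu).astype(float)
            rr = free_ratio(fit_ingrowth(CountingSeries("a", "o", schedule, y), lam2))
            ratios.append(rr.ratio)
            ses.append(rr.se)
        # propagated SE should match the empirical spread within ~20%
        assert np.mean(ses) == pytest.approx(np.std(ratios), rel=0.2)


class TestGroupSummary:
    def test_two_animal_arithmetic(self):
        rrs = [free_ratio(IngrowthFit(1.0, r, 0, 0, 0, 0, 5, 1.0, animal_id=a,
                                      organ="blood", group="g"))
               for a, r in [("a1", 0.5), ("a2", 0.7)]]
        out = group_summary(rrs)
        assert out["mean"].iloc[0] == pytest.approx(0.6)
        assert out["sd"].iloc[0] == pytest.approx(0.14142, abs=1e-4)
        assert out["n"].iloc[0] == 2

    def test_single_animal_sd_undefined(self):
        rr = free_ratio(IngrowthFit(1.0, 0.5, 0, 0, 0, 0, 5, 1.0, group="g"))
        out = group_summary([rr])
        assert np.isnan(out["sd"].iloc[0])

    def test_pooled_vs_per_animal_modes_differ(self):
        # amplitudes mimicking between-animal spread: the two aggregation
        # conventions disagree, as in the blood co-precipitation cell
        fits = [IngrowthFit(a_eq, a0, 0, 0, 0, 0, 5, 1.0, animal_id=f"a{i}",
                            organ="blood", group="g")
                for i, (a0, a_eq) in enumerate([(1.5, 4.0), (0.7, 14.0)])]
        per_animal = group_summary([free_ratio(f) for f in fits])["mean"].iloc[0]
        pooled = group_summary(fits, mode="pooled")["mean"].iloc[0]
        assert per_animal == pytest.approx((1.5 / 4 + 0.7 / 14) / 2)
        assert pooled == pytest.approx(2.2 / 18.0)
        assert per_animal != pytest.approx(pooled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_summary([])


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        p, t = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0 and t == 0.0

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 5)
        p, _ = compare_groups(a, a + 100.0, mode="student")
        assert p < 1e-3

    @pytest.mark.parametrize("mode", ["student", "welch"])
    def test_matches_scipy_oracle(self, mode):
        rng = np.random.default_rng(5)
        a = rng.normal(0.06, 0.03, 5)
        b = rng.normal(0.14, 0.07, 5)
        p, t = compare_groups(a, b, mode=mode)
        ref = stats.ttest_ind(a, b, equal_var=(mode == "student"))
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(6)
        a = rng.normal(1, 0.2, 5)
        b = a + rng.normal(0.3, 0.1, 5)
        p, t = compare_groups(a, b, mode="paired")
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_power_blood_formulation_contrast(self):
        # ratios 0.06 ± 0.03 vs 0.14 ± 0.07, n=5: the test should usually reject
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(0.06, 0.03, 5)
            b = rng.normal(0.14, 0.07, 5)
            p, _ = compare_groups(a, b, mode="student")
            rejections += p < 0.05
        assert rejections / reps > 0.5

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestIO:
    def test_counting_csv_round_trip(self, tmp_path, make_series):
        import pandas as pd
        s = make_series(86.0, 58.0, organ="spleen", animal="m1")
        df = pd.DataFrame({"animal_id": "m1", "group": "DTPA", "organ": "spleen",
                           "t_min": s.times_min, "value": s.values,
                           "window": "Bi-213 380-520 keV"})
        path = tmp_path / "counting.csv"
        df.to_csv(path, index=False)
        series = read_counting_csv(path)
        assert len(series) == 1
        fit = fit_ingrowth(series[0])
        assert fit.A0_hat == pytest.approx(58.0, rel=1e-6)
        assert series[0].group == "DTPA"

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("animal_id,organ\nm1,blood\n")
        with pytest.raises(ValueError, match="t_min"):
            read_counting_csv(path)

    def test_fit_cohort_table_shape(self, make_series):
        series = [make_series(86.0, 58.0, organ="spleen"),
                  make_series(17.9, 1.1, organ="blood")]
        df = fit_cohort(series)
        assert set(df["organ"]) == {"spleen", "blood"}
        assert df.loc[df.organ == "blood", "ratio"].iloc[0] == pytest.approx(
            1.1 / 17.9, rel=1e-8)
        assert (df["classification"] == "releasing").all()
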