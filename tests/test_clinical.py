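"""Subtype rules, association tests, KM/log-rank/Cox survival analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rarseek.clinical import (apply_horizon, classify_subtype, clinical_covariates,
                              combined_marker, cox_fit, fdr_adjust,
                              fisher_exact_2x2, km_estimate, logrank_test,
                              logrank_trend_test, three_level_groups)


class TestSubtype:
    @pytest.mark.parametrize("er,pr,her2,expected", [
        ("positive", "negative", "negative", "LuminalA"),
        ("negative", "positive", "negative", "LuminalA"),
        ("positive", "positive", "positive", "LuminalB"),
        ("negative", "negative", "positive", "HER2"),
        ("negative", "negative", "negative", "TNBC"),
    ])
    def test_mapping(self, er, pr, her2, expected):
        assert classify_subtype(er, pr, her2) == expected

    def test_total_on_all_eight_combinations(self):
        for combo in itertools.product(["positive", "negative"], repeat=3):
            assert classify_subtype(*combo) in {"LuminalA", "LuminalB", "HER2", "TNBC"}


class TestFisherFdr:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        from scipy.stats import hypergeom

        table = [[8, 2], [1, 9]]
        # enumeration oracle: sum P(tables at least as extreme) over same margins
        r1, r2 = 10, 10
        c1 = 9
        n = 20
        probs = {a: hypergeom.pmf(a, n, r1, c1) for a in range(max(0, c1 - r2), min(r1, c1) + 1)}
        obs = probs[8]
        expected = sum(p for p in probs.values() if p <= obs + 1e-12)
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-9)

    def test_extreme_table_significant(self):
        assert fisher_exact_2x2([[0, 10], [10, 0]]) < 0.001

    def test_empty_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2([[0, 0], [5, 5]]) == 1.0

    def test_fdr_hand_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_fdr_identity_cases(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        q = fdr_adjust([0.001, 0.5, 0.04])
        assert np.all(q >= [0.001, 0.5, 0.04])


class TestKaplanMeier:
    def test_hand_product_limit_values(self):
        km = km_estimate([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])["all"]
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(0.8)
        assert lookup[2.0] == pytest.approx(0.6)
        assert lookup[3.0] == pytest.approx(0.6)
        assert lookup[4.0] == pytest.approx(0.3)

    def test_no_events_curve_constant_one(self):
        km = km_estimate([2, 4, 6], [0, 0, 0])["all"]
        assert np.all(km["survival"] == 1.0)

    def test_duplicated_dataset_identical_curve(self):
        t, e = [1, 3, 5, 7], [1, 0, 1, 1]
        a = km_estimate(t, e)["all"]
        b = km_estimate(t + t, e + e)["all"]
        pd.testing.assert_frame_equal(a, b)

    def test_curve_is_monotone_from_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 40)
        e = rng.integers(0, 2, 40)
        km = km_estimate(t, e)["all"]
        s = km["survival"].to_numpy()
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        stat, p = logrank_test([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1],
                               ["a", "a", "a", "b", "b", "b"])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        # groups: A times (1, 3, 5) all events; B times (2, 4, 6) all events
        t = [1, 3, 5, 2, 4, 6]
        e = [1] * 6
        g = ["A"] * 3 + ["B"] * 3
        # hand: O_A = 3; E_A = 3/6+2/5+2/4+1/3+1/2 (risk-set shares at A's/all event times)
        # event times 1..6, E_A = sum n_A/n over each: 3/6+2/5+2/4+1/3+1/2+0/1
        e_a = 3 / 6 + 2 / 5 + 2 / 4 + 1 / 3 + 1 / 2
        var = (3 * 3) / 36 + (2 * 3) / 25 + (2 * 2) / 16 + (1 * 2) / 9 + (1 * 1) / 4
        expected = (3 - e_a) ** 2 / var
        stat, _p = logrank_test(t, e, g)
        assert stat == pytest.approx(expected, rel=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 30)
        e = rng.integers(0, 2, 30)
        g = rng.integers(0, 2, 30)
        s1, p1 = logrank_test(t, e, g)
        s2, p2 = logrank_test(t, e, 1 - g)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_trend_test_null_and_graded_effect(self):
        rng = np.random.default_rng(2)
        n = 150
        groups = rng.integers(0, 3, n)
        t_null = rng.exponential(5, n)
        e = (t_null < 10).astype(int)
        chi2, p = logrank_trend_test(np.minimum(t_null, 10), e, groups)
        assert p > 0.01
        t_trend = rng.exponential(1.0 / (0.05 * 3.0 ** groups))
        e2 = (t_trend < 10).astype(int)
        chi2t, pt = logrank_trend_test(np.minimum(t_trend, 10), e2, groups)
        assert pt < 0.01


class TestCox:
    def test_single_covariate_matches_partial_likelihood_grid(self):
        """6-subject fit equals brute-force 1-D maximization (Breslow)."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1, 0, 1, 0, 1, 0])

        def neg_pl(beta):
            # Breslow partial likelihood with no ties on this data
            ll = 0.0
            for i in range(6):
                if e[i] == 1:
                    risk = t >= t[i]
                    ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        from scipy.optimize import minimize_scalar

        res = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        fit = cox_fit(pd.DataFrame({"x": x}), t, e, horizon_years=None)
        assert fit.cox[0].coef == pytest.approx(res.x, abs=1e-6)

    def test_constant_covariate_excluded_with_warning(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 0, 1]
        X = pd.DataFrame({"c": [1, 1, 1, 1], "x": [0, 1, 0, 1]})
        with pytest.warns(UserWarning, match="constant"):
            fit = cox_fit(X, t, e, horizon_years=None)
        assert [r.covariate for r in fit.cox] == ["x"]

    def test_null_covariate_ci_coverage(self):
        """A covariate independent of hazard: 95% CI covers HR=1 ~95% of the time."""
        rng = np.random.default_rng(3)
        covered = 0
        reps = 60
        for _ in range(reps):
            n = 120
            x = rng.integers(0, 2, n)
            t = rng.exponential(5, n)
            e = (t < 10).astype(int)
            fit = cox_fit(pd.DataFrame({"x": x}), np.minimum(t, 10), e,
                          horizon_years=None)
            row = fit.cox[0]
            covered += row.ci_low <= 1.0 <= row.ci_high
        assert covered >= int(0.85 * reps)

    def test_horizon_censors_late_deaths(self):
        t, e = apply_horizon([4.0, 11.0, 12.0], [1, 1, 0], 10.0)
        np.testing.assert_allclose(t, [4.0, 10.0, 10.0])
        np.testing.assert_array_equal(e, [1, 0, 0])

    def test_sign_agrees_with_logrank_direction(self, small_cohort):
        cfg, _p, _m, clinical, truth = small_cohort
        marker = truth.and_marker(["G-16p", "G-17q"])
        df = clinical.data
        fit = cox_fit(pd.DataFrame({"m": marker}), df["survival_years"], df["event"])
        assert fit.cox[0].coef > 0  # carriers die faster by construction


class TestCombinedMarkers:
    def test_conjunction_truth_table(self):
        m = pd.DataFrame({"A": [1, 1, 0, 0], "B": [1, 0, 1, 0]})
        np.testing.assert_array_equal(combined_marker(m, ["A", "B"]), [1, 0, 0, 0])

    def test_three_level_sizes_sum_to_n(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame({"A": rng.integers(0, 2, 30), "B": rng.integers(0, 2, 30)})
        levels = three_level_groups(m, ["A", "B"])
        assert len(levels) == 30
        assert set(levels) <= {0, 1, 2}

    def test_and_marker_beats_singles_on_planted_interaction(self):
        """With a planted joint-carriage hazard, the AND marker separates
        survival at least as sharply as either single marker in most replicates."""
        from rarseek.simulate import default_config, simulate_cohort

        wins = 0
        reps = 20
        for seed in range(reps):
            cfg = default_config(seed=100 + seed, chromosomes=("16", "17"),
                                 n_samples=120, n_stageI=28)
            _p, _m, clinical, truth = simulate_cohort(cfg)
            df = clinical.data
            t, e = apply_horizon(df["survival_years"], df["event"], 10)
            a = truth.marker_vector("G-16p")
            b = truth.marker_vector("G-17q")
            both = truth.and_marker(["G-16p", "G-17q"])
            if both.sum() in (0, len(both)):
                continue
            _, p_a = logrank_test(t, e, a)
            _, p_b = logrank_test(t, e, b)
            _, p_ab = logrank_test(t, e, both)
            wins += p_ab <= min(p_a, p_b)
        assert wins >= int(0.7 * reps)
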