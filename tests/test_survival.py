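"""Survival inference chain: each operation against an independent oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from texsurv import (
    CohortSpec,
    cox_fit,
    dichotomize,
    generate_cohort,
    km_estimate,
    levene_test,
    logrank_test,
    mann_whitney,
    optimal_cutoff,
    roc_auc,
    spearman_corr,
    spearman_matrix,
)


class TestLevene:
    def test_identical_groups_give_zero_statistic(self):
        g = np.array([1.0, 2.0, 5.0, 9.0])
        stat, p = levene_test([g, g.copy()])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_anova_on_absolute_deviations(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([10.0, 20.0, 30.0])
        stat, _ = levene_test([a, b])
        # one-way ANOVA F on |x - group mean| computed from first principles
        za, zb = np.abs(a - a.mean()), np.abs(b - b.mean())
        grand = np.concatenate([za, zb]).mean()
        ss_between = 3 * (za.mean() - grand) ** 2 + 3 * (zb.mean() - grand) ** 2
        ss_within = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
        f_hand = (ss_between / 1) / (ss_within / 4)
        assert stat == pytest.approx(f_hand)

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(1000):
            groups = [rng.normal(size=15) for _ in range(3)]
            _, p = levene_test(groups)
            rejections += p < 0.05
        assert 35 <= rejections <= 65

    def test_short_group_rejected(self):
        with pytest.raises(ValueError):
            levene_test([np.array([1.0]), np.array([1.0, 2.0])])


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        assert mann_whitney([1, 2], [3, 4]).u_statistic == 0.0

    def test_exact_p_by_enumeration(self):
        r = mann_whitney([1, 3], [2, 4])
        assert r.exact
        assert r.p_value == pytest.approx(2.0 / 3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_group_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=9), rng.normal(size=14)
        r1, r2 = mann_whitney(a, b), mann_whitney(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r2.u_statistic == pytest.approx(len(a) * len(b) - r1.u_statistic)

    def test_degenerate_all_identical(self):
        r = mann_whitney([5, 5, 5], [5, 5])
        assert r.degenerate and r.p_value == 1.0


class TestRocAuc:
    def test_perfect_and_uninformative(self):
        assert roc_auc([1, 2, 10, 20], [1, 1, 0, 0]) == 1.0
        assert roc_auc([7, 7, 7, 7], [1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_equals_pairwise_mann_whitney_fraction(self):
        """AUC == (#(death < survivor) + 0.5 #ties) / (n1 n2), brute force."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            n1, n2 = rng.integers(3, 15, size=2)
            deaths = rng.integers(0, 8, size=n1).astype(float)
            survs = rng.integers(0, 8, size=n2).astype(float)
            values = np.concatenate([deaths, survs])
            labels = np.r_[np.ones(n1, int), np.zeros(n2, int)]
            pairs = [
                1.0 if d < s else (0.5 if d == s else 0.0)
                for d in deaths for s in survs
            ]
            oracle = np.sum(pairs) / (n1 * n2)
            assert roc_auc(values, labels) == pytest.approx(oracle, abs=1e-12)


def cutoff_scan_oracle(values, labels):
    """Exhaustive scan over observed values; larger cutoff wins ties on J."""
    best_j, best_c = -np.inf, None
    deaths = values[labels == 1]
    survs = values[labels == 0]
    for c in sorted(set(values)):
        j = np.mean(deaths < c) + np.mean(survs >= c) - 1.0
        if j >= best_j - 1e-12:
            if j > best_j + 1e-12 or c > best_c:
                best_j, best_c = max(best_j, j), c
    return best_c, best_j


class TestOptimalCutoff:
    def test_perfect_separation_with_tie_break(self):
        r = optimal_cutoff([1, 2, 10, 20], [1, 1, 0, 0])
        assert r.youden_j == pytest.approx(1.0)
        assert r.cutoff == 10.0  # largest cutoff attaining J = 1

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(8, 40))
            values = rng.integers(0, 12, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            r = optimal_cutoff(values, labels)
            c, j = cutoff_scan_oracle(values, labels)
            assert r.cutoff == c
            assert r.youden_j == pytest.approx(j)

    def test_null_youden_moderate_at_cohort_size(self):
        """Optimized J on label-independent values stays modest (n = 98)."""
        rng = np.random.default_rng(31)
        js = []
        for _ in range(500):
            values = rng.normal(size=98)
            labels = np.r_[np.ones(41, int), np.zeros(57, int)]
            rng.shuffle(labels)
            js.append(optimal_cutoff(values, labels).youden_j)
        assert np.mean(js) < 0.35


class TestDichotomize:
    def test_strict_less_than_convention(self):
        r = dichotomize(np.array([66.78, 66.79, 66.80]), 66.79)
        assert list(r.labels) == ["low", "high", "high"]
        assert (r.n_low, r.n_high) == (1, 2)

    def test_empty_group_flagged(self):
        r = dichotomize(np.array([1.0, 2.0, 3.0]), 10.0)
        assert r.has_empty_group and r.n_high == 0

    def test_counts_conserved_with_missing(self):
        vals = np.array([1.0, np.nan, 3.0, np.nan, 5.0])
        r = dichotomize(vals, 4.0)
        assert r.n_low + r.n_high + r.n_missing == len(vals)
        assert r.n_missing == 2


class TestKaplanMeier:
    def test_hand_product_limit_example(self):
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1) == pytest.approx(2.0 / 3.0)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_no_events_flat_curve(self):
        km = km_estimate([5, 10, 15], [0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_all_events_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, size=40).round(2) + 0.01
        km = km_estimate(times, np.ones_like(times, dtype=int))
        for t in np.unique(times):
            assert km.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_curve_monotone_in_unit_interval(self):
        rng = np.random.default_rng(4)
        km = km_estimate(rng.exponential(10, 50) + 0.1, rng.integers(0, 2, 50))
        assert km.survival[0] == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))

    def test_late_censored_subjects_add_no_steps(self):
        """Censoring beyond the last event adds no drops and leaves the
        tail flat (the drop times are exactly the event times)."""
        t = [2.0, 4.0, 6.0]
        e = [1, 1, 1]
        base = km_estimate(t, e)
        extended = km_estimate(t + [50.0, 60.0], e + [0, 0])
        drops = extended.timeline[
            np.r_[False, np.diff(extended.survival) < 0]
        ]
        base_drops = base.timeline[np.r_[False, np.diff(base.survival) < 0]]
        assert np.array_equal(drops, base_drops)
        assert extended.survival_at(70.0) == extended.survival_at(6.0)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        r = logrank_test(t, e, list(t), list(e))
        assert r.chi_square == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_hand_tabulation(self):
        """A events at 1,2; B events at 3,4: chi2 = (O-E)^2 / V by hand."""
        # t=1: risk 2+2, O_A=1, E_A=1/2, V=1*2*2*3/(16*3)=1/4
        # t=2: risk 1+2, O_A=1, E_A=1/3, V=1*1*2*2/(9*2)=2/9
        # t=3,4: A exhausted, E_A=V=0
        chi2_hand = (2 - (0.5 + 1 / 3)) ** 2 / (0.25 + 2 / 9)
        r = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert r.chi_square == pytest.approx(chi2_hand, abs=1e-10)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_permutation_null_calibration(self):
        """Rejection rate at alpha=0.05 stays within [3.5%, 6.5%] (n=60)."""
        rng = np.random.default_rng(17)
        times = rng.exponential(20, size=60) + 0.01
        events = (rng.random(60) < 0.7).astype(int)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            perm = rng.permutation(60)
            ia, ib = perm[:30], perm[30:]
            r = logrank_test(times[ia], events[ia], times[ib], events[ib])
            rejections += r.p_value < 0.05
        assert 0.035 * n_rep <= rejections <= 0.065 * n_rep


def cox_partial_loglik(beta, times, events, x):
    """Explicit tie-free partial log-likelihood (oracle)."""
    ll = 0.0
    for i in np.flatnonzero(events):
        at_risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


class TestCoxFit:
    @pytest.fixture
    def tie_free_data(self):
        rng = np.random.default_rng(41)
        n = 20
        x = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(10 / np.exp(0.8 * x))
        e = (rng.random(n) < 0.8).astype(int)
        t = np.round(t, 6)
        assert len(np.unique(t)) == n  # tie-free by construction
        return pd.DataFrame({"os_months": t, "event": e, "x": x})

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame(
            {"os_months": [1.0, 2.0, 3.0], "event": [1, 1, 1], "x": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["x"])

    def test_beta_matches_grid_search_of_partial_likelihood(self, tie_free_data):
        df = tie_free_data
        fit = cox_fit(df, ["x"])
        grid = np.arange(-5.0, 5.0, 1e-4)
        ll = [
            cox_partial_loglik(b, df["os_months"].values, df["event"].values,
                               df["x"].values)
            for b in grid
        ]
        beta_oracle = grid[int(np.argmax(ll))]
        assert fit.summary.loc["x", "beta"] == pytest.approx(beta_oracle, abs=1e-3)

    def test_hazard_ratio_consistency(self, tie_free_data):
        fit = cox_fit(tie_free_data, ["x"])
        row = fit.summary.loc["x"]
        assert row["hr"] == pytest.approx(np.exp(row["beta"]))
        assert row["ci_low"] < row["hr"] < row["ci_high"]

    def test_binary_label_swap_antisymmetry(self, tie_free_data):
        df = tie_free_data
        fit1 = cox_fit(df, ["x"])
        df2 = df.assign(x=1.0 - df["x"])
        fit2 = cox_fit(df2, ["x"])
        assert fit2.summary.loc["x", "beta"] == pytest.approx(
            -fit1.summary.loc["x", "beta"], abs=1e-6
        )

    def test_logrank_equals_cox_score_test_without_ties(self, tie_free_data):
        """Log-rank chi-square == U(0)^2 / I(0) of the Cox score (tie-free)."""
        df = tie_free_data
        t, e, x = df["os_months"].values, df["event"].values, df["x"].values
        u = i_info = 0.0
        for i in np.flatnonzero(e):
            risk = t >= t[i]
            xbar = x[risk].mean()  # beta=0: weights uniform on the risk set
            u += x[i] - xbar
            i_info += np.mean((x[risk] - xbar) ** 2)
        score_chi2 = u**2 / i_info
        lr = logrank_test(t[x == 1], e[x == 1], t[x == 0], e[x == 0])
        assert lr.chi_square == pytest.approx(score_chi2, abs=1e-6)

    def test_ci_coverage_on_simulated_cohorts(self):
        """Wald 95% CI covers the true HR 3.0 in >= 90/100 replicates."""
        covered = 0
        for rep in range(100):
            spec = CohortSpec(n_subjects=500, log_hr_feature=np.log(3.0),
                              log_hr_m1=0.0, seed=5000 + rep)
            c = generate_cohort(spec)
            c["low"] = (c["true_group"] == "low").astype(float)
            fit = cox_fit(c, ["low"])
            lo, hi = fit.ci("low")
            covered += lo <= 3.0 <= hi
        assert covered >= 90


class TestSpearman:
    def test_self_and_negation(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert spearman_corr(x, x).rho == pytest.approx(1.0)
        assert spearman_corr(x, -x).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        x, y = np.array([1.0, 2.0, 3.0, 4.0]), np.array([2.0, 1.0, 4.0, 3.0])
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]  # = 0.6 by hand
        r = spearman_corr(x, y)
        assert oracle == pytest.approx(0.6)
        assert r.rho == pytest.approx(oracle)

    def test_constant_feature_flagged(self):
        r = spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert r.rho is None

    def test_matrix_covers_all_pairs(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        entries = spearman_matrix(df)
        pairs = {(e.feature_a, e.feature_b) for e in entries}
        assert pairs == set(itertools.combinations("abcd", 2))
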