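from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from porocoil.cohort import GeneratorConfig, generate_cohort
from porocoil.stats import (
    binormal_auc,
    bonferroni,
    empirical_roc,
    logistic_fit,
    mann_whitney,
    welch_t_from_summary,
)


class TestWelch:
    def test_predictor_group_difference_from_summaries(self):
        # published group summaries for the first-coil packing density
        r = welch_t_from_summary(18.28, 4.16, 55, 10.51, 2.83, 11)
        assert r.statistic == pytest.approx(7.61, abs=0.01)
        assert r.p_value < 0.001

    def test_identical_groups(self):
        r = welch_t_from_summary(5.0, 1.0, 20, 5.0, 1.0, 20)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1.0, 1.0, 1, 2.0, 1.0, 10)


class TestMannWhitney:
    def test_fully_separated_matches_exact_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [10.0, 11.0, 12.0, 13.0]
        r = mann_whitney(x, y)
        # brute force: P(U <= 0) over all rank assignments, two-sided
        n1, n2 = len(x), len(y)
        count_extreme = 0
        total = 0
        for ranks_x in combinations(range(n1 + n2), n1):
            u = sum(ranks_x) - n1 * (n1 - 1) // 2
            total += 1
            if u <= 0 or u >= n1 * n2:
                count_extreme += 1
        assert r.p_value == pytest.approx(count_extreme / total)

    def test_identical_samples_half_u(self):
        x = np.arange(1.0, 9.0)
        r = mann_whitney(x, x.copy())
        assert r.statistic == pytest.approx(len(x) ** 2 / 2)

    def test_all_tied_flagged(self):
        r = mann_whitney([1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.p_value == 1.0
        assert "tied" in r.note


class TestBinormalAUC:
    def test_equal_means_is_chance(self):
        assert binormal_auc(5.0, 1.0, 5.0, 2.0) == pytest.approx(0.5)

    def test_published_summary_auc(self):
        auc = binormal_auc(18.28, 4.16, 10.51, 2.83)
        assert round(auc, 2) == pytest.approx(0.94)
        assert auc == pytest.approx(0.9387, abs=1e-3)

    def test_vanishing_spread_limit(self):
        assert binormal_auc(2.0, 1e-12, 1.0, 1e-12) == pytest.approx(1.0)


class TestEmpiricalROC:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        r = empirical_roc(scores, labels, ci=False)
        assert r.auc == pytest.approx(1.0)
        assert r.sens_at_cutoff == 1.0 and r.spec_at_cutoff == 1.0

    def test_independent_scores_near_chance(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        r = empirical_roc(scores, labels, ci=False)
        assert r.auc == pytest.approx(0.5, abs=0.03)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=300)
        labels = (scores + rng.normal(scale=1.0, size=300) > 0).astype(int)
        a = empirical_roc(scores, labels, ci=False)
        b = empirical_roc(np.exp(3 * scores), labels, ci=False)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_matches_sklearn_and_mann_whitney_identity(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(1.0, 1.0, 40)
        neg = rng.normal(0.0, 1.0, 60)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(40, int), np.zeros(60, int)]
        r = empirical_roc(scores, labels, direction="greater", ci=False)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        u = mann_whitney(pos, neg).statistic
        assert r.auc == pytest.approx(u / (40 * 60), abs=1e-12)

    def test_youden_cutoff_maximizes_j(self):
        rng = np.random.default_rng(3)
        scores = np.r_[rng.normal(2, 1, 50), rng.normal(0, 1, 50)]
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        r = empirical_roc(scores, labels, ci=False)
        j = r.sensitivity + r.specificity - 1.0
        assert np.max(j) == pytest.approx(r.sens_at_cutoff + r.spec_at_cutoff - 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1.0, 2.0], [1, 1])

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(1.5, 1, 30), rng.normal(0, 1, 70)]
        labels = np.r_[np.ones(30, int), np.zeros(70, int)]
        r = empirical_roc(scores, labels, n_boot=500, seed=5)
        lo, hi = r.auc_ci
        assert lo <= r.auc <= hi


class TestBonferroni:
    def test_adjustment_and_clipping(self):
        adj = bonferroni([0.002, 0.2, 1.0], m=19)
        assert adj[0] == pytest.approx(0.038)
        assert adj[1] == 1.0 and adj[2] == 1.0

    def test_m_one_identity(self):
        assert bonferroni([0.3], m=1)[0] == pytest.approx(0.3)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], m=5)


class TestLogistic:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(10)
        n = 5000
        x = rng.normal(size=n)
        eta = 0.4 - 0.7 * x
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        t = fit.term("x")
        assert abs(t.coef - (-0.7)) < 3 * t.se

    def test_null_coverage(self):
        rng = np.random.default_rng(11)
        n, reps, covered = 300, 200, 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rng.integers(0, 2, size=n)
            t = logistic_fit(pd.DataFrame({"x": x}), y).term("x")
            if t.or_ci[0] <= 1.0 <= t.or_ci[1]:
                covered += 1
        assert covered / reps > 0.90

    def test_intercept_only_balanced(self):
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        fit = logistic_fit(pd.DataFrame(index=range(100)), y)
        assert fit.term("const").coef == pytest.approx(0.0, abs=1e-8)

    def test_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.separation_flag

    def test_backward_stepwise_drops_noise(self):
        rng = np.random.default_rng(13)
        n = 2000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        eta = -0.9 * x1
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = logistic_fit(pd.DataFrame({"x1": x1, "x2": x2}), y, stepwise=True)
        names = {t.name for t in fit.terms}
        assert "x1" in names and "x2" not in names


def test_pipeline_auc_matches_binormal_surrogate():
    # empirical AUC on a large synthetic cohort vs the closed form
    frame = generate_cohort(GeneratorConfig(n_recan=100_000, n_no_recan=100_000, seed=21))
    labels = (frame["group"] == "recanalization").astype(int).to_numpy()
    r = empirical_roc(frame["first_vpd_pct"].to_numpy(), labels, ci=False)
    assert r.auc == pytest.approx(binormal_auc(18.28, 4.16, 10.51, 2.83), abs=0.01)
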