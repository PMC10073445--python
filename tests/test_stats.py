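"""Statistics layer: correlation, ROC/Youden, survival, group comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qspect.cohort import CohortConfig, simulate_cohort
from qspect.stats import (
    compare_groups,
    cox_regression,
    km_logrank,
    pearson,
    roc_with_youden,
    severity_strata_report,
)


# ---------------------------------------------------------------------------
# independent oracles

def roc_oracle(scores, labels):
    """Brute-force AUC (concordant-pair count) and Youden cutoff search."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    auc_higher = conc / (len(pos) * len(neg))
    direction = "higher" if auc_higher >= 0.5 else "lower"
    auc = auc_higher if direction == "higher" else 1 - auc_higher
    oriented = scores if direction == "higher" else -scores
    uniq = sorted(set(oriented))
    cands = [(a + b) / 2 for a, b in zip(uniq, uniq[1:])] or [uniq[0]]
    best = None
    for c in cands:
        pred = oriented > c
        sens = np.mean(pred[labels == 1]) if (labels == 1).any() else 0.0
        spec = np.mean(~pred[labels == 0])
        j = sens + spec - 1
        rep = c if direction == "higher" else -c
        key = (-j, -sens, rep)
        if best is None or key < best[0]:
            best = (key, rep, j, sens, spec)
    return auc, best[1], best[2]


def logrank_oracle(times, events, groups):
    """Hand-computed two-group log-rank chi-square (1 df)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labs = np.unique(groups)
    o_a = e_a = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (groups == labs[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (groups == labs[0])).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (o_a - e_a) ** 2 / var


def cox_partial_loglik(beta, x, times, events):
    """Risk-set product partial log-likelihood, single covariate, no ties."""
    ll = 0.0
    for i in np.argsort(times):
        if events[i]:
            risk = times >= times[i]
            ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


# ---------------------------------------------------------------------------

class TestPearson:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        res = pearson(x, -x)
        assert res.r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        r_or = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        res = pearson(x, y)
        assert res.r == pytest.approx(r_or, abs=1e-12)
        assert res.ci95[0] <= res.r <= res.ci95[1]

    def test_cohort_correlation_near_design_target(self):
        df = simulate_cohort(CohortConfig(n=5000, seed=3))
        res = pearson(df["qlu_pct"], df["meld"])
        assert res.r == pytest.approx(-0.743, abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestROC:
    def test_perfect_separation(self):
        res = roc_with_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert res.ppv == 100.0 and res.npv == 100.0 and res.accuracy == 100.0
        assert 3 < res.cutoff < 10

    def test_independent_labels_give_null_auc(self, rng):
        scores = rng.standard_normal(4000)
        labels = rng.integers(0, 2, 4000)
        res = roc_with_youden(scores, labels)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_oracle_on_small_datasets(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 13))
            scores = np.round(rng.standard_normal(n), 1)  # provoke ties
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            auc_or, cut_or, j_or = roc_oracle(scores, labels)
            res = roc_with_youden(scores, labels)
            assert res.auc == pytest.approx(auc_or, abs=1e-12)
            assert res.youden_j == pytest.approx(j_or, abs=1e-12)
            assert res.cutoff == pytest.approx(cut_or, abs=1e-12)

    def test_auc_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = np.round(rng.standard_normal(200), 1)
        labels = (rng.standard_normal(200) + scores > 0).astype(int)
        res = roc_with_youden(scores, labels, direction="higher")
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_youden_cutoff_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(1.0, 5.0, 40)
        labels = (scores + rng.standard_normal(40) > 3).astype(int)
        a = roc_with_youden(scores, labels)
        b = roc_with_youden(np.exp(scores), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        # same cases classified positive at the respective cutoffs
        np.testing.assert_array_equal(a.predict(scores), b.predict(np.exp(scores)))

    def test_direction_auto_flips_falling_markers(self):
        res = roc_with_youden([40.0, 35.0, 30.0, 15.0, 12.0, 10.0], [0, 0, 0, 1, 1, 1])
        assert res.direction == "lower"
        assert res.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_with_youden([1.0, 2.0], [1, 1])

    @settings(derandomize=True, max_examples=40)
    @given(data=st.lists(st.tuples(st.integers(-20, 20), st.booleans()),
                         min_size=4, max_size=20))
    def test_auc_bounds_and_complement_symmetry(self, data):
        scores = np.array([s for s, _ in data], dtype=float)
        labels = np.array([int(l) for _, l in data])
        if labels.sum() in (0, len(labels)):
            return
        res = roc_with_youden(scores, labels)
        assert 0.5 <= res.auc <= 1.0
        assert -1.0 <= res.youden_j <= 1.0
        flipped = roc_with_youden(-scores, labels)
        assert flipped.auc == pytest.approx(res.auc, abs=1e-12)


class TestKaplanMeierLogrank:
    def test_no_censoring_matches_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        fit = km_logrank(times, [1] * 5, ["g"] * 5)
        curve = fit.km_curves["g"]
        for i, t in enumerate(times, start=1):
            assert fit.km_survival_at("g", t) == pytest.approx((5 - i) / 5)

    def test_identical_groups_give_zero_statistic(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 0, 1, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        fit = km_logrank(times, events, groups)
        assert fit.logrank_stat == pytest.approx(0.0, abs=1e-9)

    def test_six_subject_toy_matches_hand_oracle(self):
        times = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        events = [1, 1, 1, 1, 1, 1]
        groups = ["a", "a", "a", "b", "b", "b"]
        fit = km_logrank(times, events, groups)
        assert fit.logrank_stat == pytest.approx(
            logrank_oracle(times, events, groups), rel=1e-9)

    def test_requires_an_event(self):
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [0, 0], ["a", "b"])


class TestCox:
    def test_identical_groups_hr_near_one(self, rng):
        # the same 500 subjects duplicated into both covariate groups: the
        # partial likelihood is symmetric, so the HR estimate sits at ~1
        n = 500
        t = rng.exponential(10.0, n)
        e = (t <= 12).astype(int)
        t = np.minimum(t, 12.0)
        x = np.concatenate([np.zeros(n), np.ones(n)])
        fit = cox_regression(pd.DataFrame({"x": x}),
                             np.concatenate([t, t]), np.concatenate([e, e]))
        assert abs(math.log(fit.cox[0].hazard_ratio)) < 0.05

    def test_partial_likelihood_maximized_at_fit(self, rng):
        n = 30
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.8 * x))
        t += rng.uniform(0, 1e-6, n)  # ensure no ties
        e = np.ones(n, int)
        fit = cox_regression(pd.DataFrame({"x": x}), t, e)
        beta = fit.cox[0].coef
        ll_hat = cox_partial_loglik(beta, x, t, e)
        for delta in (-0.05, 0.05):
            assert cox_partial_loglik(beta + delta, x, t, e) < ll_hat + 1e-9

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant covariate"):
            cox_regression(pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}),
                           [1, 2, 3, 4], [1, 1, 1, 0])

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_regression(pd.DataFrame({"x": [0.0, 1.0, 0.0]}), [1, 2, 3], [1, 0, 0])


class TestGroupComparison:
    def test_identical_paired_vectors(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_groups(a, a, paired=True)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_welch_matches_closed_form(self, rng):
        a = rng.standard_normal(20) + 0.5
        b = rng.standard_normal(25)
        res = compare_groups(a, b)
        se = math.sqrt(a.var(ddof=1) / 20 + b.var(ddof=1) / 25)
        assert res.statistic == pytest.approx((a.mean() - b.mean()) / se, rel=1e-12)

    def test_paired_shift_detected_reliably(self, rng):
        # +5.1 %QLU mean shift at n=68 with change SD 6.0: detected at p<0.05
        # in at least 95% of replicates
        hits = 0
        reps = 100
        for _ in range(reps):
            base = 26.1 + 10.6 * rng.standard_normal(68)
            follow = base + 5.1 + 6.0 * rng.standard_normal(68)
            if compare_groups(base, follow, paired=True).p < 0.05:
                hits += 1
        assert hits / reps >= 0.95

    def test_rank_alternatives_run(self, rng):
        a, b = rng.standard_normal(15), rng.standard_normal(15) + 1
        assert compare_groups(a, b, method="u").p < 1.0
        assert compare_groups(a, b, paired=True, method="u").test == "Wilcoxon signed-rank"


class TestStrataReport:
    def test_generator_round_trip_and_roc_composition(self):
        from qspect.cohort import get_preset
        df = simulate_cohort(get_preset("table1_strata", n=3000, seed=5))
        rep = severity_strata_report(df)
        c_mean = rep["strata"]["CTP-C"]["qlu_pct"]["mean"]
        assert c_mean == pytest.approx(15.9, abs=1.0)
        # ROC block equals a direct call on the same dichotomy
        sub = df[df["ctp_class"].isin(["A", "B"])]
        direct = roc_with_youden(sub["qlu_pct"].to_numpy(),
                                 (sub["ctp_class"] == "B").astype(int).to_numpy())
        assert rep["roc"]["CTP_A_vs_B"]["qlu_pct"]["auc"] == pytest.approx(direct.auc)
        assert rep["roc"]["CTP_A_vs_B"]["qlu_pct"]["cutoff"] == pytest.approx(direct.cutoff)
        assert rep["anova"]["qlu_pct"]["p"] < 1e-6

    def test_missing_stratum_is_reported(self):
        df = simulate_cohort(CohortConfig(n=200, seed=6))
        only_b = df[df["ctp_class"] == "B"]
        with pytest.raises(ValueError, match="missing CTP stratum"):
            severity_strata_report(only_b)
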