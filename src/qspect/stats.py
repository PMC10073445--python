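"""Prognostic statistics: correlation, ROC/Youden, survival, group tests.

This layer mirrors a clinical-imaging evaluation workflow: Pearson
correlations between imaging markers and severity scores, ROC curves with
Youden-optimal cutoffs and the full confusion-matrix metrics, Kaplan-Meier /
log-rank survival comparison, Cox proportional-hazards regression, and
paired/unpaired group tests.  Survival fitting delegates to lifelines
(Breslow tie handling); ROC/Youden and the Fisher-z confidence interval are
implemented here with the exact tie-break rules documented on each function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test

__all__ = [
    "CorrelationResult",
    "ROCResult",
    "SurvivalFit",
    "CoxCovariate",
    "GroupComparison",
    "pearson",
    "roc_with_youden",
    "km_logrank",
    "cox_regression",
    "compare_groups",
    "severity_strata_report",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    ci95: tuple[float, float]
    n: int


def pearson(x, y) -> CorrelationResult:
    """Pearson r with a two-sided t-test p-value and Fisher-z 95% CI.

    The CI is tanh(atanh(r) +/- 1.96 / sqrt(n-3)); for n <= 3 it degenerates
    to (-1, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = _sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        half = _sps.norm.ppf(0.975) / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (-1.0, 1.0)
    return CorrelationResult(r=r, p=p, ci95=ci, n=n)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    cutoff: float
    direction: str  # "higher" = larger scores predict the positive class
    sensitivity: float  # %
    specificity: float  # %
    ppv: float  # %
    npv: float  # %
    accuracy: float  # %
    youden_j: float
    n_positive: int
    n_negative: int

    def predict(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return s > self.cutoff if self.direction == "higher" else s < self.cutoff


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation, half credit for ties."""
    ranks = _sps.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def roc_with_youden(scores, labels, direction: str = "auto") -> ROCResult:
    """ROC analysis with the Youden-optimal cutoff.

    AUC uses the rank (pairwise-concordance) formulation with half credit
    for ties.  ``direction`` is chosen automatically so AUC >= 0.5 (severity
    markers that *fall* with disease get ``"lower"``) and is recorded on the
    result.  Cutoff candidates are the midpoints between adjacent distinct
    scores; the one maximizing Youden's J wins, with ties broken toward
    higher sensitivity and then toward the lower cutoff value.  A case is
    called positive when its score is strictly beyond the cutoff in the
    chosen direction.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    auc_higher = _rank_auc(s, y)
    if direction == "auto":
        direction = "higher" if auc_higher >= 0.5 else "lower"
    elif direction not in ("higher", "lower"):
        raise ValueError("direction must be 'auto', 'higher' or 'lower'")
    auc = auc_higher if direction == "higher" else 1.0 - auc_higher
    oriented = s if direction == "higher" else -s
    uniq = np.unique(oriented)
    if uniq.size == 1:
        candidates = uniq  # all scores tie; J = 0 everywhere
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    # candidate x case matrix of predictions: positive when beyond cutoff
    pred = oriented[None, :] > candidates[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    tn = (~pred & (y == 0)).sum(axis=1)
    sens = tp / n1
    spec = tn / n0
    jj = sens + spec - 1.0
    # ties in J -> higher sensitivity -> lower reported cutoff
    reported = candidates if direction == "higher" else -candidates
    order = np.lexsort((reported, -sens, -jj))
    best = order[0]
    fp = n0 - tn[best]
    fn = n1 - tp[best]
    ppv = 100.0 * tp[best] / (tp[best] + fp) if (tp[best] + fp) > 0 else math.nan
    npv = 100.0 * tn[best] / (tn[best] + fn) if (tn[best] + fn) > 0 else math.nan
    return ROCResult(
        auc=float(auc),
        cutoff=float(reported[best]),
        direction=direction,
        sensitivity=100.0 * float(sens[best]),
        specificity=100.0 * float(spec[best]),
        ppv=float(ppv),
        npv=float(npv),
        accuracy=100.0 * float((tp[best] + tn[best]) / (n1 + n0)),
        youden_j=float(jj[best]),
        n_positive=n1,
        n_negative=n0,
    )


@dataclass(frozen=True)
class CoxCovariate:
    name: str
    coef: float
    hazard_ratio: float
    ci95: tuple[float, float]
    p: float


@dataclass
class SurvivalFit:
    km_curves: dict = field(default_factory=dict)  # label -> DataFrame(time, survival)
    logrank_stat: float | None = None
    logrank_p: float | None = None
    cox: list[CoxCovariate] = field(default_factory=list)

    def km_survival_at(self, label, t: float) -> float:
        """Step-function evaluation of one group's KM curve at time t."""
        curve = self.km_curves[label]
        idx = np.searchsorted(curve["time"].to_numpy(), t, side="right") - 1
        return float(curve["survival"].iloc[idx]) if idx >= 0 else 1.0


def km_logrank(times, events, groups) -> SurvivalFit:
    """Kaplan-Meier curves per group plus the log-rank test.

    Two groups give the classic 1-df chi-square; more groups fall back to
    the k-sample log-rank.  Every group must be non-empty and at least one
    event must occur overall.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    g = np.asarray(groups)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if e.sum() < 1:
        raise ValueError("need at least one event")
    labels = pd.unique(g)
    fit = SurvivalFit()
    for lab in labels:
        sel = g == lab
        if not sel.any():
            raise ValueError(f"empty group {lab!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        sf = kmf.survival_function_
        fit.km_curves[lab] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    if len(labels) == 2:
        sel = g == labels[0]
        res = logrank_test(t[sel], t[~sel], e[sel], e[~sel])
        fit.logrank_stat = float(res.test_statistic)
        fit.logrank_p = float(res.p_value)
    elif len(labels) > 2:
        res = multivariate_logrank_test(t, g, e)
        fit.logrank_stat = float(res.test_statistic)
        fit.logrank_p = float(res.p_value)
    return fit


def cox_regression(covariates: pd.DataFrame | np.ndarray, times, events) -> SurvivalFit:
    """Cox proportional-hazards fit (partial likelihood, Breslow ties).

    Returns per-covariate hazard ratios with Wald 95% CIs and p-values.
    Raises on degenerate input (constant covariate, <2 events) and on
    non-convergence / monotone likelihood, naming the offending covariate
    where lifelines identifies one.
    """
    X = pd.DataFrame(covariates).copy()
    X.columns = [str(c) for c in X.columns]
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if e.sum() < 2:
        raise ValueError("need at least 2 events for Cox regression")
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ValueError(f"constant covariate: {col}")
    df = X.assign(_time=t, _event=e)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as err:
        raise ValueError(f"Cox fit failed to converge: {err}") from err
    fit = SurvivalFit()
    summary = cph.summary
    for name, row in summary.iterrows():
        fit.cox.append(CoxCovariate(
            name=str(name),
            coef=float(row["coef"]),
            hazard_ratio=float(row["exp(coef)"]),
            ci95=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
            p=float(row["p"]),
        ))
    return fit


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p: float
    test: str


def compare_groups(a, b, paired: bool = False, method: str = "t") -> GroupComparison:
    """Two-group comparison.

    ``method="t"``: Welch t-test unpaired, paired t-test if ``paired``.
    ``method="u"``: Mann-Whitney U unpaired, Wilcoxon signed-rank paired.
    Two-sided p-values throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal lengths")
    if method == "t":
        if paired:
            stat, p = _sps.ttest_rel(a, b)
            name = "paired t"
        else:
            stat, p = _sps.ttest_ind(a, b, equal_var=False)
            name = "Welch t"
    elif method == "u":
        if paired:
            stat, p = _sps.wilcoxon(a, b)
            name = "Wilcoxon signed-rank"
        else:
            stat, p = _sps.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney U"
    else:
        raise ValueError("method must be 't' or 'u'")
    if math.isnan(p):  # identical paired vectors: no evidence against the null
        stat, p = 0.0, 1.0
    return GroupComparison(statistic=float(stat), p=float(p), test=name)


_STRATA_PARAMS = ("lv_mL", "qlu_pct", "idml_liver", "sv_mL", "qsu_pct",
                  "idml_spleen", "icg_r15")
_ROC_MARKERS = ("qlu_pct", "lv_mL", "icg_r15")


def severity_strata_report(cohort: pd.DataFrame,
                           meld_cut: float = 15.0) -> dict:
    """Stratified descriptive + diagnostic report for a cirrhosis cohort.

    Produces group means +/- SD of the quantitative SPECT and ICG parameters
    per CTP class (A/B/C) and per MELD stratum (<=cut vs >cut), one-way ANOVA
    p-values across CTP classes, and ROC/Youden analyses of %QLU, liver
    volume and ICG-R15 for each severity dichotomy (CTP A vs B, B vs C,
    MELD low vs high; the more severe group is the positive class).
    """
    required = {"ctp_class", "meld", *_STRATA_PARAMS}
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise ValueError(f"cohort table missing columns: {', '.join(missing)}")
    present = set(cohort["ctp_class"].unique())
    absent = sorted({"A", "B", "C"} - present)
    if absent:
        raise ValueError(f"missing CTP stratum: {', '.join(absent)}")

    report: dict = {"n": int(len(cohort)), "strata": {}, "anova": {}, "roc": {}}
    for cls in ("A", "B", "C"):
        sub = cohort[cohort["ctp_class"] == cls]
        report["strata"][f"CTP-{cls}"] = {
            "n": int(len(sub)),
            **{p: {"mean": float(sub[p].mean()), "sd": float(sub[p].std(ddof=1))}
               for p in _STRATA_PARAMS},
        }
    for label, sel in (("MELD<=%g" % meld_cut, cohort["meld"] <= meld_cut),
                       ("MELD>%g" % meld_cut, cohort["meld"] > meld_cut)):
        sub = cohort[sel]
        if len(sub) == 0:
            raise ValueError(f"missing MELD stratum: {label}")
        report["strata"][label] = {
            "n": int(len(sub)),
            **{p: {"mean": float(sub[p].mean()), "sd": float(sub[p].std(ddof=1))}
               for p in _STRATA_PARAMS},
        }
    for p in _STRATA_PARAMS:
        groups = [cohort.loc[cohort["ctp_class"] == c, p].to_numpy() for c in ("A", "B", "C")]
        stat, pval = _sps.f_oneway(*groups)
        report["anova"][p] = {"F": float(stat), "p": float(pval)}

    dichotomies = {
        "CTP_A_vs_B": (cohort["ctp_class"].isin(["A", "B"]), cohort["ctp_class"] == "B"),
        "CTP_B_vs_C": (cohort["ctp_class"].isin(["B", "C"]), cohort["ctp_class"] == "C"),
        "MELD_low_vs_high": (pd.Series(True, index=cohort.index), cohort["meld"] > meld_cut),
    }
    for name, (sel, positive) in dichotomies.items():
        sub = cohort[sel]
        labels = positive[sel].astype(int).to_numpy()
        report["roc"][name] = {}
        for marker in _ROC_MARKERS:
            res = roc_with_youden(sub[marker].to_numpy(), labels)
            report["roc"][name][marker] = {
                "auc": res.auc, "cutoff": res.cutoff, "direction": res.direction,
                "sensitivity": res.sensitivity, "specificity": res.specificity,
                "ppv": res.ppv, "npv": res.npv, "accuracy": res.accuracy,
                "youden_j": res.youden_j,
            }
    return report
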