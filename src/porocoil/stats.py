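"""Two-group tests, ROC analysis and logistic regression for cohort data.

The statistical battery applied to coil-embolization cohorts: Welch t-tests
(from raw samples or from published mean/SD/n summaries), Mann–Whitney U,
Bonferroni correction, empirical ROC curves with Youden-optimal cut-off and
bootstrap AUC confidence intervals, a closed-form binormal AUC surrogate
for when only group summaries are published, and logistic regression with
optional backward stepwise elimination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: Optional[float]
    p_value: float
    p_adjusted: Optional[float] = None
    note: str = ""


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: Optional[tuple[float, float]]
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    direction: str  # 'greater' => higher score predicts positive class


def welch_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TestResult:
    """Welch two-sample t-test from group summaries (mean, SD, n).

    Uses the Satterthwaite degrees of freedom; two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be positive")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=float(p))


def mann_whitney(x_samples, y_samples) -> TestResult:
    """Mann–Whitney U test: exact for combined n <= 20, else the normal
    approximation with tie correction.  All-tied data returns p = 1 flagged.
    """
    x = np.asarray(x_samples, dtype=float)
    y = np.asarray(y_samples, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return TestResult(
            statistic=float(x.size * y.size / 2.0), df=None, p_value=1.0,
            note="all observations tied",
        )
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), df=None, p_value=float(res.pvalue))


def binormal_auc(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """Closed-form ROC AUC for two normal score distributions.

    AUC = Phi(|mean_pos - mean_neg| / sqrt(sd_pos^2 + sd_neg^2)); the
    standard binormal identity, usable directly from published group
    summaries when raw scores are unavailable.
    """
    if sd_pos < 0 or sd_neg < 0:
        raise ValueError("SDs must be non-negative")
    spread = np.hypot(sd_pos, sd_neg)
    if spread == 0.0:
        return 0.5 if mean_pos == mean_neg else 1.0
    return float(stats.norm.cdf(abs(mean_pos - mean_neg) / spread))


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    """Sens/spec at every unique-score threshold, rule score >= thr -> positive."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    # cumulative counts at each unique threshold (last index per value)
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    last = np.r_[np.nonzero(np.diff(s))[0], y.size - 1]
    thr = s[last]
    sens = tp[last] / n_pos
    spec = 1.0 - fp[last] / n_neg
    return thr, sens, spec, n_pos, n_neg


def _auc_trapezoid(sens: np.ndarray, spec: np.ndarray) -> float:
    fpr = np.r_[0.0, 1.0 - spec, 1.0]
    tpr = np.r_[0.0, sens, 1.0]
    return float(np.trapezoid(tpr, fpr))


def empirical_roc(
    scores,
    labels,
    direction: str = "auto",
    n_boot: int = 2000,
    seed: int = 0,
    ci: bool = True,
) -> ROCResult:
    """Empirical ROC with trapezoidal AUC, Youden cut-off and bootstrap CI.

    ``labels`` are 0/1 with 1 the positive class.  ``direction`` 'greater'
    treats higher scores as positive, 'less' lower scores; 'auto' picks the
    orientation with AUC >= 0.5 (logged in the result).  The Youden cut-off
    maximizes sensitivity + specificity - 1; ties resolve to the threshold
    closest to the positive-class score mean.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size != 2 or set(classes) != {0, 1}:
        raise ValueError("labels must contain both classes coded 0/1")

    def one_direction(sc, lab, sign):
        thr, sens, spec, _, _ = _roc_points(sign * sc, lab)
        return thr * sign, sens, spec, _auc_trapezoid(sens, spec)

    if direction == "auto":
        _, _, _, auc_g = one_direction(scores, labels, +1.0)
        direction = "greater" if auc_g >= 0.5 else "less"
    sign = +1.0 if direction == "greater" else -1.0
    thr, sens, spec, auc = one_direction(scores, labels, sign)

    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())
    if best.size > 1:
        pos_mean = scores[labels == 1].mean()
        best = best[np.argmin(np.abs(thr[best] - pos_mean))]
    else:
        best = best[0]

    auc_ci = None
    if ci:
        rng = np.random.default_rng(seed)
        n = scores.size
        boot = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            lab_b = labels[idx]
            if lab_b.min() == lab_b.max():
                boot[b] = np.nan
                continue
            _, sb, pb, _, _ = _roc_points(sign * scores[idx], lab_b)
            boot[b] = _auc_trapezoid(sb, pb)
        boot = boot[np.isfinite(boot)]
        auc_ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    return ROCResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=auc_ci,
        youden_cutoff=float(thr[best]),
        sens_at_cutoff=float(sens[best]),
        spec_at_cutoff=float(spec[best]),
        direction=direction,
    )


DEFAULT_BONFERRONI_M = 19


def bonferroni(p_values, m: int = DEFAULT_BONFERRONI_M) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, m * p) for m comparisons."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


@dataclass(frozen=True)
class LogisticTerm:
    name: str
    coef: float
    se: float
    odds_ratio: float
    or_ci: tuple[float, float]
    p_value: float


@dataclass(frozen=True)
class LogisticFitResult:
    terms: tuple[LogisticTerm, ...]
    converged: bool
    separation_flag: bool
    llf: float

    def term(self, name: str) -> LogisticTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def logistic_fit(
    X: pd.DataFrame,
    y,
    add_intercept: bool = True,
    stepwise: bool = False,
    p_remove: float = 0.05,
) -> LogisticFitResult:
    """Maximum-likelihood logistic regression with Wald odds-ratio CIs.

    Fits via IRLS (statsmodels Logit).  With ``stepwise=True`` performs
    backward elimination, repeatedly dropping the least significant
    covariate until every remaining one has Wald p <= ``p_remove``.
    Quasi-perfect separation is flagged rather than silently reported.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    cols = list(X.columns)

    def fit_once(columns):
        design = X[columns]
        if add_intercept:
            design = sm.add_constant(design, has_constant="add")
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            raise ValueError("design matrix is rank-deficient")
        with np.errstate(all="ignore"):
            try:
                res = sm.Logit(y, design).fit(disp=False, maxiter=200)
            except (PerfectSeparationError, np.linalg.LinAlgError):
                # quasi-separated data: gradient fit still returns a
                # (flagged) estimate instead of aborting
                res = sm.Logit(y, design).fit(
                    disp=False, maxiter=500, method="bfgs"
                )
        return res

    res = fit_once(cols)
    if stepwise:
        while cols:
            pvals = res.pvalues.drop("const", errors="ignore")
            worst = pvals.idxmax()
            if pvals[worst] <= p_remove:
                break
            cols.remove(worst)
            if not cols:
                res = fit_once(cols)
                break
            res = fit_once(cols)

    separation = bool(np.any(np.abs(res.params) > 15) or not res.mle_retvals["converged"])
    conf = res.conf_int()
    terms = []
    with np.errstate(over="ignore"):  # exp overflows to inf on separated fits
        for name in res.params.index:
            lo, hi = conf.loc[name]
            terms.append(
                LogisticTerm(
                    name=str(name),
                    coef=float(res.params[name]),
                    se=float(res.bse[name]),
                    odds_ratio=float(np.exp(res.params[name])),
                    or_ci=(float(np.exp(lo)), float(np.exp(hi))),
                    p_value=float(res.pvalues[name]),
                )
            )
    return LogisticFitResult(
        terms=tuple(terms),
        converged=bool(res.mle_retvals["converged"]),
        separation_flag=separation,
        llf=float(res.llf),
    )


def group_comparison_table(
    frame: pd.DataFrame,
    group_col: str,
    positive_group: str,
    variables: Sequence[str],
    m_bonferroni: int = DEFAULT_BONFERRONI_M,
) -> pd.DataFrame:
    """Per-variable Welch t-test table with Bonferroni-adjusted p-values."""
    pos = frame[frame[group_col] == positive_group]
    neg = frame[frame[group_col] != positive_group]
    rows = []
    for var in variables:
        x, ycol = pos[var].to_numpy(), neg[var].to_numpy()
        r = welch_t_from_summary(
            x.mean(), x.std(ddof=1), x.size, ycol.mean(), ycol.std(ddof=1), ycol.size
        )
        rows.append(
            {
                "variable": var,
                "mean_pos": x.mean(),
                "sd_pos": x.std(ddof=1),
                "mean_neg": ycol.mean(),
                "sd_neg": ycol.std(ddof=1),
                "t": r.statistic,
                "df": r.df,
                "p": r.p_value,
            }
        )
    table = pd.DataFrame(rows)
    table["p_bonferroni"] = bonferroni(table["p"].to_numpy(), max(m_bonferroni, len(table)))
    return table
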