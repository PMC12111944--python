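"""Diagnostic-accuracy statistics for continuous biomarkers.

ROC curves are built on the convention used throughout this package:
*a positive call is score ≥ threshold*, with candidate thresholds taken
at every distinct observed score (plus one above the maximum, the
"call nobody" operating point).  The AUC is the Mann–Whitney
concordance probability with ties counted one half.

Cut-off selection offers the three operating points used in clinical
grey-zone protocols:

* *optimal* — maximises Youden's J = Se + Sp − 1 (ties resolved toward
  the lower threshold);
* *rule-out* — maximises specificity subject to a sensitivity floor
  (default 0.80), so a negative call confidently excludes disease;
* *rule-in* — maximises sensitivity subject to a specificity floor
  (default 0.74), so a positive call confidently confirms it.

Paired AUC comparison uses the DeLong covariance construction;
proportion confidence intervals are Wilson; Spearman CIs use the
Fisher z-transform with the Fieller–Hartley–Pearson standard error
sqrt(1.06/(n−3)).  Group comparison follows the conventional routing
rule: a normality test gates Student's t versus Mann–Whitney, with
Pearson's χ² for categorical data.  Backward-stepwise logistic
regression removes, one at a time, the predictor with the largest Wald
p > 0.10, accepting the removal only while the AIC does not worsen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RocCurve",
    "ProportionCI",
    "DiagnosticPerformance",
    "StepwiseResult",
    "roc_curve",
    "compare_auc",
    "optimal_cutoff",
    "rule_cutoffs",
    "performance_at",
    "spearman_ci",
    "group_compare",
    "stepwise_logistic",
]


@dataclass(frozen=True)
class RocCurve:
    """ROC curve on the score ≥ threshold convention.

    ``thresholds`` are the distinct scores in increasing order plus a
    final value above the maximum; ``se_at``/``sp_at`` are aligned with
    them.  ``tp_at``/``tn_at`` carry the exact integer confusion counts
    so downstream cut-off selection involves no float rounding.
    """

    thresholds: np.ndarray
    se_at: np.ndarray
    sp_at: np.ndarray
    tp_at: np.ndarray
    tn_at: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ProportionCI:
    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion-matrix performance at one threshold.

    Ratios with a zero denominator are ``None`` (undefined), never 0.
    """

    threshold: float
    se: Optional[ProportionCI]
    sp: Optional[ProportionCI]
    ppv: Optional[ProportionCI]
    npv: Optional[ProportionCI]
    accuracy: Optional[ProportionCI]
    tp: int
    fp: int
    tn: int
    fn: int


def _validate_scores_labels(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    return scores, labels


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Build the ROC curve for a positively oriented score.

    AUC equals the Mann–Whitney concordance probability (ties counted
    ½), computed from midranks.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    n_pos, n_neg = len(pos), len(neg)

    uniq = np.unique(scores)
    # final threshold above every score: the Se=0 / Sp=1 operating point
    step = max(1.0, abs(uniq[-1]))
    thresholds = np.append(uniq, uniq[-1] + step)

    # counts of scores >= t (positive calls) via searchsorted on sorted arrays
    tp = n_pos - np.searchsorted(pos, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg, thresholds, side="left")
    tn = n_neg - fp

    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    return RocCurve(
        thresholds=thresholds,
        se_at=tp / n_pos,
        sp_at=tn / n_neg,
        tp_at=tp.astype(int),
        tn_at=tn.astype(int),
        auc=float(auc),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    r_all = _midranks(np.concatenate([pos, neg]))
    r_pos = _midranks(pos)
    r_neg = _midranks(neg)
    v10 = (r_all[:m] - r_pos) / n          # placement of each positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # placement of each negative
    return v10, v01


def compare_auc(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> Dict[str, float]:
    """Paired two-sided AUC comparison (DeLong).

    Both markers must be measured on the same subjects.  Returns
    ``{"auc_a", "auc_b", "delta", "z", "p_value"}``.  Identical score
    vectors give delta 0 and p = 1.
    """
    scores_a, labels = _validate_scores_labels(scores_a, labels)
    scores_b, _ = _validate_scores_labels(scores_b, labels)
    if len(scores_a) != len(scores_b):
        raise ValueError("paired scores must have identical length")

    v10a, v01a = _delong_placements(scores_a, labels)
    v10b, v01b = _delong_placements(scores_b, labels)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = len(v10a), len(v01a)

    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        z = 0.0 if delta == 0 else np.inf * np.sign(delta)
    else:
        z = delta / np.sqrt(var)
    p = 1.0 if (var <= 0 and delta == 0) else 2.0 * stats.norm.sf(abs(z))
    return {
        "auc_a": float(auc_a),
        "auc_b": float(auc_b),
        "delta": float(delta),
        "z": float(z),
        "p_value": float(min(1.0, p)),
    }


def optimal_cutoff(roc: RocCurve) -> Tuple[float, "DiagnosticPerformance"]:
    """Threshold maximising Se + Sp (Youden), ties toward the lower one."""
    j = roc.se_at + roc.sp_at
    idx = int(np.argmax(j))  # argmax returns the first (lowest) maximiser
    t = float(roc.thresholds[idx])
    return t, _performance_from_counts(
        t,
        tp=int(roc.tp_at[idx]),
        fn=roc.n_pos - int(roc.tp_at[idx]),
        tn=int(roc.tn_at[idx]),
        fp=roc.n_neg - int(roc.tn_at[idx]),
    )


def rule_cutoffs(
    roc: RocCurve, se_floor: float = 0.80, sp_floor: float = 0.74
) -> Dict[str, Optional[float]]:
    """Rule-in / rule-out thresholds by constrained exhaustive scan.

    ``rule_out`` maximises specificity among thresholds with
    Se ≥ ``se_floor`` (a confident negative call needs high sensitivity
    at the threshold); ``rule_in`` maximises sensitivity among
    thresholds with Sp ≥ ``sp_floor``.  Degenerate operating points
    (Se = 0 or Sp = 0, i.e. calling everybody or nobody) are never
    returned.  A floor no usable threshold satisfies yields ``None``
    for that rule.  Ties are resolved by the larger unconstrained
    quantity, then the lower threshold.
    """
    if not (0 < se_floor < 1 and 0 < sp_floor < 1):
        raise ValueError("floors must lie in (0, 1)")

    usable = (roc.se_at > 0) & (roc.sp_at > 0)

    def best(mask: np.ndarray, maximise: np.ndarray, then: np.ndarray):
        mask = mask & usable
        if not mask.any():
            return None
        cand = np.flatnonzero(mask)
        key = maximise[cand]
        cand = cand[key == key.max()]
        key2 = then[cand]
        cand = cand[key2 == key2.max()]
        return float(roc.thresholds[cand[0]])

    return {
        "rule_out": best(roc.se_at >= se_floor, roc.sp_at, roc.se_at),
        "rule_in": best(roc.sp_at >= sp_floor, roc.se_at, roc.sp_at),
    }


def _wilson(k: int, n: int) -> Optional[ProportionCI]:
    if n == 0:
        return None
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return ProportionCI(value=k / n, ci_low=float(lo), ci_high=float(hi))


def _performance_from_counts(
    threshold: float, tp: int, fp: int, tn: int, fn: int
) -> DiagnosticPerformance:
    return DiagnosticPerformance(
        threshold=threshold,
        se=_wilson(tp, tp + fn),
        sp=_wilson(tn, tn + fp),
        ppv=_wilson(tp, tp + fp),
        npv=_wilson(tn, tn + fn),
        accuracy=_wilson(tp + tn, tp + fp + tn + fn),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def performance_at(
    scores: Sequence[float], labels: Sequence[bool], threshold: float
) -> DiagnosticPerformance:
    """Confusion-matrix performance calling score ≥ threshold positive."""
    scores, labels = _validate_scores_labels(scores, labels)
    call = scores >= threshold
    return _performance_from_counts(
        threshold,
        tp=int((call & labels).sum()),
        fp=int((call & ~labels).sum()),
        tn=int((~call & ~labels).sum()),
        fn=int((~call & labels).sum()),
    )


def spearman_ci(
    x: Sequence[float], y: Sequence[float]
) -> Dict[str, float]:
    """Spearman rank correlation with a Fisher-z confidence interval.

    Ties receive average ranks.  The CI uses the Fieller–Hartley–Pearson
    standard error sqrt(1.06/(n−3)) on the z scale.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: ranks undefined")
    rho, p = stats.spearmanr(x, y)
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(abs(rho) - 1.0) < 1e-12:
        rho = math.copysign(1.0, rho)
    if abs(rho) == 1.0:
        lo, hi = rho, rho
    else:
        z = np.arctanh(rho)
        se = np.sqrt(1.06 / (n - 3))
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return {"rho": rho, "ci_low": float(lo), "ci_high": float(hi), "p": float(p)}


def _looks_categorical(values: np.ndarray) -> bool:
    if values.dtype == bool or values.dtype.kind in "OUS":
        return True
    return len(np.unique(values)) <= 2


def group_compare(
    values: Sequence,
    group_labels: Sequence,
    alpha_normality: float = 0.05,
) -> Dict[str, object]:
    """Two-group comparison with the conventional test-routing rule.

    Continuous data: a Kolmogorov–Smirnov-type normality test
    (Lilliefors, parameters estimated) on each group; both normal →
    Student's t-test, otherwise Mann–Whitney U.  Categorical (boolean or
    two-valued) data → Pearson's χ² without continuity correction.
    Returns ``{"statistic", "p", "test_used"}``.
    """
    values = np.asarray(values)
    groups = np.asarray(group_labels)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {len(uniq)}")
    a = values[groups == uniq[0]]
    b = values[groups == uniq[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")

    if _looks_categorical(values):
        table = pd.crosstab(pd.Series(groups), pd.Series(values)).to_numpy()
        if table.shape[1] < 2:  # single category everywhere
            return {"statistic": 0.0, "p": 1.0, "test_used": "chi2"}
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return {"statistic": float(stat), "p": float(p), "test_used": "chi2"}

    a = a.astype(float)
    b = b.astype(float)

    def normal(g: np.ndarray) -> bool:
        if len(g) < 4 or np.ptp(g) == 0:
            return False
        from statsmodels.stats.diagnostic import lilliefors

        _, p = lilliefors(g, dist="norm")
        return p >= alpha_normality

    if normal(a) and normal(b):
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        return {"statistic": float(stat), "p": float(p), "test_used": "t"}
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"statistic": float(stat), "p": float(p), "test_used": "mannwhitney"}


@dataclass
class StepwiseResult:
    """Backward-stepwise logistic regression outcome."""

    selected: List[str]
    removed: List[str]
    coefficients: Dict[str, float]
    odds_ratios: Dict[str, float]
    or_ci: Dict[str, Tuple[float, float]]
    p_values: Dict[str, float]
    aic: float
    separation_flag: bool = False
    warnings: List[str] = field(default_factory=list)


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Fit a logit, falling back to BFGS on (quasi-)separation."""
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            res = model.fit(method="bfgs", maxiter=200, disp=0)
            return res, True
    sep = any("separation" in str(w.message).lower() for w in caught)
    return res, sep


def stepwise_logistic(
    outcome: Sequence[bool],
    candidate_predictors: pd.DataFrame,
    p_exclusion: float = 0.10,
) -> StepwiseResult:
    """Backward-stepwise logistic regression.

    Starts from the full model and repeatedly removes the predictor with
    the largest Wald p-value above ``p_exclusion``, keeping the removal
    only while the AIC does not worsen.  Odds ratios are
    ``exp(coefficient)`` with Wald 95% intervals.  Perfect separation is
    flagged and the (unstable) model still returned.
    """
    y = np.asarray(outcome, float)
    X = candidate_predictors.copy().astype(float)
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values in outcome or predictors")
    if len(y) <= 10 * X.shape[1]:
        warnings.warn(
            "fewer than 10 events-free observations per candidate predictor",
            stacklevel=2,
        )
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant predictors: {constant}")

    cols = list(X.columns)
    removed: List[str] = []
    notes: List[str] = []
    any_sep = False

    res, sep = _fit_logit(y, X[cols])
    any_sep |= sep
    while cols:
        pvals = res.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] <= p_exclusion:
            break
        trial_cols = [c for c in cols if c != worst]
        trial, sep = _fit_logit(y, X[trial_cols])
        if trial.aic > res.aic:
            notes.append(f"kept {worst}: removal worsens AIC")
            break
        any_sep |= sep
        removed.append(worst)
        cols = trial_cols
        res = trial
        if not cols:
            break

    params = res.params.drop("const", errors="ignore")
    conf = res.conf_int()
    with np.errstate(over="ignore"):
        ors = np.exp(params)
        or_ci = {
            name: (
                float(np.exp(conf.loc[name, 0])),
                float(np.exp(conf.loc[name, 1])),
            )
            for name in params.index
        }
    if any_sep:
        notes.append("perfect or quasi-perfect separation detected")
    return StepwiseResult(
        selected=list(params.index),
        removed=removed,
        coefficients={k: float(v) for k, v in params.items()},
        odds_ratios={k: float(v) for k, v in ors.items()},
        or_ci=or_ci,
        p_values={k: float(res.pvalues[k]) for k in params.index},
        aic=float(res.aic),
        separation_flag=any_sep,
        warnings=notes,
    )
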