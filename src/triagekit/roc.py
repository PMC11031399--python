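"""ROC curves, Mann-Whitney AUC and DeLong variance/paired tests.

Directionality is handled once and centrally: scores of a lower-is-positive
biomarker are negated on entry, every downstream computation assumes higher =
positive, and thresholds are mapped back to the original scale for reporting.

The AUC is the Mann-Whitney two-sample statistic with ties credited 1/2; its
variance and the covariance between two correlated AUCs follow DeLong's
structural-components (placement-value) construction, computed via midranks
in O(n log n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .cohort import Orientation

__all__ = [
    "ROCCurve",
    "AUCResult",
    "PairedAUCComparison",
    "orient_scores",
    "auc_mw",
    "roc_points",
    "delong_paired",
    "fit_logistic_score",
]


def orient_scores(scores, orientation) -> np.ndarray:
    """Map scores to the canonical higher-is-positive scale."""
    s = np.asarray(scores, dtype=float)
    if Orientation(orientation) is Orientation.LOWER_IS_POSITIVE:
        return -s
    return s


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    y = y.astype(float).astype(int)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("degenerate outcome: only one class present")
    return y


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve on the oriented (higher-is-positive) scale.

    One point per candidate threshold; thresholds are midpoints between
    consecutive distinct scores plus +-inf sentinels, in descending order, so
    the curve runs from (sens 0, spec 1) to (sens 1, spec 0).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int

    def auc(self) -> float:
        """Trapezoidal area; equals the Mann-Whitney AUC exactly."""
        fpr = 1.0 - self.specificity
        return float(np.trapezoid(self.sensitivity, fpr))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


@dataclass(frozen=True)
class AUCResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class PairedAUCComparison:
    auc_a: float
    auc_b: float
    difference: float
    ci_low: float
    ci_high: float
    p_value: float  # NaN when the difference variance is degenerate
    variance: float


def _placements(oriented: np.ndarray, y: np.ndarray):
    """DeLong placement values via midranks.

    Returns (auc, v_pos, v_neg): v_pos[i] is the fraction of negatives a
    positive outranks (ties 1/2); v_neg[j] the fraction of positives the
    negative j is outranked by, complemented.
    """
    pos = oriented[y == 1]
    neg = oriented[y == 0]
    m, n = len(pos), len(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    tx = rankdata(pos)
    ty = rankdata(neg)
    v_pos = (tz[:m] - tx) / n
    v_neg = 1.0 - (tz[m:] - ty) / m
    auc = float(v_pos.mean())
    return auc, v_pos, v_neg


def _component_var(v: np.ndarray) -> float:
    return float(np.var(v, ddof=1)) if v.size > 1 else 0.0


def auc_mw(scores, labels, orientation=Orientation.HIGHER_IS_POSITIVE,
           ci_level: float = 0.95) -> AUCResult:
    """Mann-Whitney AUC with DeLong variance and normal-approximation CI."""
    y = _check_labels(labels)
    s = orient_scores(scores, orientation)
    if np.isnan(s).any():
        raise ValueError("scores contain missing values; take complete cases first")
    auc, v_pos, v_neg = _placements(s, y)
    m, n = int((y == 1).sum()), int((y == 0).sum())
    var = _component_var(v_pos) / m + _component_var(v_neg) / n
    z = norm.ppf(0.5 + ci_level / 2)
    half = z * np.sqrt(var)
    return AUCResult(auc, var, max(0.0, auc - half), min(1.0, auc + half), m, n)


def candidate_thresholds(oriented: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct oriented scores, plus +-inf
    sentinels, in descending order."""
    u = np.unique(oriented)  # ascending
    mids = (u[1:] + u[:-1]) / 2.0
    return np.concatenate([[np.inf], mids[::-1], [-np.inf]])


def _sens_spec_at(thresholds: np.ndarray, pos_sorted: np.ndarray,
                  neg_sorted: np.ndarray):
    """Sensitivity/specificity of the rule 'positive iff score >= t'."""
    m, n = len(pos_sorted), len(neg_sorted)
    # count of scores >= t via searchsorted on ascending arrays
    sens = (m - np.searchsorted(pos_sorted, thresholds, side="left")) / m
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / n
    return sens, spec


def roc_points(scores, labels, orientation=Orientation.HIGHER_IS_POSITIVE) -> ROCCurve:
    """Full empirical ROC curve (one point per candidate threshold)."""
    y = _check_labels(labels)
    s = orient_scores(scores, orientation)
    if np.isnan(s).any():
        raise ValueError("scores contain missing values; take complete cases first")
    thr = candidate_thresholds(s)
    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    sens, spec = _sens_spec_at(thr, pos, neg)
    return ROCCurve(thr, sens, spec, len(pos), len(neg))


def delong_paired(scores_a, scores_b, labels,
                  orientation_a=Orientation.HIGHER_IS_POSITIVE,
                  orientation_b=Orientation.HIGHER_IS_POSITIVE,
                  ci_level: float = 0.95) -> PairedAUCComparison:
    """DeLong test for two AUCs measured on the same subjects.

    The difference is ``auc_a - auc_b``; its variance uses the covariance of
    placement components, so correlation between the markers tightens the CI.
    A zero-variance difference yields the degenerate CI [d, d] and a NaN
    p-value rather than a division by zero.
    """
    y = _check_labels(labels)
    sa = orient_scores(scores_a, orientation_a)
    sb = orient_scores(scores_b, orientation_b)
    if len(sa) != len(sb) or len(sa) != len(y):
        raise ValueError("paired comparison requires aligned score vectors")
    if np.isnan(sa).any() or np.isnan(sb).any():
        raise ValueError("scores contain missing values; take complete cases first")
    auc_a, vp_a, vn_a = _placements(sa, y)
    auc_b, vp_b, vn_b = _placements(sb, y)
    m, n = len(vp_a), len(vn_a)

    def _cov(u, v):
        return float(np.cov(u, v, ddof=1)[0, 1]) if len(u) > 1 else 0.0

    var = ((_component_var(vp_a) + _component_var(vp_b) - 2 * _cov(vp_a, vp_b)) / m
           + (_component_var(vn_a) + _component_var(vn_b) - 2 * _cov(vn_a, vn_b)) / n)
    diff = auc_a - auc_b
    if var <= 1e-15:
        return PairedAUCComparison(auc_a, auc_b, diff, diff, diff, np.nan, 0.0)
    se = np.sqrt(var)
    z = norm.ppf(0.5 + ci_level / 2)
    p = 2 * norm.sf(abs(diff) / se)
    return PairedAUCComparison(auc_a, auc_b, diff, diff - z * se, diff + z * se,
                               float(p), var)


def fit_logistic_score(primary, covariate, labels):
    """Linear predictor of a binary logistic fit of outcome on (primary, covariate).

    Used for the sensitivity analysis that adjusts plasma p-tau217 for
    non-phosphorylated tau instead of forming their ratio.  The returned
    vector is a derived higher-is-positive biomarker for the cutoff machinery.
    Perfect separation is flagged: the primary score is returned unchanged
    with a warning.
    """
    import statsmodels.api as sm

    y = _check_labels(labels)
    x1 = np.asarray(primary, dtype=float)
    x2 = np.asarray(covariate, dtype=float)
    if np.isnan(x1).any() or np.isnan(x2).any():
        raise ValueError("scores contain missing values; take complete cases first")
    X = sm.add_constant(np.column_stack([x1, x2]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = res.params
        if not res.mle_retvals.get("converged", True) or np.abs(params).max() > 1e3:
            raise RuntimeError("suspect separation")
    except Exception:
        warnings.warn("logistic fit failed (perfect separation?); "
                      "falling back to the primary score", stacklevel=2)
        return x1.copy()
    return X @ params
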