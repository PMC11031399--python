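"""Confusion-matrix metrics for binary and triage classifications.

Intermediate subjects are excluded from accuracy/PPV/NPV/sensitivity/
specificity and accounted for separately through ``intermediate_fraction``.
Metrics with an empty denominator are *undefined* — represented as NaN and
listed in ``MetricSet.undefined`` — never silently 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .cutpoints import CutoffSet, classify

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "METRIC_NAMES",
    "metrics_from_labels",
    "metrics_from_codes",
    "reference_by_triage",
    "status_change_rate",
]

METRIC_NAMES = ("accuracy", "ppv", "npv", "sensitivity", "specificity",
                "intermediate_fraction")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_classified(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Diagnostic accuracy metrics; NaN entries are listed in ``undefined``."""

    accuracy: float
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    intermediate_fraction: float
    n_classified: int
    n_intermediate: int
    counts: ConfusionCounts
    undefined: frozenset = field(default_factory=frozenset)

    def __getitem__(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def _ratio(num: int, den: int):
    return (num / den, False) if den else (np.nan, True)


def metrics_from_codes(codes: np.ndarray, truth: np.ndarray) -> MetricSet:
    """Metrics from integer triage codes (0 negative, 1 intermediate,
    2 positive, -1 missing) and 0/1 truth (NaN allowed)."""
    valid = (codes >= 0) & ~np.isnan(truth)
    c = codes[valid]
    t = truth[valid].astype(int)
    inter = c == 1
    n_int = int(inter.sum())
    cc, tt = c[~inter], t[~inter]
    pred_pos = cc == 2
    tp = int((pred_pos & (tt == 1)).sum())
    fp = int((pred_pos & (tt == 0)).sum())
    fn = int((~pred_pos & (tt == 1)).sum())
    tn = int((~pred_pos & (tt == 0)).sum())
    counts = ConfusionCounts(tp, fp, fn, tn)
    n_cls = counts.n_classified
    if n_cls == 0:
        warnings.warn("no classified subjects; all metrics undefined", stacklevel=2)
    undefined = set()
    vals = {}
    for name, num, den in (
        ("accuracy", tp + tn, n_cls),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("intermediate_fraction", n_int, n_cls + n_int),
    ):
        val, undef = _ratio(num, den)
        vals[name] = val
        if undef:
            undefined.add(name)
    return MetricSet(**vals, n_classified=n_cls, n_intermediate=n_int,
                     counts=counts, undefined=frozenset(undefined))


def labels_to_codes(pred) -> np.ndarray:
    """Triage labels -> integer codes (-1 for missing)."""
    if isinstance(pred, pd.Series):
        pred = pred.array
    cat = pd.Categorical(pred, categories=["negative", "intermediate", "positive"])
    return cat.codes.astype(np.int64)


def metrics_from_labels(pred, truth) -> MetricSet:
    """Metrics from triage labels (categorical) and a binary truth vector."""
    codes = labels_to_codes(pred)
    t = np.asarray(truth, dtype=float)
    if len(codes) != len(t):
        raise ValueError("prediction and truth vectors must be aligned")
    return metrics_from_codes(codes, t)


def reference_by_triage(reference, labels):
    """Summaries and pairwise rank-sum comparisons of a continuous reference
    measure (e.g. Centiloids) across the three triage groups.

    Returns ``(summary, comparisons)`` DataFrames.  The expectation under a
    well-behaved triage is an ordered gradient: intermediate subjects sit
    between the negative and positive groups on the reference scale.
    Comparisons involving a group with fewer than two subjects are skipped
    with a note.
    """
    ref = np.asarray(reference, dtype=float)
    codes = labels_to_codes(labels)
    groups = {}
    rows = []
    for code, name in ((0, "negative"), (1, "intermediate"), (2, "positive")):
        vals = ref[(codes == code) & ~np.isnan(ref)]
        groups[name] = vals
        rows.append({"group": name, "n": len(vals),
                     "mean": vals.mean() if len(vals) else np.nan,
                     "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan})
    summary = pd.DataFrame(rows)
    comps = []
    pairs = [("negative", "intermediate"), ("intermediate", "positive"),
             ("negative", "positive")]
    for a, b in pairs:
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            comps.append({"group_a": a, "group_b": b, "p_value": np.nan,
                          "note": "skipped: group too small"})
            continue
        stat = mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        comps.append({"group_a": a, "group_b": b, "p_value": stat.pvalue,
                      "note": ""})
    return summary, pd.DataFrame(comps)


def status_change_rate(long_df: pd.DataFrame, cutoffs: CutoffSet,
                       score_column: str, subject_column: str = "subject_id",
                       time_column: str = "visit_time"):
    """Fraction of subjects whose single-cutoff biomarker status changes
    between the first and any later visit.

    ``long_df`` is a long-format table with one row per subject visit.
    Subjects with fewer than two non-missing visits are excluded (noted in
    the returned dict).  Returns ``(rate, info)`` where ``info`` carries the
    changer ids, n_subjects and n_excluded.
    """
    if cutoffs.mode != "single":
        raise ValueError("status stability is defined for the single-cutoff rule")
    df = long_df[[subject_column, time_column, score_column]].dropna()
    changers = []
    n_included = 0
    n_excluded = 0
    for sid, grp in df.groupby(subject_column, sort=False):
        if len(grp) < 2:
            n_excluded += 1
            continue
        n_included += 1
        lab = classify(grp.sort_values(time_column)[score_column].to_numpy(),
                       cutoffs)
        if (lab[1:] != lab.iloc[0]).any():
            changers.append(sid)
    if n_excluded:
        warnings.warn(f"{n_excluded} subjects with a single visit excluded "
                      "from status-stability", stacklevel=2)
    rate = len(changers) / n_included if n_included else np.nan
    return rate, {"changers": changers, "n_subjects": n_included,
                  "n_excluded": n_excluded}
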