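"""Constrained-optimal cutoffs and three-way triage classification.

Two rules are implemented:

* **single cutoff** — maximise sensitivity subject to specificity >= a floor
  (default 90%); subjects at or above the threshold (oriented scale) are
  positive;
* **two cutoffs** — a *lower* threshold maximising specificity subject to
  sensitivity >= 95%, and an *upper* threshold maximising sensitivity subject
  to specificity >= 95%.  Subjects between the two are *intermediate*:
  at/above the upper -> positive, strictly below the lower -> negative.

Candidate thresholds are midpoints between consecutive distinct oriented
scores plus +-inf sentinels, which makes the >=-boundary convention
unambiguous and invariant under strictly increasing transforms (at the cost
of a possible sub-subject discrepancy against implementations that scan
observed values).  Ties in the objective are broken towards the threshold
that binds the constraint most tightly, so the achieved constrained metric is
the smallest attainable value at or above its floor — exactly the floor on
tie-free data whenever ``floor x class size`` is an integer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Orientation
from .roc import _check_labels, _sens_spec_at, candidate_thresholds, orient_scores

__all__ = [
    "CutoffSet",
    "derive_single_cutoff",
    "derive_two_cutoffs",
    "classify",
    "TRIAGE_CATEGORIES",
]

TRIAGE_CATEGORIES = ("negative", "intermediate", "positive")


@dataclass(frozen=True)
class CutoffSet:
    """One or two thresholds on the oriented (higher-is-positive) scale.

    ``lower == upper == threshold`` in single mode.  ``achieved_inbag`` records
    the in-sample sensitivity/specificity at each threshold.  Use
    :meth:`thresholds_original_scale` for values on the measured biomarker
    scale (for a lower-is-positive biomarker the oriented thresholds are
    negated and swap roles).
    """

    mode: str  # "single" | "dual"
    orientation: Orientation
    lower: float
    upper: float
    achieved_inbag: dict = field(default_factory=dict)
    biomarker: str | None = None
    crossed: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("single", "dual"):
            raise ValueError("mode must be 'single' or 'dual'")
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        if self.lower > self.upper:
            raise ValueError("oriented thresholds must satisfy lower <= upper")

    @property
    def threshold(self) -> float:
        if self.mode != "single":
            raise AttributeError("threshold is defined for single mode only")
        return self.lower

    def thresholds_original_scale(self) -> tuple[float, ...]:
        """Thresholds on the measured scale, ascending."""
        vals = (self.lower,) if self.mode == "single" else (self.lower, self.upper)
        if self.orientation is Orientation.LOWER_IS_POSITIVE:
            vals = tuple(-v for v in vals)
        return tuple(sorted(vals))

    def to_json(self, **extra) -> str:
        payload = {
            "mode": self.mode,
            "orientation": self.orientation.value,
            "thresholds_original_scale": list(self.thresholds_original_scale()),
            "achieved_inbag": self.achieved_inbag,
            "biomarker": self.biomarker,
            "crossed": self.crossed,
            **extra,
        }
        return json.dumps(payload, indent=2)


def _prepare(scores, labels, orientation):
    y = _check_labels(labels)
    s = orient_scores(scores, orientation)
    if np.isnan(s).any():
        raise ValueError("scores contain missing values; take complete cases first")
    thr = candidate_thresholds(s)
    sens, spec = _sens_spec_at(thr, np.sort(s[y == 1]), np.sort(s[y == 0]))
    return thr, sens, spec


_EPS = 1e-12  # guards float comparison of exact count fractions against targets


def _select(thr, objective, constraint, floor):
    """Best threshold: maximise `objective` s.t. `constraint` >= floor.

    Ties in the objective are broken by the smallest constraint value (the
    constraint binds as tightly as possible), which is unique: distinct
    candidate thresholds never share both sensitivity and specificity.
    """
    feasible = np.flatnonzero(constraint >= floor - _EPS)
    obj = objective[feasible]
    best = obj.max()
    cand = feasible[obj >= best - _EPS]
    con = constraint[cand]
    idx = int(cand[np.argmin(con)])
    return idx


def derive_single_cutoff(scores, labels, orientation=Orientation.HIGHER_IS_POSITIVE,
                         spec_floor: float = 0.90, biomarker: str | None = None) -> CutoffSet:
    """Threshold maximising sensitivity with specificity fixed at >= ``spec_floor``."""
    if not 0 < spec_floor <= 1:
        raise ValueError("spec_floor must lie in (0, 1]")
    thr, sens, spec = _prepare(scores, labels, orientation)
    idx = _select(thr, sens, spec, spec_floor)
    if sens[idx] == 0.0:
        warnings.warn("no finite threshold attains the specificity floor; "
                      "sentinel selected (sensitivity 0)", stacklevel=2)
    t = float(thr[idx])
    achieved = {"sensitivity": float(sens[idx]), "specificity": float(spec[idx])}
    return CutoffSet("single", orientation, t, t, achieved, biomarker)


def derive_two_cutoffs(scores, labels, orientation=Orientation.HIGHER_IS_POSITIVE,
                       sens_target: float = 0.95, spec_target: float = 0.95,
                       biomarker: str | None = None) -> CutoffSet:
    """Lower threshold: max specificity s.t. sensitivity >= ``sens_target``;
    upper threshold: max sensitivity s.t. specificity >= ``spec_target``.

    If the thresholds cross (possible on weakly discriminating data) a warning
    is emitted, both collapse to their midpoint and the set is flagged
    ``crossed`` — the intermediate zone is then empty by construction.
    """
    for t in (sens_target, spec_target):
        if not 0 < t <= 1:
            raise ValueError("targets must lie in (0, 1]")
    thr, sens, spec = _prepare(scores, labels, orientation)
    i_lo = _select(thr, spec, sens, sens_target)
    i_up = _select(thr, sens, spec, spec_target)
    lower, upper = float(thr[i_lo]), float(thr[i_up])
    achieved = {
        "lower": {"sensitivity": float(sens[i_lo]), "specificity": float(spec[i_lo])},
        "upper": {"sensitivity": float(sens[i_up]), "specificity": float(spec[i_up])},
    }
    crossed = lower > upper
    if crossed:
        warnings.warn("two-cutoff thresholds crossed; collapsing to their "
                      "midpoint (empty intermediate zone)", stacklevel=2)
        lower = upper = (lower + upper) / 2.0
    return CutoffSet("dual", orientation, lower, upper, achieved, biomarker, crossed)


def classify(scores, cutoffs: CutoffSet) -> pd.Series:
    """Triage labels for raw (original-scale) scores.

    Single mode: positive iff oriented score >= threshold, else negative.
    Dual mode: positive iff >= upper, negative iff < lower, intermediate
    between.  Missing scores yield missing labels.
    """
    s = orient_scores(np.asarray(scores, dtype=float), cutoffs.orientation)
    out = np.full(s.shape, None, dtype=object)
    ok = ~np.isnan(s)
    if cutoffs.mode == "single":
        out[ok] = np.where(s[ok] >= cutoffs.lower, "positive", "negative")
    else:
        lab = np.where(s[ok] >= cutoffs.upper, "positive",
                       np.where(s[ok] < cutoffs.lower, "negative", "intermediate"))
        out[ok] = lab
    index = scores.index if isinstance(scores, pd.Series) else None
    return pd.Series(pd.Categorical(out, categories=list(TRIAGE_CATEGORIES)),
                     index=index)
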