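"""Model/Results interface over the cutoff + bootstrap machinery.

`BiomarkerCutoffModel` evaluates one fluid biomarker against one binary
outcome: ROC/AUC, constrained cutoff derivation (single or dual mode) and
stratified-bootstrap metric estimates.  `PairedBiomarkerModel` compares a
plasma reference biomarker with a CSF comparator on the shared complete-case
subjects: DeLong AUC difference plus bootstrap metric differences with the
clinical equivalence/superiority verdict.  Both follow the familiar
``Model(data...).fit() -> Results`` pattern with a ``summary()`` table.
"""

from __future__ import annotations


import numpy as np
import pandas as pd

from .bootstrap import (BootstrapConfig, DEFAULT_METRICS, inbag_estimates,
                        oob_bootstrap, paired_difference)
from .cohort import BiomarkerSpec, CohortTable, OutcomeSpec, derive_outcome
from .cutpoints import classify, derive_single_cutoff, derive_two_cutoffs
from .metrics import metrics_from_labels
from .roc import auc_mw, delong_paired, roc_points

__all__ = ["BiomarkerCutoffModel", "BiomarkerCutoffResults",
           "PairedBiomarkerModel", "PairedBiomarkerResults"]


def _fmt(x: float) -> str:
    return "   nan" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:6.3f}"


class BiomarkerCutoffModel:
    """Constrained-cutoff evaluation of one biomarker against one outcome.

    Parameters
    ----------
    scores, outcome : array-like
        Complete-case biomarker values (original scale) and 0/1 outcome.
    orientation : Orientation
        Pathological direction of the biomarker.
    mode : {"single", "dual"}
        Single cutoff (specificity floor) or two-cutoff triage.
    spec_floor, sens_target, spec_target : float
        Constraint levels of the two rules (defaults 0.90 and 0.95/0.95).
    """

    def __init__(self, scores, outcome, orientation="higher_is_positive",
                 mode="single", spec_floor=0.90, sens_target=0.95,
                 spec_target=0.95, name="biomarker"):
        scores = np.asarray(scores, dtype=float)
        outcome = np.asarray(outcome, dtype=float)
        keep = ~np.isnan(scores) & ~np.isnan(outcome)
        self.n_dropped = int((~keep).sum())
        self.scores = scores[keep]
        self.outcome = outcome[keep].astype(int)
        self.orientation = orientation
        if mode not in ("single", "dual"):
            raise ValueError("mode must be 'single' or 'dual'")
        self.mode = mode
        self.spec_floor = spec_floor
        self.sens_target = sens_target
        self.spec_target = spec_target
        self.name = name

    @classmethod
    def from_cohort(cls, table: CohortTable, biomarker: str,
                    outcome_spec: OutcomeSpec, subgroup: str = "all", **kwargs):
        """Build from a cohort table, deriving the outcome and taking the
        complete cases of the (biomarker, outcome-source) pair."""
        sub = table.subgroup(subgroup)
        spec = sub.biomarker_specs.get(biomarker) or BiomarkerSpec(
            biomarker, kwargs.pop("orientation", "higher_is_positive"))
        y = derive_outcome(sub, outcome_spec)
        return cls(sub.df[biomarker], y, orientation=spec.orientation,
                   name=biomarker, **kwargs)

    def cutoff_rule(self):
        """The (scores, labels) -> CutoffSet callable this model uses."""
        if self.mode == "single":
            def rule(s, y):
                return derive_single_cutoff(s, y, self.orientation,
                                            self.spec_floor, self.name)
        else:
            def rule(s, y):
                return derive_two_cutoffs(s, y, self.orientation,
                                          self.sens_target, self.spec_target,
                                          self.name)
        return rule

    def fit(self, n_resamples: int = 1000, seed: int | None = None,
            oob: bool = False) -> "BiomarkerCutoffResults":
        config = BootstrapConfig(n_resamples=n_resamples, seed=seed)
        auc = auc_mw(self.scores, self.outcome, self.orientation)
        rule = self.cutoff_rule()
        cutoffs = rule(self.scores, self.outcome)
        labels = classify(self.scores, cutoffs)
        observed = metrics_from_labels(labels, self.outcome)
        estimates = inbag_estimates(self.scores, self.outcome, rule,
                                    DEFAULT_METRICS, config)
        oob_estimates = oob_info = None
        if oob:
            oob_estimates, oob_info = oob_bootstrap(
                self.scores, self.outcome, rule, DEFAULT_METRICS, config)
        return BiomarkerCutoffResults(self, auc, cutoffs, labels, observed,
                                      estimates, config, oob_estimates, oob_info)

    def roc(self):
        return roc_points(self.scores, self.outcome, self.orientation)


class BiomarkerCutoffResults:
    """Fitted cutoffs, AUC and bootstrap metric estimates for one biomarker."""

    def __init__(self, model, auc, cutoffs, labels, observed, estimates,
                 config, oob_estimates=None, oob_info=None):
        self.model = model
        self.auc = auc
        self.cutoffs = cutoffs
        self.triage_labels = labels
        self.observed = observed
        self.estimates = estimates
        self.config = config
        self.oob_estimates = oob_estimates
        self.oob_info = oob_info

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for m, est in self.estimates.items():
            rows.append({"biomarker": self.model.name, "mode": self.model.mode,
                         "metric": m, "observed": est.observed,
                         "boot_mean": est.point, "ci_low": est.ci_low,
                         "ci_high": est.ci_high,
                         "n_valid_replicates": est.n_valid_replicates})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Biomarker cutoff evaluation: {m.name} ({m.mode} mode)",
            "=" * 60,
            f"n = {len(m.scores)} ({int(m.outcome.sum())} positive), "
            f"orientation = {str(getattr(m.orientation, 'value', m.orientation))}",
            f"AUC = {self.auc.auc:.3f} (95% CI {self.auc.ci_low:.3f}, "
            f"{self.auc.ci_high:.3f})",
            "thresholds (original scale): "
            + ", ".join(f"{t:.4g}" for t in self.cutoffs.thresholds_original_scale()),
            "",
            f"{'metric':<22}{'observed':>9}{'boot mean':>11}{'95% CI':>20}",
        ]
        for name, est in self.estimates.items():
            lines.append(f"{name:<22}{_fmt(est.observed):>9}{_fmt(est.point):>11}"
                         f"   ({_fmt(est.ci_low)}, {_fmt(est.ci_high)})")
        return "\n".join(lines)


class PairedBiomarkerModel:
    """Paired comparison of a plasma reference biomarker against a CSF one.

    Built on the intersection of complete cases for both biomarkers and the
    outcome; one stratified resample per replicate drives both markers.
    """

    def __init__(self, scores_plasma, scores_csf, outcome,
                 orientation_plasma="higher_is_positive",
                 orientation_csf="higher_is_positive", mode="single",
                 spec_floor=0.90, sens_target=0.95, spec_target=0.95,
                 name_plasma="plasma", name_csf="csf"):
        sp = np.asarray(scores_plasma, dtype=float)
        sc = np.asarray(scores_csf, dtype=float)
        y = np.asarray(outcome, dtype=float)
        if not (len(sp) == len(sc) == len(y)):
            raise ValueError("inputs must be aligned per subject")
        keep = ~np.isnan(sp) & ~np.isnan(sc) & ~np.isnan(y)
        self.n_dropped = int((~keep).sum())
        self.plasma = BiomarkerCutoffModel(sp[keep], y[keep], orientation_plasma,
                                           mode, spec_floor, sens_target,
                                           spec_target, name_plasma)
        self.csf = BiomarkerCutoffModel(sc[keep], y[keep], orientation_csf,
                                        mode, spec_floor, sens_target,
                                        spec_target, name_csf)
        self.outcome = y[keep].astype(int)
        self.mode = mode

    @classmethod
    def from_cohort(cls, table: CohortTable, plasma: str, csf: str,
                    outcome_spec: OutcomeSpec, subgroup: str = "all", **kwargs):
        sub = table.subgroup(subgroup)
        y = derive_outcome(sub, outcome_spec)
        o_p = sub.biomarker_specs[plasma].orientation
        o_c = sub.biomarker_specs[csf].orientation
        return cls(sub.df[plasma], sub.df[csf], y, o_p, o_c,
                   name_plasma=plasma, name_csf=csf, **kwargs)

    def fit(self, n_resamples: int = 1000, seed: int | None = None
            ) -> "PairedBiomarkerResults":
        config = BootstrapConfig(n_resamples=n_resamples, seed=seed)
        auc_cmp = delong_paired(self.plasma.scores, self.csf.scores,
                                self.outcome, self.plasma.orientation,
                                self.csf.orientation)
        verdicts, estimates = paired_difference(
            self.plasma.scores, self.csf.scores, self.outcome,
            self.plasma.cutoff_rule(), self.csf.cutoff_rule(),
            DEFAULT_METRICS, config)
        return PairedBiomarkerResults(self, auc_cmp, verdicts, estimates, config)


class PairedBiomarkerResults:
    def __init__(self, model, auc_comparison, verdicts, estimates, config):
        self.model = model
        self.auc_comparison = auc_comparison
        self.verdicts = verdicts
        self.estimates = estimates
        self.config = config

    def verdicts_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts:
            d = v.difference
            rows.append({"plasma": self.model.plasma.name,
                         "csf": self.model.csf.name, "mode": self.model.mode,
                         "metric": v.metric, "difference": d.point,
                         "observed_difference": d.observed,
                         "ci_low": d.ci_low, "ci_high": d.ci_high,
                         "verdict": v.verdict})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        a = self.auc_comparison
        lines = [
            f"Paired comparison: {m.plasma.name} (reference) vs {m.csf.name} "
            f"({m.mode} mode)",
            "=" * 70,
            f"n = {len(m.outcome)} ({int(m.outcome.sum())} positive)",
            f"AUC {m.plasma.name} = {a.auc_a:.3f}, AUC {m.csf.name} = {a.auc_b:.3f}; "
            f"DeLong diff = {a.difference:+.3f} "
            f"(95% CI {a.ci_low:+.3f}, {a.ci_high:+.3f}), p = {a.p_value:.3g}",
            "",
            f"{'metric':<22}{'diff':>8}{'95% CI':>20}  verdict",
        ]
        for v in self.verdicts:
            d = v.difference
            lines.append(f"{v.metric:<22}{_fmt(d.point):>8}   "
                         f"({_fmt(d.ci_low)}, {_fmt(d.ci_high)})  {v.verdict}")
        return "\n".join(lines)
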