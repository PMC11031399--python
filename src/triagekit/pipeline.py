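"""End-to-end analysis orchestration.

`run_analysis` executes, for every configured outcome x subgroup: complete-case
subsetting, per-biomarker AUC, DeLong paired AUC comparisons against the
plasma reference, single- and two-cutoff derivation with in-bag bootstrap
metrics, and paired plasma-vs-CSF differences with clinical verdicts.
Optional sensitivity analyses: out-of-bag bootstrap, cross-cohort cutoff
transfer and the logistic covariate-adjustment variant.  Any failing
combination is recorded as skipped (with the reason) and the run continues.

Everything is deterministic given the config seed; the provenance block
(config hash, seed, package version) suffices to reproduce a run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import BootstrapConfig, transfer_evaluation
from .cohort import (AMYLOID_PET_OUTCOME, CLINICAL_AD_OUTCOME, CohortTable,
                     OutcomeSpec, TAU_PET_OUTCOME, VISUAL_READ_OUTCOME,
                     complete_case_subset, derive_outcome, read_cohort)
from .model import BiomarkerCutoffModel, PairedBiomarkerModel
from .roc import fit_logistic_score

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_analysis", "write_report"]

_NAMED_OUTCOMES = {
    "abeta_pet": AMYLOID_PET_OUTCOME,
    "tau_pet": TAU_PET_OUTCOME,
    "visual_read": VISUAL_READ_OUTCOME,
    "clinical_ad": CLINICAL_AD_OUTCOME,
}


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    cohort_path: str | None = None
    biomarkers: tuple[str, ...] = ("pct_ptau217", "csf_ptau181_ab42", "csf_ab42_40")
    reference_biomarker: str = "pct_ptau217"
    outcomes: tuple = ("abeta_pet", "tau_pet")
    subgroups: tuple[str, ...] = ("all", "CU", "CI")
    modes: tuple[str, ...] = ("single", "dual")
    spec_floor: float = 0.90
    sens_target: float = 0.95
    spec_target: float = 0.95
    n_resamples: int = 1000
    seed: int = 0
    run_oob: bool = False
    run_logistic_covariate: bool = False
    transfer_cutoffs: dict | None = None

    def __post_init__(self) -> None:
        self.biomarkers = tuple(self.biomarkers)
        self.subgroups = tuple(self.subgroups)
        self.modes = tuple(self.modes)
        self.outcomes = tuple(
            _NAMED_OUTCOMES[o] if isinstance(o, str) else
            (OutcomeSpec(**o) if isinstance(o, dict) else o)
            for o in self.outcomes
        )
        if not self.outcomes or not self.biomarkers:
            raise ValueError("need at least one outcome and one biomarker")
        if self.reference_biomarker not in self.biomarkers:
            raise ValueError("reference biomarker must be among the biomarkers")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        payload = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _combo_seed(seed: int, *key: str) -> int:
    return (seed * 1000003 + zlib.crc32("|".join(key).encode())) % (2**31 - 1)


def run_analysis(config: AnalysisConfig, table: CohortTable | None = None) -> dict:
    """Execute the full analysis; returns the run report as a dict of
    DataFrames plus provenance metadata."""
    if table is None:
        if config.cohort_path is None:
            raise ValueError("no cohort: provide cohort_path or a table")
        table = read_cohort(config.cohort_path)
    for b in config.biomarkers:
        if b not in table.df.columns:
            raise ValueError(f"biomarker column {b!r} missing from cohort")

    auc_rows, metric_rows, diff_rows, delong_rows, cutoff_rows = [], [], [], [], []
    skipped = []

    def skip(reason: str, **key):
        skipped.append({**key, "reason": reason})
        logger.warning("skipped %s: %s", key, reason)

    for outcome in config.outcomes:
        for subgroup in config.subgroups:
            sub = table.subgroup(subgroup)
            okey = {"outcome": outcome.name, "subgroup": subgroup}
            fits = {}
            for biomarker in config.biomarkers:
                key = {**okey, "biomarker": biomarker}
                try:
                    cc = complete_case_subset(sub, [biomarker, outcome.source_column])
                except Exception as exc:  # pragma: no cover - config errors
                    skip(str(exc), **key)
                    continue
                logger.info("%s: %d complete cases", key, len(cc))
                for mode in config.modes:
                    try:
                        model = BiomarkerCutoffModel.from_cohort(
                            cc, biomarker, outcome, mode=mode,
                            spec_floor=config.spec_floor,
                            sens_target=config.sens_target,
                            spec_target=config.spec_target)
                        res = model.fit(
                            n_resamples=config.n_resamples,
                            seed=_combo_seed(config.seed, outcome.name,
                                             subgroup, biomarker, mode),
                            oob=config.run_oob and mode == "single")
                    except Exception as exc:
                        skip(str(exc), **key, mode=mode)
                        continue
                    fits[(biomarker, mode)] = res
                    if mode == config.modes[0]:
                        auc_rows.append({**key, "n": len(model.scores),
                                         "auc": res.auc.auc,
                                         "ci_low": res.auc.ci_low,
                                         "ci_high": res.auc.ci_high})
                    frame = res.estimates_frame()
                    for c, v in key.items():
                        frame[c] = v
                    metric_rows.append(frame)
                    cutoff_rows.append({**key, "mode": mode,
                                        "thresholds": list(res.cutoffs.thresholds_original_scale()),
                                        **{f"achieved_{k}": v
                                           for k, v in res.cutoffs.achieved_inbag.items()}})
            # paired comparisons against the plasma reference
            ref = config.reference_biomarker
            for csf in config.biomarkers:
                if csf == ref:
                    continue
                key = {**okey, "plasma": ref, "csf": csf}
                try:
                    cc = complete_case_subset(
                        sub, [ref, csf, outcome.source_column])
                    for mode in config.modes:
                        pm = PairedBiomarkerModel.from_cohort(
                            cc, ref, csf, outcome, mode=mode,
                            spec_floor=config.spec_floor,
                            sens_target=config.sens_target,
                            spec_target=config.spec_target)
                        pres = pm.fit(
                            n_resamples=config.n_resamples,
                            seed=_combo_seed(config.seed, outcome.name,
                                             subgroup, ref, csf, mode))
                        frame = pres.verdicts_frame()
                        frame["outcome"] = outcome.name
                        frame["subgroup"] = subgroup
                        diff_rows.append(frame)
                        if mode == config.modes[0]:
                            a = pres.auc_comparison
                            delong_rows.append({**key, "auc_plasma": a.auc_a,
                                                "auc_csf": a.auc_b,
                                                "difference": a.difference,
                                                "ci_low": a.ci_low,
                                                "ci_high": a.ci_high,
                                                "p_value": a.p_value})
                except Exception as exc:
                    skip(str(exc), **key)

    report = {
        "auc": pd.DataFrame(auc_rows),
        "metrics": (pd.concat(metric_rows, ignore_index=True)
                    if metric_rows else pd.DataFrame()),
        "differences": (pd.concat(diff_rows, ignore_index=True)
                        if diff_rows else pd.DataFrame()),
        "delong": pd.DataFrame(delong_rows),
        "cutoffs": cutoff_rows,
        "skipped": skipped,
        "provenance": {"config_hash": config.digest(), "seed": config.seed,
                       "version": __version__},
    }
    if config.run_logistic_covariate:
        report["logistic_covariate"] = _logistic_sensitivity(config, table)
    if config.transfer_cutoffs:
        report["transfer"] = _transfer_sensitivity(config, table)
    return report


def _logistic_sensitivity(config: AnalysisConfig, table: CohortTable):
    """Re-run the reference evaluation with p-tau217 adjusted for
    non-phosphorylated tau via logistic regression instead of the ratio."""
    rows = []
    for outcome in config.outcomes:
        sub = table.subgroup("CI")
        try:
            cc = complete_case_subset(
                sub, ["ptau217", "nonphospho_tau", outcome.source_column])
            y = derive_outcome(cc, outcome).to_numpy()
            lp = fit_logistic_score(cc.df["ptau217"].to_numpy(),
                                    cc.df["nonphospho_tau"].to_numpy(), y)
            model = BiomarkerCutoffModel(lp, y, "higher_is_positive", "single",
                                         config.spec_floor, name="logit_ptau217")
            res = model.fit(n_resamples=config.n_resamples,
                            seed=_combo_seed(config.seed, outcome.name, "logit"))
            frame = res.estimates_frame()
            frame["outcome"] = outcome.name
            rows.append(frame)
        except Exception as exc:
            logger.warning("logistic covariate analysis skipped for %s: %s",
                           outcome.name, exc)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def _transfer_sensitivity(config: AnalysisConfig, table: CohortTable):
    """Evaluate externally supplied cutoffs (e.g. derived in another cohort)."""
    from .cutpoints import CutoffSet

    rows = []
    for biomarker, spec in config.transfer_cutoffs.items():
        cut = spec if isinstance(spec, CutoffSet) else CutoffSet(**spec)
        for outcome in config.outcomes:
            sub = table.subgroup("CI")
            try:
                cc = complete_case_subset(sub, [biomarker, outcome.source_column])
                y = derive_outcome(cc, outcome).to_numpy()
                est = transfer_evaluation(
                    cut, cc.df[biomarker].to_numpy(), y,
                    config=BootstrapConfig(
                        n_resamples=config.n_resamples,
                        seed=_combo_seed(config.seed, outcome.name,
                                         biomarker, "transfer")))
                for m, e in est.items():
                    rows.append({"biomarker": biomarker, "outcome": outcome.name,
                                 "metric": m, "observed": e.observed,
                                 "boot_mean": e.point, "ci_low": e.ci_low,
                                 "ci_high": e.ci_high})
            except Exception as exc:
                logger.warning("transfer analysis skipped for %s/%s: %s",
                               biomarker, outcome.name, exc)
    return pd.DataFrame(rows)


def write_report(report: dict, out_dir) -> None:
    """Write the run report: CSV tables plus a JSON metadata block."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("auc", "metrics", "differences", "delong",
                 "logistic_covariate", "transfer"):
        if name in report and len(report[name]):
            report[name].to_csv(out / f"{name}.csv", index=False)
    meta = {"provenance": report["provenance"], "skipped": report["skipped"],
            "cutoffs": report["cutoffs"]}
    (out / "report.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
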