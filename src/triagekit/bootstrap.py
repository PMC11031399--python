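"""Stratified bootstrap estimation and plasma-vs-CSF equivalence testing.

Resampling is with replacement *within each outcome stratum*, preserving the
positive/negative counts of every replicate (n = 1,000 by default).  Point
estimates are bootstrap means with 2.5/97.5 percentile CIs; the observed
full-sample statistic is always reported alongside.  For paired plasma-CSF
differences one resample index vector per replicate drives both biomarkers.

The clinical verdict rule: the two tests are *equivalent* when the 95% CI of
the mean difference (oriented so that a positive value favours plasma)
includes zero, *plasma superior* when the whole CI is above zero, and *CSF
favoured* when it is entirely below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cutpoints import CutoffSet, classify
from .metrics import labels_to_codes, metrics_from_codes
from .roc import _check_labels

__all__ = [
    "BootstrapConfig",
    "EstimateWithCI",
    "DifferenceVerdict",
    "stratified_resample",
    "inbag_estimates",
    "paired_difference",
    "oob_bootstrap",
    "transfer_evaluation",
    "verdict_from_ci",
]

DEFAULT_METRICS = ("accuracy", "ppv", "npv", "sensitivity", "specificity",
                   "intermediate_fraction")


@dataclass(frozen=True)
class BootstrapConfig:
    n_resamples: int = 1000
    stratify_by_outcome: bool = True
    ci_level: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass(frozen=True)
class EstimateWithCI:
    """Bootstrap mean + percentile CI, with the observed full-sample value."""

    point: float
    observed: float
    ci_low: float
    ci_high: float
    n_valid_replicates: int
    unreliable: bool = False  # > half the replicates undefined


@dataclass(frozen=True)
class DifferenceVerdict:
    """Plasma-minus-CSF difference for one metric and its clinical verdict."""

    metric: str
    difference: EstimateWithCI
    verdict: str  # equivalent | plasma_superior | csf_favored


def verdict_from_ci(ci_low: float, ci_high: float) -> str:
    """Three-way verdict from the CI of a positive-favours-plasma difference."""
    if np.isnan(ci_low) or np.isnan(ci_high):
        return "equivalent"
    if ci_low > 0:
        return "plasma_superior"
    if ci_high < 0:
        return "csf_favored"
    return "equivalent"


def stratified_resample(labels, rng: np.random.Generator,
                        stratify: bool = True) -> np.ndarray:
    """Index vector of one bootstrap resample.

    With stratification (default) each outcome stratum is resampled with
    replacement to exactly its original size, so every replicate preserves
    the observed class counts.
    """
    y = _check_labels(labels)
    n = len(y)
    if not stratify:
        return rng.integers(0, n, size=n)
    idx = np.empty(n, dtype=np.int64)
    start = 0
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        k = len(members)
        idx[start:start + k] = members[rng.integers(0, k, size=k)]
        start += k
    return idx


def _aggregate(observed: float, draws: np.ndarray, ci_level: float) -> EstimateWithCI:
    draws = np.asarray(draws, dtype=float)
    valid = draws[~np.isnan(draws)]
    n_valid = len(valid)
    unreliable = n_valid < len(draws) / 2
    if n_valid == 0:
        return EstimateWithCI(np.nan, observed, np.nan, np.nan, 0, True)
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(valid, [alpha, 1 - alpha])  # linear interpolation
    return EstimateWithCI(float(valid.mean()), observed, float(lo), float(hi),
                          n_valid, unreliable)


def _replicate_metrics(codes: np.ndarray, truth: np.ndarray, idx_iter,
                       metric_list) -> dict[str, np.ndarray]:
    out = {m: [] for m in metric_list}
    for idx in idx_iter:
        ms = metrics_from_codes(codes[idx], truth[idx])
        for m in metric_list:
            out[m].append(ms[m])
    return {m: np.asarray(v) for m, v in out.items()}


def _resample_indices(labels, config: BootstrapConfig):
    rng = np.random.default_rng(config.seed)
    return [stratified_resample(labels, rng, config.stratify_by_outcome)
            for _ in range(config.n_resamples)]


def inbag_estimates(scores, labels, cutoff_rule, metric_list=DEFAULT_METRICS,
                    config: BootstrapConfig = BootstrapConfig()) -> dict[str, EstimateWithCI]:
    """In-bag bootstrap: cutoffs derived once on the full sample and held
    fixed; metrics recomputed on every stratified resample.

    ``cutoff_rule`` maps ``(scores, labels) -> CutoffSet``.
    """
    truth = np.asarray(labels, dtype=float)
    cutoffs = cutoff_rule(scores, labels)
    codes = labels_to_codes(classify(np.asarray(scores, dtype=float), cutoffs))
    observed = metrics_from_codes(codes, truth)
    draws = _replicate_metrics(codes, truth, _resample_indices(labels, config),
                               metric_list)
    result = {m: _aggregate(observed[m], draws[m], config.ci_level)
              for m in metric_list}
    for m, est in result.items():
        if est.unreliable:
            warnings.warn(f"metric {m!r}: more than half of the bootstrap "
                          "replicates were undefined", stacklevel=2)
    return result


def paired_difference(scores_plasma, scores_csf, labels, cutoff_rule_plasma,
                      cutoff_rule_csf, metric_list=DEFAULT_METRICS,
                      config: BootstrapConfig = BootstrapConfig()):
    """Paired plasma-vs-CSF metric differences with equivalence verdicts.

    Both biomarkers must be measured on the same subjects (complete cases for
    both and the outcome).  One stratified index vector per replicate is
    applied to both, so the within-replicate difference is paired.  The
    difference is plasma - CSF except for ``intermediate_fraction``, where it
    is CSF - plasma: fewer intermediates favours plasma, and expressing the
    intermediate count as a fraction of the sample scales the difference to a
    maximum of 1, comparable with the other metrics.

    Returns ``(verdicts, estimates)`` where estimates maps
    ``{"plasma"|"csf"} -> {metric -> EstimateWithCI}``.
    """
    sp = np.asarray(scores_plasma, dtype=float)
    sc = np.asarray(scores_csf, dtype=float)
    truth = np.asarray(labels, dtype=float)
    if len(sp) != len(sc) or len(sp) != len(truth):
        raise ValueError("paired comparison requires aligned complete-case vectors")
    if np.isnan(sp).any() or np.isnan(sc).any() or np.isnan(truth).any():
        raise ValueError("missing values present; pair on the complete-case "
                         "intersection first")
    codes_p = labels_to_codes(classify(sp, cutoff_rule_plasma(sp, labels)))
    codes_c = labels_to_codes(classify(sc, cutoff_rule_csf(sc, labels)))
    obs_p = metrics_from_codes(codes_p, truth)
    obs_c = metrics_from_codes(codes_c, truth)
    indices = _resample_indices(labels, config)
    draws_p = _replicate_metrics(codes_p, truth, indices, metric_list)
    draws_c = _replicate_metrics(codes_c, truth, indices, metric_list)
    estimates = {
        "plasma": {m: _aggregate(obs_p[m], draws_p[m], config.ci_level)
                   for m in metric_list},
        "csf": {m: _aggregate(obs_c[m], draws_c[m], config.ci_level)
                for m in metric_list},
    }
    verdicts = []
    for m in metric_list:
        if m == "intermediate_fraction":
            diff_draws = draws_c[m] - draws_p[m]
            diff_obs = obs_c[m] - obs_p[m]
        else:
            diff_draws = draws_p[m] - draws_c[m]
            diff_obs = obs_p[m] - obs_c[m]
        est = _aggregate(diff_obs, diff_draws, config.ci_level)
        verdicts.append(DifferenceVerdict(m, est,
                                          verdict_from_ci(est.ci_low, est.ci_high)))
    return verdicts, estimates


def oob_bootstrap(scores, labels, cutoff_rule, metric_list=DEFAULT_METRICS,
                  config: BootstrapConfig = BootstrapConfig()):
    """Out-of-bag bootstrap: cutoffs re-derived on each stratified in-bag
    resample; metrics computed on the subjects left out of that resample.

    Replicates whose out-of-bag set lacks an outcome class are skipped and
    counted.  Returns ``(estimates, info)`` with ``info['oob_fraction']`` the
    mean fraction of subjects out of bag (about 36.8% for large n).
    """
    s = np.asarray(scores, dtype=float)
    truth = np.asarray(labels, dtype=float)
    full_cut = cutoff_rule(s, labels)
    observed = metrics_from_codes(labels_to_codes(classify(s, full_cut)), truth)
    rng = np.random.default_rng(config.seed)
    n = len(s)
    draws = {m: [] for m in metric_list}
    oob_sizes = []
    n_skipped = 0
    for _ in range(config.n_resamples):
        idx = stratified_resample(labels, rng, config.stratify_by_outcome)
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        oob_sizes.append(len(oob))
        y_oob = truth[oob]
        if len(oob) == 0 or len(np.unique(y_oob)) < 2:
            n_skipped += 1
            for m in metric_list:
                draws[m].append(np.nan)
            continue
        cut = cutoff_rule(s[idx], truth[idx].astype(int))
        ms = metrics_from_codes(labels_to_codes(classify(s[oob], cut)), y_oob)
        for m in metric_list:
            draws[m].append(ms[m])
    if n_skipped == config.n_resamples:
        raise RuntimeError("every out-of-bag replicate lacked an outcome class")
    estimates = {m: _aggregate(observed[m], np.asarray(draws[m]), config.ci_level)
                 for m in metric_list}
    info = {"oob_fraction": float(np.mean(oob_sizes)) / n, "n_skipped": n_skipped}
    return estimates, info


def transfer_evaluation(cutoffs: CutoffSet, scores, labels,
                        metric_list=DEFAULT_METRICS,
                        config: BootstrapConfig = BootstrapConfig()) -> dict[str, EstimateWithCI]:
    """Evaluate externally derived cutoffs on a new cohort with bootstrap CIs.

    Only the evaluation cohort is resampled; the cutoffs stay fixed, which is
    the cross-cohort transfer design (and exposes calibration drift when the
    assay scales differ).
    """
    s = np.asarray(scores, dtype=float)
    truth = np.asarray(labels, dtype=float)
    codes = labels_to_codes(classify(s, cutoffs))
    observed = metrics_from_codes(codes, truth)
    draws = _replicate_metrics(codes, truth, _resample_indices(labels, config),
                               metric_list)
    return {m: _aggregate(observed[m], draws[m], config.ci_level)
            for m in metric_list}
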