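"""Synthetic cohorts with the statistical structure of a plasma/CSF
biomarker study.

The generative model per subject:

* a binary disease state ``S`` ~ Bernoulli(prevalence) within each cognitive
  group (CU vs cognitively impaired);
* a continuous PET reference value drawn from a state-conditional Gaussian
  (defaults emulate the amyloid-PET Centiloid distributions of the negative
  and positive triage groups: mean (s.d.) 0.4 (20.3) vs 91.4 (30.1));
* each fluid biomarker on a latent Gaussian scale:

  .. math:: b = s \\,(d\\,S + \\sqrt{\\rho}\\,\\sigma z + \\sqrt{1-\\rho}\\,\\sigma\\varepsilon)

  where ``d`` is the latent loading (separation between state means), ``z``
  a severity term shared across biomarkers (correlating plasma and CSF so
  paired comparisons are meaningful), ``eps`` independent noise, ``sigma``
  the noise scale and ``s`` +-1 by orientation.  The binormal AUC of such a
  biomarker is the closed form ``Phi(d / sqrt(2) / sigma)``.

All randomness flows from a single ``numpy`` Generator seeded once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import BiomarkerSpec, CohortTable, Orientation, compute_ptau_ratio

__all__ = [
    "BiomarkerParams",
    "GroupParams",
    "SimulationConfig",
    "generate_cohort",
    "binormal_scores",
    "theoretical_auc",
    "inject_missingness",
]


@dataclass(frozen=True)
class BiomarkerParams:
    """Latent-scale parameters of one simulated biomarker."""

    latent_loading: float = 2.3
    noise_sd: float = 1.0
    orientation: Orientation = Orientation.HIGHER_IS_POSITIVE

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        object.__setattr__(self, "orientation", Orientation(self.orientation))


@dataclass(frozen=True)
class GroupParams:
    """State mixture and reference-measure parameters for one cognitive group."""

    prevalence: float
    ref_neg_mean: float = 0.4
    ref_neg_sd: float = 20.3
    ref_pos_mean: float = 91.4
    ref_pos_sd: float = 30.1
    suvr_neg_mean: float = 1.15
    suvr_neg_sd: float = 0.10
    suvr_pos_mean: float = 1.60
    suvr_pos_sd: float = 0.30

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie strictly inside (0, 1)")
        for sd in (self.ref_neg_sd, self.ref_pos_sd, self.suvr_neg_sd, self.suvr_pos_sd):
            if sd <= 0:
                raise ValueError("reference s.d.s must be > 0")


def _default_biomarkers() -> dict[str, BiomarkerParams]:
    # Plasma ratio the strongest discriminator, CSF Abeta42/40 the weakest,
    # mirroring the ordering seen for tau-PET prediction.
    return {
        "pct_ptau217": BiomarkerParams(2.6, 1.0, Orientation.HIGHER_IS_POSITIVE),
        "csf_ptau181_ab42": BiomarkerParams(2.2, 1.0, Orientation.HIGHER_IS_POSITIVE),
        "csf_ab42_40": BiomarkerParams(1.7, 1.0, Orientation.LOWER_IS_POSITIVE),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort draw.

    Defaults follow the study's operating conditions: outcome prevalence 0.15
    among cognitively unimpaired and 0.50 among cognitively impaired subjects,
    plasma-CSF shared-severity correlation ``rho`` = 0.6 (a free simulation
    parameter; the study reports no joint correlation), Gaussian latent
    biomarker scales, and no missingness unless requested.
    """

    n_cu: int = 720
    n_ci: int = 702
    cu: GroupParams = field(default_factory=lambda: GroupParams(prevalence=0.15))
    ci: GroupParams = field(default_factory=lambda: GroupParams(prevalence=0.50))
    biomarkers: dict[str, BiomarkerParams] = field(default_factory=_default_biomarkers)
    rho: float = 0.6
    missing_rates: dict[str, float] = field(default_factory=dict)
    visual_read_error: float = 0.02
    clinical_dx_error: float = 0.10
    exact_prevalence: bool = False
    exp_transform: bool = False
    cohort_name: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cu < 0 or self.n_ci < 0:
            raise ValueError("subject counts must be >= 0")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        for col, r in self.missing_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"missing rate for {col!r} outside [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for grp in ("cu", "ci"):
            if grp in d and isinstance(d[grp], dict):
                d[grp] = GroupParams(**d[grp])
        if "biomarkers" in d:
            d["biomarkers"] = {
                k: (BiomarkerParams(**v) if isinstance(v, dict) else v)
                for k, v in d["biomarkers"].items()
            }
        return cls(**d)


def theoretical_auc(d: float, sd0: float = 1.0, sd1: float = 1.0) -> float:
    """Exact AUC of the two-Gaussian (binormal) model: Phi(d / sqrt(sd0^2 + sd1^2))."""
    if sd0 <= 0 or sd1 <= 0:
        raise ValueError("noise s.d.s must be > 0")
    return float(norm.cdf(d / np.hypot(sd0, sd1)))


def binormal_scores(n_neg: int, n_pos: int, d: float, sd0: float = 1.0,
                    sd1: float = 1.0, seed=None):
    """Tie-free binormal scores and labels: negatives N(0, sd0), positives N(d, sd1).

    Returns ``(scores, labels)`` with labels 0/1.  This is the elementary
    simulation harness behind the cohort generator; its population AUC is
    :func:`theoretical_auc`.
    """
    rng = np.random.default_rng(seed)
    scores = np.concatenate([
        rng.normal(0.0, sd0, size=n_neg),
        rng.normal(d, sd1, size=n_pos),
    ])
    labels = np.concatenate([np.zeros(n_neg, int), np.ones(n_pos, int)])
    return scores, labels


def _simulate_group(rng: np.random.Generator, n: int, status_pool: list[str],
                    gp: GroupParams, cfg: SimulationConfig, start: int):
    if cfg.exact_prevalence:
        n_pos = int(round(n * gp.prevalence))
        state = np.zeros(n, int)
        state[:n_pos] = 1
        rng.shuffle(state)
    else:
        state = (rng.random(n) < gp.prevalence).astype(int)

    centiloid = np.where(
        state == 1,
        rng.normal(gp.ref_pos_mean, gp.ref_pos_sd, n),
        rng.normal(gp.ref_neg_mean, gp.ref_neg_sd, n),
    )
    suvr = np.where(
        state == 1,
        rng.normal(gp.suvr_pos_mean, gp.suvr_pos_sd, n),
        rng.normal(gp.suvr_neg_mean, gp.suvr_neg_sd, n),
    )
    suvr = np.clip(suvr, 0.05, None)  # SUVR is a positive ratio

    shared = rng.normal(size=n)
    cols: dict[str, np.ndarray] = {}
    for name, bp in cfg.biomarkers.items():
        eps = rng.normal(size=n)
        latent = (bp.latent_loading * state
                  + np.sqrt(cfg.rho) * bp.noise_sd * shared
                  + np.sqrt(1 - cfg.rho) * bp.noise_sd * eps)
        if bp.orientation is Orientation.LOWER_IS_POSITIVE:
            latent = -latent
        if cfg.exp_transform:
            latent = np.exp(latent)  # strictly increasing: rank statistics unchanged
        cols[name] = latent

    visual = np.where(rng.random(n) < cfg.visual_read_error, 1 - state, state)
    status = rng.choice(status_pool, size=n) if len(status_pool) > 1 else \
        np.repeat(status_pool[0], n)
    # clinical AD diagnosis: only defined among impaired subjects, 0 for CU
    dx = np.where(rng.random(n) < cfg.clinical_dx_error, 1 - state, state)
    dx = np.where(status == "CU", 0, dx)

    df = pd.DataFrame({
        "subject_id": [f"S{start + i:05d}" for i in range(n)],
        "cohort": cfg.cohort_name,
        "cognitive_status": status,
        "visit_time": 0.0,
        **cols,
        "centiloid": centiloid,
        "tau_suvr": suvr,
        "visual_read": visual.astype(float),
        "clinical_dx_ad": dx.astype(float),
    })
    return df


def generate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw a synthetic cohort; bitwise reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    frames = []
    if config.n_cu:
        frames.append(_simulate_group(rng, config.n_cu, ["CU"],
                                      config.cu, config, 0))
    if config.n_ci:
        frames.append(_simulate_group(rng, config.n_ci, ["MCI", "dementia"],
                                      config.ci, config, config.n_cu))
    if not frames:
        raise ValueError("empty simulation: n_cu + n_ci must be > 0")
    df = pd.concat(frames, ignore_index=True)

    specs = {name: BiomarkerSpec(name, bp.orientation)
             for name, bp in config.biomarkers.items()}
    if "pct_ptau217" in df.columns:
        # decompose %p-tau217 into plausible component concentrations so the
        # ratio-vs-covariate sensitivity analysis has raw inputs to work with
        nonphospho = np.exp(rng.normal(np.log(30.0), 0.3, len(df)))
        df["nonphospho_tau"] = nonphospho
        df["ptau217"] = np.exp(df["pct_ptau217"]) * nonphospho / 100.0
        df["pct_ptau217"] = compute_ptau_ratio(df["ptau217"], df["nonphospho_tau"])
        specs.setdefault("ptau217",
                         BiomarkerSpec("ptau217", Orientation.HIGHER_IS_POSITIVE,
                                       "pg/ml"))
        specs.setdefault("nonphospho_tau",
                         BiomarkerSpec("nonphospho_tau",
                                       Orientation.HIGHER_IS_POSITIVE, "pg/ml"))
    table = CohortTable(df, specs)
    if config.missing_rates:
        table = inject_missingness(table, config.missing_rates,
                                   rng.integers(2**31 - 1))
    return table


def inject_missingness(table: CohortTable, rates: dict[str, float], seed=None) -> CohortTable:
    """Independently blank each targeted cell with its column's rate (seeded)."""
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    for col, rate in rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"missing rate for {col!r} outside [0, 1]")
        if col not in df.columns:
            raise ValueError(f"column {col!r} not in cohort")
        mask = rng.random(len(df)) < rate
        df.loc[mask, col] = np.nan
    return CohortTable(df, dict(table.biomarker_specs))
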