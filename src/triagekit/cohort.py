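"""Subject-level cohort data model.

A cohort is a table with one row per subject visit, carrying fluid-biomarker
concentrations (plasma %p-tau217 and its components, CSF ratios), continuous
PET reference measures (amyloid Centiloids, tau SUVR) and optional binary
outcomes (visual read, clinical AD diagnosis).  Binary study outcomes are
*derived* from these columns via explicit :class:`OutcomeSpec` rules; biomarker
directionality is always declared via :class:`BiomarkerSpec`, never inferred
from the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Orientation",
    "BiomarkerSpec",
    "OutcomeSpec",
    "CohortTable",
    "COHORT_COLUMNS",
    "COGNITIVE_STATUSES",
    "compute_ptau_ratio",
    "derive_outcome",
    "complete_case_subset",
    "read_cohort",
    "write_cohort",
]

#: Canonical column order of the cohort CSV dialect.
COHORT_COLUMNS = [
    "subject_id",
    "cohort",
    "cognitive_status",
    "visit_time",
    "ptau217",
    "nonphospho_tau",
    "pct_ptau217",
    "csf_ab42_40",
    "csf_ptau181_ab42",
    "centiloid",
    "tau_suvr",
    "visual_read",
    "clinical_dx_ad",
]

COGNITIVE_STATUSES = ("CU", "MCI", "dementia")

#: Columns holding fluid-biomarker scores (candidates for BiomarkerSpec names).
BIOMARKER_COLUMNS = ("ptau217", "nonphospho_tau", "pct_ptau217",
                     "csf_ab42_40", "csf_ptau181_ab42")

_CONTINUOUS_SOURCES = ("centiloid", "tau_suvr")
_BINARY_SOURCES = ("visual_read", "clinical_dx_ad")


class Orientation(str, Enum):
    """Which direction of a biomarker is pathological.

    Plasma %p-tau217 and CSF p-tau181/Abeta42 rise with pathology
    (``HIGHER_IS_POSITIVE``); the CSF Abeta42/40 ratio falls
    (``LOWER_IS_POSITIVE``).
    """

    HIGHER_IS_POSITIVE = "higher_is_positive"
    LOWER_IS_POSITIVE = "lower_is_positive"


@dataclass(frozen=True)
class BiomarkerSpec:
    """Name, pathological direction and units of one fluid biomarker."""

    name: str
    orientation: Orientation
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        if not self.name:
            raise ValueError("biomarker name must be non-empty")


@dataclass(frozen=True)
class OutcomeSpec:
    """Rule deriving a binary outcome from a reference column.

    ``threshold`` is required for the continuous sources (``centiloid``,
    ``tau_suvr``) and forbidden for the binary ones.  ``rule`` selects the
    boundary inequality: amyloid PET positivity uses ``ge`` (Centiloids >= 37)
    while tau PET positivity uses strict ``gt`` (SUVR > 1.32).
    """

    name: str
    source_column: str
    threshold: float | None = None
    rule: str = "ge"

    def __post_init__(self) -> None:
        if self.source_column not in _CONTINUOUS_SOURCES + _BINARY_SOURCES:
            raise ValueError(
                f"unknown outcome source column {self.source_column!r}; "
                f"expected one of {_CONTINUOUS_SOURCES + _BINARY_SOURCES}"
            )
        if self.source_column in _CONTINUOUS_SOURCES:
            if self.threshold is None:
                raise ValueError(
                    f"continuous source {self.source_column!r} requires a threshold"
                )
            if self.rule not in ("ge", "gt"):
                raise ValueError(f"rule must be 'ge' or 'gt', got {self.rule!r}")
        elif self.threshold is not None:
            raise ValueError(
                f"binary source {self.source_column!r} takes no threshold"
            )


#: Default outcome rules as used throughout the analysis.
AMYLOID_PET_OUTCOME = OutcomeSpec("abeta_pet", "centiloid", threshold=37.0, rule="ge")
TAU_PET_OUTCOME = OutcomeSpec("tau_pet", "tau_suvr", threshold=1.32, rule="gt")
VISUAL_READ_OUTCOME = OutcomeSpec("visual_read", "visual_read")
CLINICAL_AD_OUTCOME = OutcomeSpec("clinical_ad", "clinical_dx_ad")

DEFAULT_BIOMARKER_SPECS = (
    BiomarkerSpec("pct_ptau217", Orientation.HIGHER_IS_POSITIVE, "%"),
    BiomarkerSpec("csf_ptau181_ab42", Orientation.HIGHER_IS_POSITIVE, "ratio"),
    BiomarkerSpec("csf_ab42_40", Orientation.LOWER_IS_POSITIVE, "ratio"),
    BiomarkerSpec("ptau217", Orientation.HIGHER_IS_POSITIVE, "pg/ml"),
    BiomarkerSpec("nonphospho_tau", Orientation.HIGHER_IS_POSITIVE, "pg/ml"),
)


@dataclass
class CohortTable:
    """A cohort: one pandas row per subject visit plus biomarker metadata.

    Invariants checked on construction: subject_id unique per visit_time,
    cognitive_status in {CU, MCI, dementia}, tau_suvr > 0 when present, and
    every biomarker column present in the frame has a spec.
    """

    df: pd.DataFrame
    biomarker_specs: dict[str, BiomarkerSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        if "subject_id" not in df.columns:
            raise ValueError("cohort frame requires a subject_id column")
        if df["subject_id"].isna().any() or (df["subject_id"].astype(str) == "").any():
            raise ValueError("subject_id must be non-empty for every record")
        visit = df["visit_time"] if "visit_time" in df.columns else pd.Series(
            np.zeros(len(df)), index=df.index
        )
        key = pd.MultiIndex.from_arrays([df["subject_id"], visit.fillna(0.0)])
        if key.duplicated().any():
            raise ValueError("subject_id must be unique per visit_time")
        if "cognitive_status" in df.columns:
            status = df["cognitive_status"].dropna()
            bad = set(status) - set(COGNITIVE_STATUSES)
            if bad:
                raise ValueError(f"invalid cognitive_status values: {sorted(bad)}")
        if "tau_suvr" in df.columns:
            suvr = pd.to_numeric(df["tau_suvr"], errors="coerce")
            if (suvr.dropna() <= 0).any():
                raise ValueError("tau_suvr must be > 0 when present")
        for col in BIOMARKER_COLUMNS:
            if col in df.columns and df[col].notna().any():
                if self.biomarker_specs and col not in self.biomarker_specs:
                    raise ValueError(f"biomarker column {col!r} has no BiomarkerSpec")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        shared = [c for c in COHORT_COLUMNS if c in self.df.columns or c in other.df.columns]
        a = self.df.reindex(columns=shared).reset_index(drop=True)
        b = other.df.reindex(columns=shared).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        # units are presentation metadata the CSV dialect does not carry
        return ({k: v.orientation for k, v in self.biomarker_specs.items()}
                == {k: v.orientation for k, v in other.biomarker_specs.items()})

    def subgroup(self, name: str) -> "CohortTable":
        """Return the 'all', 'CU' or 'CI' (MCI or dementia) subgroup."""
        if name == "all":
            return self
        if name == "CU":
            mask = self.df["cognitive_status"] == "CU"
        elif name == "CI":
            mask = self.df["cognitive_status"].isin(["MCI", "dementia"])
        else:
            raise ValueError(f"unknown subgroup {name!r}; expected all/CU/CI")
        return CohortTable(self.df.loc[mask].copy(), dict(self.biomarker_specs))


def compute_ptau_ratio(ptau217, nonphospho):
    """%p-tau217: the p-tau217 concentration as a percentage of
    non-phosphorylated mid-region tau.

    Accepts scalars or array-likes.  Missing values (NaN) propagate; a
    non-positive denominator raises ``ValueError`` (the ratio is undefined).
    """
    p = np.asarray(ptau217, dtype=float)
    q = np.asarray(nonphospho, dtype=float)
    if np.any(q[~np.isnan(q)] <= 0):
        raise ValueError("non-phosphorylated tau concentration must be > 0")
    with np.errstate(invalid="ignore"):
        out = 100.0 * p / q
    if out.ndim == 0:
        return float(out)
    return out


def derive_outcome(table: CohortTable, spec: OutcomeSpec) -> pd.Series:
    """Binary outcome (1.0/0.0, NaN for missing) aligned to the cohort rows."""
    df = table.df
    if spec.source_column not in df.columns:
        raise ValueError(f"source column {spec.source_column!r} not in cohort")
    src = pd.to_numeric(df[spec.source_column], errors="coerce")
    if spec.source_column in _BINARY_SOURCES:
        bad = src.dropna()[~src.dropna().isin([0, 1])]
        if len(bad):
            raise ValueError(
                f"binary source {spec.source_column!r} contains non-binary values"
            )
        out = src.astype(float)
    else:
        if spec.rule == "ge":
            pos = src >= spec.threshold
        else:
            pos = src > spec.threshold
        out = pos.astype(float)
        out[src.isna()] = np.nan
    out.name = spec.name
    return out


def complete_case_subset(table: CohortTable, required_columns: list[str]) -> CohortTable:
    """Retain only rows with every required column non-missing (original order).

    The number of dropped rows is logged; an all-missing result warns.
    """
    missing_cols = [c for c in required_columns if c not in table.df.columns]
    if missing_cols:
        raise ValueError(f"columns not in cohort: {missing_cols}")
    if not required_columns:
        return table
    mask = table.df[required_columns].notna().all(axis=1)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("complete_case_subset: dropped %d of %d records missing %s",
                    n_drop, len(table), required_columns)
    out = CohortTable(table.df.loc[mask].copy(), dict(table.biomarker_specs))
    if len(out) == 0:
        warnings.warn("complete-case subset is empty", stacklevel=2)
    return out


def read_cohort(path, specs: dict[str, BiomarkerSpec] | None = None) -> CohortTable:
    """Read a cohort CSV (empty field = missing).

    Unknown columns are dropped with a warning; non-numeric entries in numeric
    columns raise with the offending row number.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "cohort": str,
                                  "cognitive_status": str})
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown cohort columns: {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    numeric_cols = [c for c in COHORT_COLUMNS if c in df.columns
                    and c not in ("subject_id", "cohort", "cognitive_status")]
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(
                f"non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at file row {row}"
            )
        df[col] = parsed
    if specs is None:
        specs = {s.name: s for s in DEFAULT_BIOMARKER_SPECS if s.name in df.columns}
    return CohortTable(df, dict(specs))


def write_cohort(table: CohortTable, path) -> None:
    """Write the cohort CSV dialect (round-trip stable; missing = empty field)."""
    cols = [c for c in COHORT_COLUMNS if c in table.df.columns]
    table.df.to_csv(path, columns=cols, index=False)
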