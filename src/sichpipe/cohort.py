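"""Per-patient sICH cohort table: loading, validation and derived fields.

The cohort is a small per-patient table of clinical severity scores
(ICH score, GCS, 90-day mRS, modified Graeb score), radiological volumes
(intraparenchymal hemorrhage and perihematomal edema, in ml), the
neutrophil-to-lymphocyte ratio, and absolute counts of the DEspR+CD11b+
("rogue") and NET-forming neutrophil subsets in cells/μl.  A 13-patient
pilot cohort ships with the package as ``data/pilot_cohort.csv``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, ValidationError

#: Required columns, in canonical order.
REQUIRED_COLUMNS = [
    "id", "sex", "age", "pmhx", "ich_site", "icu_days", "cmo_day",
    "death_day", "ich_score", "mrs_90d", "fcm_day", "gcs",
    "iph_vol", "phe_vol", "mgs", "nlr", "rogue_n_count", "net_n_count",
]

#: Optional plasma-biomarker columns; absent in the packaged fixture.
OPTIONAL_COLUMNS = ["il6", "mpo", "sc5b9", "et1", "mt_ndna_ratio"]

_NUMERIC = [
    "age", "icu_days", "cmo_day", "death_day", "ich_score", "mrs_90d",
    "fcm_day", "gcs", "iph_vol", "phe_vol", "mgs", "nlr",
    "rogue_n_count", "net_n_count",
] + OPTIONAL_COLUMNS

# (column, lower bound, upper bound); None = unbounded on that side.
_BOUNDS = [
    ("gcs", 3, 15),
    ("mrs_90d", 0, 6),
    ("ich_score", 0, 6),
    ("mgs", 0, 32),
    ("iph_vol", 0, None),
    ("phe_vol", 0, None),
    ("rogue_n_count", 0, None),
    ("net_n_count", 0, None),
]


@dataclass
class CohortTable:
    """Validated cohort with one row per patient.

    ``df`` keeps the canonical column order; missing optional values are
    ``NaN``.  ``n`` always equals the number of rows.
    """

    df: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n

    def column(self, name: str) -> np.ndarray:
        """Return a column as a numpy array, raising if absent."""
        if name not in self.df.columns:
            raise SchemaError(f"cohort has no column {name!r}")
        return self.df[name].to_numpy()


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate patient id(s): {dupes}")
    for col, lo, hi in _BOUNDS:
        vals = df[col]
        bad = pd.Series(False, index=df.index)
        if lo is not None:
            bad |= vals < lo
        if hi is not None:
            bad |= vals > hi
        bad &= vals.notna()
        if bad.any():
            row = df.loc[bad, "id"].iloc[0]
            raise ValidationError(
                f"column {col!r} out of range [{lo}, {hi}] for patient id {row}"
            )
    nlr_bad = (df["nlr"] <= 0) & df["nlr"].notna()
    if nlr_bad.any():
        row = df.loc[nlr_bad, "id"].iloc[0]
        raise ValidationError(f"nlr must be > 0 (patient id {row})")


def load_cohort(path: str | Path) -> CohortTable:
    """Load and validate a cohort CSV.

    Empty cells become ``NaN`` (explicit missing markers); parsing uses the
    C locale regardless of environment.  Raises :class:`SchemaError` when a
    required column is absent and :class:`ValidationError` when a value is
    out of range, naming the offending patient id.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "pmhx": str,
                                  "ich_site": str})
    for col in _NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    _validate(df)
    ordered = REQUIRED_COLUMNS + [c for c in df.columns
                                  if c not in REQUIRED_COLUMNS]
    return CohortTable(df[ordered].reset_index(drop=True))


def save_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort back to CSV, round-trippable through load_cohort."""
    cohort.df.to_csv(path, index=False)


def packaged_cohort() -> CohortTable:
    """Load the 13-patient pilot cohort shipped with the package."""
    with resources.as_file(
        resources.files("sichpipe.data") / "pilot_cohort.csv"
    ) as p:
        return load_cohort(p)


def derive_fields(cohort: CohortTable) -> CohortTable:
    """Return a copy with derived flags and K/μl count columns.

    Adds ``survivor`` (no recorded death day), ``ivh`` (modified Graeb
    score > 0, the only printed indicator of intraventricular extension),
    ``cmo`` (comfort-measures-only day recorded), and ``rogue_n_k`` /
    ``net_n_k`` (counts rescaled from cells/μl to thousands/μl).
    Original columns are unchanged.
    """
    df = cohort.df.copy()
    df["survivor"] = df["death_day"].isna()
    df["ivh"] = df["mgs"] > 0
    df["cmo"] = df["cmo_day"].notna()
    df["rogue_n_k"] = df["rogue_n_count"] / 1000.0
    df["net_n_k"] = df["net_n_count"] / 1000.0
    return CohortTable(df)


def nlr(neutrophils_k: float, lymphocytes_k: float) -> float:
    """Neutrophil-to-lymphocyte ratio from same-day CBC differential counts.

    Both arguments are absolute counts in K/μl; the ratio is dimensionless.
    """
    if lymphocytes_k <= 0:
        raise DomainError("lymphocyte count must be > 0 to form the NLR")
    return neutrophils_k / lymphocytes_k


def cells_per_ul_to_k(count: float | np.ndarray) -> float | np.ndarray:
    """Exact conversion cells/μl → K/μl (factor 1000)."""
    return np.asarray(count, dtype=float) / 1000.0


def k_to_cells_per_ul(count_k: float | np.ndarray) -> float | np.ndarray:
    """Exact conversion K/μl → cells/μl (factor 1000)."""
    return np.asarray(count_k, dtype=float) * 1000.0
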