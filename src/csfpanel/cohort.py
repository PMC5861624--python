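"""Patient-level cohort data model, I/O and preprocessing.

A cohort is held as a :class:`pandas.DataFrame` with one row per subject:
identifier, diagnostic group, cohort label, confirmation flag, demographics
and one column per measured CSF biomarker.  Ratio biomarkers
(T-tau/Aβ1–42 and AβX-42/X-40) are derived columns, computed from their
constituents and never read from disk.

Preprocessing mirrors routine practice for immunoassay panels: values
outside an assay's reliable range are clamped to the range limits,
concentrations are analysed on the natural-log scale, and group summaries
are reported as median (Q1–Q3) with per-biomarker available n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS: tuple[str, ...] = ("AD", "DLB", "bvFTD", "PNFA", "SD", "HC")
DEMENTIA_GROUPS: tuple[str, ...] = ("AD", "DLB", "bvFTD", "PNFA", "SD")
OTHER_DEMENTIA_GROUPS: tuple[str, ...] = ("DLB", "bvFTD", "PNFA", "SD")

MEASURED_BIOMARKERS: tuple[str, ...] = (
    "abeta_1_42", "t_tau", "p_tau_181", "nfl", "ykl_40",
    "abx_38", "abx_40", "abx_42", "sappa", "sappb",
)

#: ratio name -> (numerator, denominator); derived, never read from file
RATIO_DEFINITIONS: dict[str, tuple[str, str]] = {
    "t_tau_abeta_1_42": ("t_tau", "abeta_1_42"),
    "abx42_abx40": ("abx_42", "abx_40"),
}

ALL_BIOMARKERS: tuple[str, ...] = MEASURED_BIOMARKERS + tuple(RATIO_DEFINITIONS)

META_COLUMNS: tuple[str, ...] = (
    "subject_id", "group", "cohort", "confirmed",
    "age_at_lp", "sex", "onset_to_lp_months", "mmse",
)

FILE_COLUMNS: tuple[str, ...] = META_COLUMNS + MEASURED_BIOMARKERS


class CohortValidationError(ValueError):
    """A cohort table violates the data model; message names row/column."""


@dataclass(frozen=True)
class BiomarkerDefinition:
    """Identity, units and AD-side orientation of one panel analyte.

    ``ad_direction`` states on which side of a threshold AD cases lie
    (``"lower"`` for the amyloid measures, ``"higher"`` for the tau
    measures); it is configuration, not data.
    """

    name: str
    units: str
    ad_direction: str  # "higher" | "lower"
    kind: str = "measured"  # "measured" | "ratio"
    numerator: str | None = None
    denominator: str | None = None

    def __post_init__(self) -> None:
        if self.ad_direction not in ("higher", "lower"):
            raise ValueError(f"invalid ad_direction {self.ad_direction!r}")
        if self.kind == "ratio" and (self.numerator is None or self.denominator is None):
            raise ValueError("ratio biomarker needs numerator and denominator")


@dataclass(frozen=True)
class AssayRange:
    """Reliable detectable range of one assay; values outside are clamped."""

    biomarker: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError(
                f"invalid assay range for {self.biomarker}: ({self.lower}, {self.upper})"
            )


def empty_cohort() -> pd.DataFrame:
    """Return an empty cohort table with the canonical columns."""
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in FILE_COLUMNS})
    for c in ("subject_id", "group", "cohort", "sex"):
        df[c] = df[c].astype(object)
    df["confirmed"] = df["confirmed"].astype(int)
    return df


def validate_cohort(table: pd.DataFrame) -> None:
    """Check the cohort data model; raise CohortValidationError on violation."""
    missing_cols = [c for c in FILE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise CohortValidationError(f"missing columns: {missing_cols}")
    bad_group = ~table["group"].isin(GROUPS)
    if bad_group.any():
        row = int(np.flatnonzero(bad_group.to_numpy())[0])
        raise CohortValidationError(
            f"row {row}: unknown group label {table['group'].iloc[row]!r} "
            f"in column 'group' (expected one of {GROUPS})"
        )
    dup = table["subject_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise CohortValidationError(
            f"row {row}: duplicate subject_id {table['subject_id'].iloc[row]!r}"
        )
    for col in MEASURED_BIOMARKERS:
        vals = pd.to_numeric(table[col], errors="coerce")
        nonpos = vals.notna() & (vals <= 0)
        if nonpos.any():
            row = int(np.flatnonzero(nonpos.to_numpy())[0])
            raise CohortValidationError(
                f"row {row}: non-positive concentration {vals.iloc[row]} "
                f"in column {col!r}"
            )


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (empty cells = missing) and validate it."""
    table = pd.read_csv(
        path,
        dtype={
            "subject_id": str, "group": str, "cohort": str, "sex": str,
            "confirmed": "Int64",
        },
    )
    validate_cohort(table)
    table["confirmed"] = table["confirmed"].fillna(0).astype(int)
    for col in MEASURED_BIOMARKERS + ("age_at_lp", "onset_to_lp_months", "mmse"):
        table[col] = pd.to_numeric(table[col])
    return table


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV; missing values become empty cells."""
    table.loc[:, list(FILE_COLUMNS)].to_csv(path, index=False)


def compute_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Add the derived ratio columns.

    A ratio is present exactly when both constituents are present
    (positivity of concentrations guarantees a non-zero denominator).
    """
    out = table.copy()
    for name, (num, den) in RATIO_DEFINITIONS.items():
        out[name] = out[num] / out[den]
    return out


def clamp_to_range(
    table: pd.DataFrame,
    ranges: Iterable[AssayRange],
    return_counts: bool = False,
):
    """Clamp values outside each assay's reliable range to its limits.

    Missing values stay missing.  Idempotent.  Per-biomarker clamp counts
    are logged (and returned when ``return_counts`` is set).
    """
    out = table.copy()
    counts: dict[str, int] = {}
    for r in ranges:
        if r.biomarker not in out.columns:
            continue
        v = out[r.biomarker]
        n_clamped = int(((v < r.lower) | (v > r.upper)).sum())
        counts[r.biomarker] = n_clamped
        if n_clamped:
            logger.info("clamped %d values of %s to [%g, %g]",
                        n_clamped, r.biomarker, r.lower, r.upper)
        out[r.biomarker] = v.clip(lower=r.lower, upper=r.upper)
    if return_counts:
        return out, counts
    return out


def log_transform(table: pd.DataFrame, biomarkers: Iterable[str]) -> pd.DataFrame:
    """Natural-log transform the named biomarker columns (missing preserved)."""
    out = table.copy()
    for b in biomarkers:
        vals = out[b]
        if (vals.dropna() <= 0).any():
            raise ValueError(f"non-positive value in {b!r}; cannot log-transform")
        out[b] = np.log(vals)
    return out


def summarize_by_group(
    table: pd.DataFrame, biomarkers: Iterable[str] | None = None
) -> pd.DataFrame:
    """Median (Q1–Q3) and available n per group × biomarker.

    Quantiles use linear interpolation between order statistics (the
    conventional "type 7" rule).  Groups with no non-missing values get
    NaN summaries with ``n_available`` 0, never zeros.
    """
    if biomarkers is None:
        biomarkers = [b for b in ALL_BIOMARKERS if b in table.columns]
    rows = []
    for group, sub in table.groupby("group", sort=False):
        n_group = len(sub)
        for b in biomarkers:
            vals = sub[b].dropna().to_numpy(dtype=float)
            if vals.size:
                q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            else:
                q1 = med = q3 = np.nan
            rows.append({
                "group": group, "biomarker": b, "median": med,
                "q1": q1, "q3": q3, "n_available": vals.size, "n_group": n_group,
            })
    return pd.DataFrame(rows)


def summarize_demographics(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group age / sex / disease-duration summary (Table-1 shaped)."""
    rows = []
    for group, sub in table.groupby("group", sort=False):
        age = sub["age_at_lp"].dropna()
        onset = sub["onset_to_lp_months"].dropna()
        entry = {
            "group": group,
            "n": len(sub),
            "age_median": age.median(),
            "age_q1": age.quantile(0.25),
            "age_q3": age.quantile(0.75),
            "pct_male": 100.0 * (sub["sex"] == "male").mean() if len(sub) else np.nan,
            "onset_median": onset.median() if len(onset) else np.nan,
            "onset_q1": onset.quantile(0.25) if len(onset) else np.nan,
            "onset_q3": onset.quantile(0.75) if len(onset) else np.nan,
        }
        rows.append(entry)
    return pd.DataFrame(rows)


def default_biomarker_definitions(
    directions: Mapping[str, str] | None = None,
    units: Mapping[str, str] | None = None,
) -> dict[str, BiomarkerDefinition]:
    """Panel definitions with default AD-side orientations.

    Lower in AD: the amyloid measures and NFL (NFL is raised further in the
    FTD-spectrum comparators).  Higher in AD: the tau measures, the
    T-tau/Aβ1–42 ratio, YKL-40 and the soluble APP fragments.
    """
    default_dir = {
        "abeta_1_42": "lower", "abx_38": "lower", "abx_40": "lower",
        "abx_42": "lower", "abx42_abx40": "lower", "nfl": "lower",
        "t_tau": "higher", "p_tau_181": "higher", "t_tau_abeta_1_42": "higher",
        "ykl_40": "higher", "sappa": "higher", "sappb": "higher",
    }
    default_units = {
        "abeta_1_42": "pg/mL", "t_tau": "pg/mL", "p_tau_181": "pg/L",
        "nfl": "ng/L", "ykl_40": "ng/mL", "abx_38": "ng/L", "abx_40": "ng/L",
        "abx_42": "ng/L", "sappa": "ng/mL", "sappb": "ng/mL",
        "t_tau_abeta_1_42": "", "abx42_abx40": "",
    }
    if directions:
        default_dir.update(directions)
    if units:
        default_units.update(units)
    defs = {}
    for name in ALL_BIOMARKERS:
        if name in RATIO_DEFINITIONS:
            num, den = RATIO_DEFINITIONS[name]
            defs[name] = BiomarkerDefinition(
                name, default_units[name], default_dir[name],
                kind="ratio", numerator=num, denominator=den,
            )
        else:
            defs[name] = BiomarkerDefinition(name, default_units[name], default_dir[name])
    return defs


def infer_direction(table: pd.DataFrame, biomarker: str) -> str:
    """Infer AD orientation as the sign of AD median minus pooled non-AD median."""
    vals = table[biomarker]
    ad = vals[table["group"] == "AD"].dropna()
    rest = vals[table["group"] != "AD"].dropna()
    if ad.empty or rest.empty:
        raise ValueError(f"cannot infer direction for {biomarker!r}: empty side")
    return "higher" if ad.median() >= rest.median() else "lower"
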