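"""Patient-level cohort handling for nodal-staging survival analyses.

The cohort is a flat table of radically resected, initially non-metastatic
colorectal cancer patients: one row per subject with overall-survival
follow-up (months), a death indicator, lymph-node counts (examined and
positive), and the clinicopathological covariates used by the adjusted
survival models.  This module owns the CSV schema, the study's exclusion
filters, simple median/mode imputation, and UICC stage derivation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("lnstage")

# --------------------------------------------------------------------------
# Schema
# --------------------------------------------------------------------------

#: Exclusion criteria in the order they are tallied.  A record carrying
#: several flags is counted once, under the first true flag in this order.
EXCLUSION_ORDER = (
    "metastatic",
    "incomplete_histopath",
    "margin_positive",
    "death_within_30d",
    "emergency",
    "lost_followup",
    "polyposis_or_ibd",
)

FLAG_COLUMNS = tuple(f"flag_{name}" for name in EXCLUSION_ORDER)

SEX_LEVELS = ("male", "female")
T_LEVELS = ("T1", "T2", "T3", "T4")
GRADE_LEVELS = ("G1", "G2", "G3", "G4")  # 'unknown' is treated as missing
LOCATION_LEVELS = (
    "caecum",
    "ascending",
    "transverse",
    "descending",
    "sigmoid",
    "rectum",
    "synchronous",
)
YESNO_LEVELS = ("no", "yes")

#: Declared category order used to break mode ties during imputation.
CATEGORY_ORDERS = {
    "sex": SEX_LEVELS,
    "t_cat": T_LEVELS,
    "grade": GRADE_LEVELS,
    "location": LOCATION_LEVELS,
    "neoadjuvant": YESNO_LEVELS,
}

CONTINUOUS_IMPUTABLE = ("age", "size_mm")
CATEGORICAL_IMPUTABLE = ("sex", "t_cat", "grade", "location", "neoadjuvant")

REQUIRED_COLUMNS = (
    "id",
    "time_months",
    "event",
    "age",
    "sex",
    "neln",
    "pln",
    "t_cat",
    "grade",
    "size_mm",
    "location",
    "neoadjuvant",
)

OPTIONAL_COLUMNS = ("n1c",) + FLAG_COLUMNS


class CohortError(ValueError):
    """Raised for schema, parse or invariant violations in a cohort table."""


@dataclass
class Cohort:
    """An ordered collection of patient records with provenance.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per patient, columns per the documented CSV schema (plus any
        derived columns such as ``lnr`` or ``stage``).
    provenance : str
        Source path, or a description of the generator and seed.
    """

    df: pd.DataFrame
    provenance: str = "unknown"

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), self.provenance)


# --------------------------------------------------------------------------
# Reading / validation
# --------------------------------------------------------------------------

def _parse_bool(raw: str) -> bool:
    return str(raw).strip().lower() in ("1", "true", "yes")


def validate_cohort(df: pd.DataFrame) -> None:
    """Check cohort-level invariants, raising :class:`CohortError` on failure.

    Invariants: non-empty, unique ids, time > 0, event in {0, 1},
    neln >= 1 and 0 <= pln <= neln for every record.
    """
    if len(df) == 0:
        raise CohortError("empty cohort")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].unique()[:5]
        raise CohortError(f"duplicate patient ids: {list(dupes)}")
    if (df["time_months"] <= 0).any():
        bad = df.loc[df["time_months"] <= 0, "id"].iloc[0]
        raise CohortError(f"non-positive follow-up time for id {bad!r}")
    if not df["event"].isin([0, 1]).all():
        bad = df.loc[~df["event"].isin([0, 1]), "id"].iloc[0]
        raise CohortError(f"event indicator outside {{0,1}} for id {bad!r}")
    if (df["neln"] < 1).any():
        bad = df.loc[df["neln"] < 1, "id"].iloc[0]
        raise CohortError(f"examined node count < 1 for id {bad!r}")
    over = df["pln"] > df["neln"]
    if over.any():
        bad = df.loc[over, "id"].iloc[0]
        raise CohortError(f"positive nodes exceed examined nodes for id {bad!r}")


def read_cohort(path, strict: bool = True) -> Cohort:
    """Read a cohort CSV.

    Missing cells are empty strings in the file and become NA in memory,
    never silently defaulted.  In strict mode (default) any malformed row
    aborts with a row-indexed error; in lenient mode malformed rows are
    logged, skipped, and summarised.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortError(f"missing required columns: {missing_cols}")

    rows = []
    errors: list[str] = []
    for idx, rec in raw.iterrows():
        try:
            rows.append(_parse_row(rec))
        except (ValueError, KeyError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        msg = "; ".join(errors[:10])
        if strict:
            raise CohortError(f"{len(errors)} malformed row(s): {msg}")
        logger.warning("skipped %d malformed row(s): %s", len(errors), msg)
    if not rows:
        raise CohortError("empty cohort")

    df = pd.DataFrame(rows)
    validate_cohort(df)
    return Cohort(df, provenance=str(path))


def _parse_row(rec: pd.Series) -> dict:
    def req_float(col):
        v = rec[col].strip()
        if v == "":
            raise ValueError(f"missing required value in column {col!r}")
        return float(v)

    def opt_float(col):
        v = rec[col].strip()
        return np.nan if v == "" else float(v)

    def opt_cat(col, levels):
        v = rec[col].strip()
        if v == "" or v.lower() == "unknown":
            return None
        if v not in levels:
            raise ValueError(f"unrecognised {col} value {v!r}")
        return v

    row = {
        "id": rec["id"].strip(),
        "time_months": req_float("time_months"),
        "event": int(req_float("event")),
        "age": opt_float("age"),
        "sex": opt_cat("sex", SEX_LEVELS),
        "neln": int(req_float("neln")),
        "pln": int(req_float("pln")),
        "t_cat": opt_cat("t_cat", T_LEVELS),
        "grade": opt_cat("grade", GRADE_LEVELS),
        "size_mm": opt_float("size_mm"),
        "location": opt_cat("location", LOCATION_LEVELS),
        "neoadjuvant": opt_cat("neoadjuvant", YESNO_LEVELS),
    }
    if row["id"] == "":
        raise ValueError("empty id")
    row["n1c"] = _parse_bool(rec["n1c"]) if "n1c" in rec.index else False
    for col in FLAG_COLUMNS:
        row[col] = _parse_bool(rec[col]) if col in rec.index else False
    return row


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as UTF-8 CSV with missing cells as empty strings."""
    out = cohort.df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False, na_rep="")


# --------------------------------------------------------------------------
# Exclusion filtering
# --------------------------------------------------------------------------

def filter_cohort(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Apply the study exclusion criteria.

    Returns the retained cohort (all exclusion flags false) and a tally of
    excluded records per criterion.  A record with several flags set is
    counted once, under the earliest criterion in :data:`EXCLUSION_ORDER`,
    so the tally entries and the retained count always sum to the input size.
    """
    df = cohort.df
    tally = {name: 0 for name in EXCLUSION_ORDER}
    excluded = np.zeros(len(df), dtype=bool)
    for name in EXCLUSION_ORDER:
        col = f"flag_{name}"
        if col not in df.columns:
            continue
        hit = df[col].astype(bool).to_numpy() & ~excluded
        tally[name] = int(hit.sum())
        excluded |= hit
    kept = Cohort(df.loc[~excluded].reset_index(drop=True), cohort.provenance)
    if len(kept) == 0:
        raise CohortError("empty cohort after exclusion filtering")
    logger.info(
        "exclusion filter: %d -> %d retained (%s)", len(df), len(kept), tally
    )
    return kept, tally


# --------------------------------------------------------------------------
# Imputation
# --------------------------------------------------------------------------

def impute_missing(cohort: Cohort) -> Cohort:
    """Single imputation: column median (continuous) or mode (categorical).

    The median of an even number of observed values is the mean of the two
    central order statistics.  Mode ties are broken by the declared category
    order in :data:`CATEGORY_ORDERS`.  A column with no observed value at
    all raises :class:`CohortError`.
    """
    df = cohort.df.copy()
    for col in CONTINUOUS_IMPUTABLE:
        if col not in df.columns:
            continue
        observed = df[col].dropna()
        if df[col].isna().any():
            if observed.empty:
                raise CohortError(f"column {col!r} entirely missing")
            df[col] = df[col].fillna(float(observed.median()))
    for col in CATEGORICAL_IMPUTABLE:
        if col not in df.columns:
            continue
        missing = df[col].isna()
        if not missing.any():
            continue
        observed = df.loc[~missing, col]
        if observed.empty:
            raise CohortError(f"column {col!r} entirely missing")
        counts = observed.value_counts()
        top = counts.max()
        # deterministic tie-break: first modal level in the declared order
        order = CATEGORY_ORDERS.get(col, tuple(sorted(counts.index)))
        mode = next(lv for lv in order if counts.get(lv, 0) == top)
        df.loc[missing, col] = mode
    return Cohort(df, cohort.provenance)


# --------------------------------------------------------------------------
# UICC stage
# --------------------------------------------------------------------------

def derive_stage(t_cat: str, pln: int, n1c: bool = False) -> str:
    """UICC stage of one non-metastatic record.

    Any nodal involvement (pln >= 1, or tumor deposits without positive
    nodes, the N1c situation) is stage III; otherwise T1/T2 is stage I and
    T3/T4 stage II.
    """
    if pln >= 1 or n1c:
        return "III"
    if t_cat in ("T1", "T2"):
        return "I"
    if t_cat in ("T3", "T4"):
        return "II"
    raise CohortError(f"cannot stage record with t_cat={t_cat!r}")


def add_stage(cohort: Cohort) -> Cohort:
    """Append a ``stage`` column ('I' | 'II' | 'III') to the cohort."""
    df = cohort.df.copy()
    n1c = df["n1c"] if "n1c" in df.columns else pd.Series(False, index=df.index)
    df["stage"] = [
        derive_stage(t, int(p), bool(f))
        for t, p, f in zip(df["t_cat"], df["pln"], n1c)
    ]
    return Cohort(df, cohort.provenance)
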