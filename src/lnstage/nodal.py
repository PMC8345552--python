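"""Per-patient nodal staging quantities: N category, LNR and LODDS.

Three summaries of the lymphadenectomy specimen are compared throughout the
package:

* the AJCC/UICC 8th-edition N category — a function of the count of
  positive nodes only (N0: 0, N1: 1–3, N2: >=4, with subcategories
  N1a/N1b/N1c/N2a/N2b);
* the lymph node ratio, ``LNR = pln / neln``;
* the log odds of positive nodes,
  ``LODDS = ln((pln + 0.5) / (neln - pln + 0.5))``, an empirical-logistic
  transform that stays finite when no or all examined nodes are positive
  and keeps discriminating among such patients through ``neln``.

Natural logarithm throughout; classification schemes that assume another
base record it in their metadata.
"""
from __future__ import annotations

import numpy as np

from .cohort import Cohort, CohortError

__all__ = [
    "compute_lnr",
    "compute_lodds",
    "compute_n_category",
    "add_nodal_metrics",
]


def _check_counts(pln, neln) -> tuple[np.ndarray, np.ndarray]:
    pln = np.asarray(pln)
    neln = np.asarray(neln)
    if np.any(neln < 1):
        raise ValueError("neln must be >= 1")
    if np.any(pln < 0) or np.any(pln > neln):
        raise ValueError("pln must satisfy 0 <= pln <= neln")
    return pln, neln


def compute_lnr(pln, neln):
    """Lymph node ratio pln/neln in [0, 1].  Accepts scalars or arrays."""
    pln, neln = _check_counts(pln, neln)
    out = pln / neln
    return float(out) if out.ndim == 0 else out


def compute_lodds(pln, neln):
    """Log odds of positive nodes, ln((pln+0.5)/(neln-pln+0.5)).

    Finite for every valid pair, including pln = 0 and pln = neln, and
    antisymmetric: lodds(p, n) = -lodds(n - p, n).
    """
    pln, neln = _check_counts(pln, neln)
    out = np.log((pln + 0.5) / (neln - pln + 0.5))
    return float(out) if out.ndim == 0 else out


def compute_n_category(pln: int, n1c: bool = False) -> tuple[str, str]:
    """AJCC 8th-edition N category and subcategory for one patient.

    Returns ``(category, subcategory)`` with category in {N0, N1, N2}.
    A patient with tumor deposits but no positive nodes (``n1c``) is
    N1/N1c; otherwise 1 positive node is N1a, 2–3 N1b, 4–6 N2a and 7 or
    more N2b.
    """
    if pln < 0:
        raise ValueError("pln must be >= 0")
    if n1c:
        if pln > 0:
            raise ValueError("N1c requires pln == 0")
        return "N1", "N1c"
    if pln == 0:
        return "N0", "none"
    if pln == 1:
        return "N1", "N1a"
    if pln <= 3:
        return "N1", "N1b"
    if pln <= 6:
        return "N2", "N2a"
    return "N2", "N2b"


def add_nodal_metrics(cohort: Cohort) -> Cohort:
    """Append ``lnr``, ``lodds``, ``n_cat`` and ``n_subcat`` columns.

    The N1c patient keeps pln = 0 in the ratio metrics (its LNR/LODDS are
    computed from zero positive nodes) but is categorised N1, so stage-III
    subsets retain it.
    """
    df = cohort.df.copy()
    if "pln" not in df.columns or "neln" not in df.columns:
        raise CohortError("cohort lacks node count columns")
    pln = df["pln"].to_numpy(dtype=int)
    neln = df["neln"].to_numpy(dtype=int)
    df["lnr"] = compute_lnr(pln, neln)
    df["lodds"] = compute_lodds(pln, neln)
    n1c = (
        df["n1c"].astype(bool).to_numpy()
        if "n1c" in df.columns
        else np.zeros(len(df), dtype=bool)
    )
    cats = [compute_n_category(int(p), bool(f)) for p, f in zip(pln, n1c)]
    df["n_cat"] = [c[0] for c in cats]
    df["n_subcat"] = [c[1] for c in cats]
    return Cohort(df, cohort.provenance)
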