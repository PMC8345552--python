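"""End-to-end orchestration of the classification-system comparison.

One run: load or simulate a cohort -> exclusion filter -> median/mode
imputation -> nodal metrics -> classify every patient under every scheme
-> per analysis cohort (full cohort and each requested subgroup) fit the
adjusted base Cox model with N-category indicators and with each scheme's
class indicators -> Harrell's C on each model's linear predictor ->
jackknife Delta-C of each scheme against the N-category model ->
Benjamini-Hochberg FDR within the subgroup's scheme family -> tabular
reports (base-model table, comparison table, KM and landmark-ROC exports)
plus a JSON run manifest.

Class indicators always contrast against the lowest occupied class.  A
class left empty by a small subgroup is merged into the adjacent lower
class (the first class, if empty, merges into the class above it); every
merge is recorded on the report row.  The cohort-quantile LODDS scheme is
fitted once on the full analysis cohort, not per subgroup.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, filter_cohort, impute_missing, add_stage, write_cohort
from .discrimination import (
    fdr_adjust,
    harrell_c_ci,
    jackknife_delta_c,
    landmark_auc,
)
from .nodal import add_nodal_metrics
from .schemes import (
    ClassificationScheme,
    DEFAULT_QUANTILE_SPEC,
    builtin_schemes,
    classify_values,
    fit_quantile_scheme,
)
from .survival import CoxFit, cox_fit, encode_base_covariates, logrank_test

logger = logging.getLogger("lnstage")

SUBGROUP_SELECTORS = ("uicc", "neoadjuvant", "location", "neln12")
DEFAULT_HORIZONS = (12.0, 36.0, 60.0)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    schemes: tuple[ClassificationScheme, ...] = ()
    use_quantile_scheme: bool = True
    subgroups: tuple[str, ...] = SUBGROUP_SELECTORS
    horizons: tuple[float, ...] = DEFAULT_HORIZONS
    out_dir: str | None = None
    ties: str = "efron"

    def __post_init__(self):
        if not self.schemes:
            self.schemes = builtin_schemes()
        unknown = [s for s in self.subgroups if s not in SUBGROUP_SELECTORS]
        if unknown:
            raise ValueError(f"unknown subgroup selector(s): {unknown}")
        if any(h <= 0 for h in self.horizons):
            raise ValueError("horizons must be positive")


@dataclass
class SchemeEvaluation:
    """One report row: a scheme evaluated within one analysis cohort."""

    scheme: str
    subgroup: str
    n: int
    n_events: int
    class_hr: dict = field(default_factory=dict)  # label -> (hr, lo, hi)
    c_index: float = np.nan
    c_low: float = np.nan
    c_high: float = np.nan
    delta_c: float | None = None
    p_raw: float | None = None
    p_fdr: float | None = None
    reference: bool = False
    merges: list[str] = field(default_factory=list)
    converged: bool = True


# --------------------------------------------------------------------------
# subgroups
# --------------------------------------------------------------------------

def subgroup_split(cohort: Cohort, selector: str) -> dict[str, Cohort]:
    """Partition a staged cohort by one of the four named splits."""
    df = cohort.df
    if selector == "uicc":
        mask = df["stage"].isin(["I", "II"])
        parts = {"UICC I/II": mask, "UICC III": ~mask}
    elif selector == "neoadjuvant":
        mask = df["neoadjuvant"] == "yes"
        parts = {"neoadjuvant yes": mask, "neoadjuvant no": ~mask}
    elif selector == "location":
        mask = df["location"] == "rectum"
        parts = {"rectum": mask, "colon": ~mask}
    elif selector == "neln12":
        mask = df["neln"] >= 12
        parts = {"NELN >=12": mask, "NELN <12": ~mask}
    else:
        raise ValueError(f"unknown subgroup selector {selector!r}")
    out = {}
    for name, m in parts.items():
        sub = Cohort(df.loc[m].reset_index(drop=True), cohort.provenance)
        logger.info("subgroup %s: n=%d", name, len(sub))
        out[name] = sub
    return out


# --------------------------------------------------------------------------
# class indicators
# --------------------------------------------------------------------------

def _class_indicators(
    indices: np.ndarray, labels: list[str], prefix: str
) -> tuple[pd.DataFrame, list[str], str]:
    """Reference-contrast indicator columns for ordered class indices.

    Empty classes are merged into the adjacent lower class (the lowest
    class, if empty, merges upward); the lowest occupied class is the
    reference.  Returns (indicator frame, merge notes, reference label).
    """
    k = len(labels)
    counts = np.bincount(indices, minlength=k + 1)[1:]
    occupied = [c for c in range(1, k + 1) if counts[c - 1] > 0]
    if not occupied:
        raise ValueError("no occupied classes")
    merges: list[str] = []
    for c in range(1, k + 1):
        if counts[c - 1] == 0:
            below = [o for o in occupied if o < c]
            target = max(below) if below else min(occupied)
            merges.append(
                f"class {labels[c - 1]!r} empty, merged into {labels[target - 1]!r}"
            )
    ref = occupied[0]
    cols = {
        f"{prefix}_{c}": (indices == c).astype(int) for c in occupied[1:]
    }
    X = pd.DataFrame(cols, index=pd.RangeIndex(len(indices)))
    return X, merges, labels[ref - 1]


N_CAT_LABELS = ["N0", "N1", "N2"]


def _n_category_indices(df: pd.DataFrame) -> np.ndarray:
    return df["n_cat"].map({"N0": 1, "N1": 2, "N2": 3}).to_numpy(dtype=int)


# --------------------------------------------------------------------------
# model evaluation within one analysis cohort
# --------------------------------------------------------------------------

def _fit_with_indices(
    cohort: Cohort,
    indices: np.ndarray,
    labels: list[str],
    prefix: str,
    ties: str,
) -> tuple[CoxFit, np.ndarray, list[str], pd.DataFrame]:
    base_X, _ = encode_base_covariates(cohort)
    base_X = base_X.reset_index(drop=True)
    ind_X, merges, _ref = _class_indicators(indices, labels, prefix)
    X = pd.concat([base_X, ind_X], axis=1)
    fit = cox_fit(X, cohort.df["time_months"], cohort.df["event"], ties=ties)
    lp = fit.linear_predictor(X)
    return fit, lp, merges, X


def evaluate_subgroup(
    cohort: Cohort,
    schemes: tuple[ClassificationScheme, ...],
    subgroup: str,
    ties: str = "efron",
) -> list[SchemeEvaluation]:
    """Compare every scheme against the N-category model on one cohort.

    The N-category row comes first, flagged as the reference with
    ``delta_c = 0`` and no p-value; scheme rows carry the jackknife
    Delta-C versus that model and BH-FDR-adjusted p-values with family
    size equal to the number of schemes in this subgroup.
    """
    df = cohort.df
    times = df["time_months"].to_numpy(float)
    events = df["event"].to_numpy(int)
    n, n_events = len(df), int(events.sum())

    n_fit, n_lp, n_merges, _ = _fit_with_indices(
        cohort, _n_category_indices(df), N_CAT_LABELS, "n_cat", ties
    )
    n_c = harrell_c_ci(n_lp, times, events)
    rows = [
        SchemeEvaluation(
            scheme="N category (AJCC 8th)",
            subgroup=subgroup,
            n=n,
            n_events=n_events,
            class_hr=_hr_table(n_fit, "n_cat", N_CAT_LABELS),
            c_index=n_c.c_index,
            c_low=n_c.ci_low,
            c_high=n_c.ci_high,
            delta_c=0.0,
            reference=True,
            merges=n_merges,
            converged=n_fit.converged,
        )
    ]

    raw_ps = []
    for scheme in schemes:
        var = scheme.variable.lower()
        indices = classify_values(df[var].to_numpy(float), scheme)
        labels = [c.label for c in scheme.classes]
        fit, lp, merges, _ = _fit_with_indices(cohort, indices, labels, "cls", ties)
        c_res = harrell_c_ci(lp, times, events)
        dres = jackknife_delta_c(lp, n_lp, times, events)
        rows.append(
            SchemeEvaluation(
                scheme=scheme.name,
                subgroup=subgroup,
                n=n,
                n_events=n_events,
                class_hr=_hr_table(fit, "cls", labels),
                c_index=c_res.c_index,
                c_low=c_res.ci_low,
                c_high=c_res.ci_high,
                delta_c=dres.delta_c,
                p_raw=dres.p_value,
                merges=merges + list(scheme.metadata.get("repair", "").splitlines()),
                converged=fit.converged,
            )
        )
        raw_ps.append(1.0 if dres.p_value is None else dres.p_value)

    if raw_ps:
        adj = fdr_adjust(raw_ps, m=len(raw_ps))
        for row, p_adj in zip(rows[1:], adj):
            row.p_fdr = float(p_adj)
    return rows


def _hr_table(fit: CoxFit, prefix: str, labels: list[str]) -> dict:
    out = {}
    for term, hr, lo, hi in zip(fit.terms, fit.hr, fit.ci_low, fit.ci_high):
        if term.startswith(prefix + "_"):
            idx = int(term.rsplit("_", 1)[1])
            out[labels[idx - 1]] = (float(hr), float(lo), float(hi))
    return out


# --------------------------------------------------------------------------
# KM / risk groups / ROC exports
# --------------------------------------------------------------------------

def risk_group(t_cat: str, n_cat: str) -> str:
    """Adjuvant-therapy risk rule: high risk is T4, N2 or both; low risk
    is T1, T2, or T3 with N1."""
    if t_cat == "T4" or n_cat == "N2":
        return "high"
    return "low"


def export_km(cohort: Cohort, grouping) -> tuple[pd.DataFrame, object]:
    """Plot-ready KM step coordinates per group, with a log-rank test.

    ``grouping`` is a :class:`ClassificationScheme`, the string ``"risk"``
    (low/high adjuvant-risk rule), or the name of a categorical column.
    Groups with zero subjects are omitted with a notice; with fewer than
    two non-empty groups the log-rank test is omitted (None).
    """
    from .survival import km_estimate  # local import to avoid cycle noise

    df = cohort.df
    if isinstance(grouping, ClassificationScheme):
        idx = classify_values(df[grouping.variable.lower()].to_numpy(float), grouping)
        labels = np.array([grouping.classes[i - 1].label for i in idx], dtype=object)
    elif grouping == "risk":
        labels = np.array(
            [risk_group(t, n) for t, n in zip(df["t_cat"], df["n_cat"])], dtype=object
        )
    else:
        labels = df[grouping].astype(str).to_numpy()

    frames = []
    for g in pd.unique(labels):
        mask = labels == g
        if not mask.any():
            logger.info("export_km: group %r empty, omitted", g)
            continue
        curve = km_estimate(df.loc[mask, "time_months"], df.loc[mask, "event"])
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": np.concatenate([[0.0], curve.times]),
                    "survival": np.concatenate([[1.0], curve.survival]),
                    "at_risk": np.concatenate([[int(mask.sum())], curve.at_risk]),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    lr = None
    if len(pd.unique(labels)) >= 2:
        lr = logrank_test(df["time_months"], df["event"], labels)
    return table, lr


def roc_auc_table(cohort: Cohort, schemes, horizons=DEFAULT_HORIZONS) -> pd.DataFrame:
    """Landmark AUCs at the requested horizons.

    Scores both the continuous nodal metrics (LNR, LODDS, positive and
    examined node counts) and each scheme's ordinal class index.
    """
    df = cohort.df
    times = df["time_months"].to_numpy(float)
    events = df["event"].to_numpy(int)
    scores = {
        "LNR (continuous)": df["lnr"].to_numpy(float),
        "LODDS (continuous)": df["lodds"].to_numpy(float),
        "positive LN": df["pln"].to_numpy(float),
        "examined LN": -df["neln"].to_numpy(float),  # fewer nodes = worse
    }
    for scheme in schemes:
        scores[f"{scheme.name} (classes)"] = classify_values(
            df[scheme.variable.lower()].to_numpy(float), scheme
        ).astype(float)
    rows = []
    for name, sc in scores.items():
        for h in horizons:
            res = landmark_auc(sc, times, events, h)
            rows.append(
                {
                    "score": name,
                    "horizon_months": h,
                    "auc": res.auc,
                    "n_cases": res.n_cases,
                    "n_controls": res.n_controls,
                    "n_excluded": res.n_excluded,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def prepare_cohort(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Filter, impute, derive metrics and stage — the shared front end."""
    filtered, tally = filter_cohort(cohort)
    prepared = add_stage(add_nodal_metrics(impute_missing(filtered)))
    return prepared, tally


def run_full_analysis(cohort: Cohort, cfg: RunConfig | None = None):
    """Run the complete comparison; returns (report DataFrame, artifacts).

    The artifacts dict holds the exclusion tally, the base-model summaries
    per analysis cohort, the landmark-AUC table, and — when ``out_dir`` is
    set — everything is also written to disk (CSV/JSON) together with a
    run manifest.  Deterministic given the input cohort and config.
    """
    cfg = cfg or RunConfig()
    prepared, tally = prepare_cohort(cohort)

    schemes = list(cfg.schemes)
    if cfg.use_quantile_scheme:
        schemes.append(
            fit_quantile_scheme(prepared.df["lodds"].to_numpy(float), DEFAULT_QUANTILE_SPEC)
        )
    schemes = tuple(schemes)

    analysis_cohorts: dict[str, Cohort] = {"all": prepared}
    for selector in cfg.subgroups:
        analysis_cohorts.update(subgroup_split(prepared, selector))

    all_rows: list[SchemeEvaluation] = []
    base_fits: dict[str, pd.DataFrame] = {}
    skipped: list[str] = []
    for name, sub in analysis_cohorts.items():
        if int(sub.df["event"].sum()) == 0:
            logger.warning("subgroup %r has no events; skipped", name)
            skipped.append(name)
            continue
        from .survival import fit_base_model

        base_fits[name] = fit_base_model(sub, ties=cfg.ties).summary()
        all_rows.extend(evaluate_subgroup(sub, schemes, name, ties=cfg.ties))

    report = evaluations_to_frame(all_rows)
    auc = roc_auc_table(prepared, schemes, cfg.horizons)
    artifacts = {
        "exclusion_tally": tally,
        "base_models": base_fits,
        "auc_table": auc,
        "schemes": [s.name for s in schemes],
        "skipped_subgroups": skipped,
        "n_analysis": len(prepared),
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "comparison_report.csv", index=False)
        auc.to_csv(out / "landmark_auc.csv", index=False)
        for name, frame in base_fits.items():
            safe = name.replace(" ", "_").replace("/", "-").replace(">=", "ge").replace("<", "lt")
            frame.to_csv(out / f"base_model_{safe}.csv", index=False)
        write_cohort(prepared, out / "analysis_cohort.csv")
        manifest = {
            "provenance": cohort.provenance,
            "n_input": len(cohort),
            "n_analysis": len(prepared),
            "exclusion_tally": tally,
            "schemes": [s.name for s in schemes],
            "subgroups": list(analysis_cohorts),
            "skipped_subgroups": skipped,
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return report, artifacts


def evaluations_to_frame(rows: list[SchemeEvaluation]) -> pd.DataFrame:
    records = []
    for r in rows:
        records.append(
            {
                "subgroup": r.subgroup,
                "scheme": r.scheme,
                "reference": r.reference,
                "n": r.n,
                "n_events": r.n_events,
                "c_index": r.c_index,
                "c_low": r.c_low,
                "c_high": r.c_high,
                "delta_c": r.delta_c,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "class_hr": json.dumps(
                    {k: [round(v, 4) for v in vals] for k, vals in r.class_hr.items()}
                ),
                "notes": "; ".join(m for m in r.merges if m),
                "converged": r.converged,
            }
        )
    return pd.DataFrame(records)
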