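"""Interval-based lymph-node classification schemes.

A scheme is a named, ordered partition of the LNR axis ([0, 1]) or the
LODDS axis (all reals) into interval classes.  The registry ships the
seven published fixed-cut-off schemes that showed superior stage-III
discrimination in the study this package operationalises — two LNR
(Lee; Fortea-Sanchis) and five LODDS (Fortea-Sanchis; He; Calero;
Bagante; Jian-Hui) — plus a cohort-quantile LODDS scheme cut at the
25th/50th/75th percentiles.  Further published schemes load from
YAML/JSON config.

Two of the printed cut-off tables need repair to form a partition, and
both repairs are recorded in scheme metadata:

* "LNR Fortea-Sanchis" prints classes 0–0.24 / 0.25–0.60 / >0.60.  The
  (0.24, 0.25) gap is read as rounding of a 0.25 boundary: classes are
  [0, 0.25), [0.25, 0.60], (0.60, 1].
* "LODDS Bagante" prints class 3 as ">0.9; <=1.5" directly after class 2
  ">=-2; <=-0.9"; the lower bound is taken as a sign slip for >-0.9,
  otherwise (-0.9, 0.9] would be unassigned.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "IntervalClass",
    "ClassificationScheme",
    "QuantileSchemeSpec",
    "SchemeError",
    "builtin_schemes",
    "get_scheme",
    "classify",
    "classify_values",
    "fit_quantile_scheme",
    "load_schemes",
    "save_schemes",
    "DEFAULT_QUANTILE_SPEC",
]

NEG_INF = float("-inf")
POS_INF = float("inf")


class SchemeError(ValueError):
    """Invalid scheme definition or unclassifiable value."""


@dataclass(frozen=True)
class IntervalClass:
    """One interval class of a scheme, with explicit bound closures."""

    label: str
    lower: float
    lower_closed: bool
    upper: float
    upper_closed: bool

    def __post_init__(self):
        if self.lower > self.upper:
            raise SchemeError(f"class {self.label!r}: lower > upper")
        if self.lower == self.upper and not (self.lower_closed and self.upper_closed):
            raise SchemeError(f"class {self.label!r}: degenerate open interval")

    def contains(self, value: float) -> bool:
        lo_ok = value > self.lower or (self.lower_closed and value == self.lower)
        hi_ok = value < self.upper or (self.upper_closed and value == self.upper)
        return lo_ok and hi_ok


@dataclass(frozen=True)
class ClassificationScheme:
    """Named ordered partition of the LNR or LODDS axis."""

    name: str
    source: str
    variable: str  # "LNR" | "LODDS"
    classes: tuple[IntervalClass, ...]
    kind: str = "fixed"  # "fixed" | "quantile"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.variable not in ("LNR", "LODDS"):
            raise SchemeError(f"unknown variable {self.variable!r}")
        if not self.classes:
            raise SchemeError(f"scheme {self.name!r} has no classes")
        self.validate()

    @property
    def range(self) -> tuple[float, float]:
        return (0.0, 1.0) if self.variable == "LNR" else (NEG_INF, POS_INF)

    def validate(self) -> None:
        """Check ordering, adjacency (no gaps/overlaps) and range coverage."""
        lo, hi = self.range
        cls = self.classes
        first, last = cls[0], cls[-1]
        if first.lower > lo or (first.lower == lo and not first.lower_closed and lo != NEG_INF):
            raise SchemeError(
                f"scheme {self.name!r}: first class does not reach lower range bound"
            )
        if last.upper < hi or (last.upper == hi and not last.upper_closed and hi != POS_INF):
            raise SchemeError(
                f"scheme {self.name!r}: last class does not reach upper range bound"
            )
        for a, b in zip(cls, cls[1:]):
            if b.upper < a.upper or (b.lower, not b.lower_closed) < (a.lower, not a.lower_closed):
                raise SchemeError(
                    f"scheme {self.name!r}: classes {a.label!r}/{b.label!r} out of order"
                )
            if a.upper != b.lower:
                kind = "overlap" if a.upper > b.lower else "gap"
                raise SchemeError(
                    f"scheme {self.name!r}: {kind} between classes "
                    f"{a.label!r} and {b.label!r}"
                )
            if a.upper_closed == b.lower_closed:
                kind = "overlap" if a.upper_closed else "gap"
                raise SchemeError(
                    f"scheme {self.name!r}: boundary {kind} at {a.upper} between "
                    f"classes {a.label!r} and {b.label!r}"
                )


@dataclass(frozen=True)
class QuantileSchemeSpec:
    """Specification for a cohort-quantile LODDS scheme."""

    variable: str = "LODDS"
    probabilities: tuple[float, ...] = (0.25, 0.50, 0.75)

    def __post_init__(self):
        ps = self.probabilities
        if not all(0 < p < 1 for p in ps) or list(ps) != sorted(set(ps)):
            raise SchemeError("probabilities must be strictly increasing in (0,1)")


DEFAULT_QUANTILE_SPEC = QuantileSchemeSpec()


# --------------------------------------------------------------------------
# Built-in schemes
# --------------------------------------------------------------------------

def _cls(label, lower, lc, upper, uc):
    return IntervalClass(label, lower, lc, upper, uc)


def _make_builtins() -> tuple[ClassificationScheme, ...]:
    lee = ClassificationScheme(
        name="LNR Lee",
        source="Lee et al.",
        variable="LNR",
        classes=(
            _cls(">=0; <=0.1", 0.0, True, 0.1, True),
            _cls(">0.1; <=0.2", 0.1, False, 0.2, True),
            _cls(">0.2; <=0.3", 0.2, False, 0.3, True),
            _cls(">0.3", 0.3, False, 1.0, True),
        ),
    )
    fortea_lnr = ClassificationScheme(
        name="LNR Fortea-Sanchis",
        source="Fortea-Sanchis et al.",
        variable="LNR",
        classes=(
            _cls("0; <0.25", 0.0, True, 0.25, False),
            _cls(">=0.25; <=0.60", 0.25, True, 0.60, True),
            _cls(">0.60", 0.60, False, 1.0, True),
        ),
        metadata={
            "repair": "printed 0-0.24 / 0.25-0.60 gap read as a rounded 0.25 boundary"
        },
    )
    fortea_lodds = ClassificationScheme(
        name="LODDS Fortea-Sanchis",
        source="Fortea-Sanchis et al.",
        variable="LODDS",
        classes=(
            _cls("<-2", NEG_INF, False, -2.0, False),
            _cls(">=-2; <=-1", -2.0, True, -1.0, True),
            _cls(">-1", -1.0, False, POS_INF, False),
        ),
    )
    he = ClassificationScheme(
        name="LODDS He",
        source="He et al.",
        variable="LODDS",
        classes=(
            _cls("<-3", NEG_INF, False, -3.0, False),
            _cls(">=-3; <-2", -3.0, True, -2.0, False),
            _cls(">=-2; <-1", -2.0, True, -1.0, False),
            _cls(">=-1; <0", -1.0, True, 0.0, False),
            _cls(">=0", 0.0, True, POS_INF, False),
        ),
    )
    calero = ClassificationScheme(
        name="LODDS Calero",
        source="Calero et al.",
        variable="LODDS",
        classes=(
            _cls("<=-3", NEG_INF, False, -3.0, True),
            _cls(">-3; <=-1", -3.0, False, -1.0, True),
            _cls(">-1; <=3", -1.0, False, 3.0, True),
            _cls(">3", 3.0, False, POS_INF, False),
        ),
    )
    bagante = ClassificationScheme(
        name="LODDS Bagante",
        source="Bagante et al.",
        variable="LODDS",
        classes=(
            _cls("<-2", NEG_INF, False, -2.0, False),
            _cls(">=-2; <=-0.9", -2.0, True, -0.9, True),
            _cls(">-0.9; <=1.5", -0.9, False, 1.5, True),
            _cls(">1.5", 1.5, False, POS_INF, False),
        ),
        metadata={
            "repair": "printed class-3 lower bound '>0.9' read as sign slip for >-0.9"
        },
    )
    jian_hui = ClassificationScheme(
        name="LODDS Jian-Hui",
        source="Jian-Hui et al.",
        variable="LODDS",
        classes=(
            _cls("<=-1.5", NEG_INF, False, -1.5, True),
            _cls(">-1.5; <=-1", -1.5, False, -1.0, True),
            _cls(">-1; <=0", -1.0, False, 0.0, True),
            _cls(">0", 0.0, False, POS_INF, False),
        ),
    )
    return (lee, fortea_lnr, fortea_lodds, he, calero, bagante, jian_hui)


_BUILTINS = _make_builtins()


def builtin_schemes() -> tuple[ClassificationScheme, ...]:
    """The seven shipped fixed-cut-off schemes, in registry order.

    The cohort-quantile LODDS scheme is specified separately by
    :data:`DEFAULT_QUANTILE_SPEC` and materialised per cohort with
    :func:`fit_quantile_scheme`.
    """
    return _BUILTINS


def get_scheme(name: str) -> ClassificationScheme:
    """Look up a built-in scheme by (prefix of its) name."""
    for s in _BUILTINS:
        if s.name == name or s.name.startswith(name):
            return s
    raise SchemeError(f"unknown scheme {name!r}")


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify(value: float, scheme: ClassificationScheme) -> tuple[int, str]:
    """Assign ``value`` to its unique class; returns (1-based index, label)."""
    if not math.isfinite(value):
        raise SchemeError(f"non-finite value {value!r} for scheme {scheme.name!r}")
    for i, cls in enumerate(scheme.classes, start=1):
        if cls.contains(value):
            return i, cls.label
    raise SchemeError(f"value {value} outside all classes of scheme {scheme.name!r}")


def classify_values(values, scheme: ClassificationScheme) -> np.ndarray:
    """Vectorised :func:`classify`; returns 1-based class indices."""
    values = np.asarray(values, dtype=float)
    out = np.zeros(values.shape, dtype=int)
    for i, cls in enumerate(scheme.classes, start=1):
        lo_ok = (values > cls.lower) | (cls.lower_closed & (values == cls.lower))
        hi_ok = (values < cls.upper) | (cls.upper_closed & (values == cls.upper))
        out[lo_ok & hi_ok & (out == 0)] = i
    if np.any(out == 0):
        bad = values[out == 0][0]
        raise SchemeError(f"value {bad} outside all classes of scheme {scheme.name!r}")
    return out


def fit_quantile_scheme(
    values, spec: QuantileSchemeSpec = DEFAULT_QUANTILE_SPEC, name: str = "LODDS quantile"
) -> ClassificationScheme:
    """Cut the LODDS axis at empirical percentiles of the supplied cohort.

    Percentiles use linear interpolation between order statistics.  Classes
    are half-open ``[q_{k-1}, q_k)`` with the first open below and the last
    closed at +inf, so every real value classifies.
    """
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 4:
        raise SchemeError("need at least 4 distinct values to fit quantile scheme")
    cuts = np.quantile(values, list(spec.probabilities), method="linear")
    if len(np.unique(cuts)) != len(cuts):
        raise SchemeError("non-distinct quantiles")
    bounds = [NEG_INF, *cuts, POS_INF]
    classes = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        classes.append(
            IntervalClass(
                label=f"LODDS{k + 1}",
                lower=lo,
                lower_closed=k > 0,
                upper=hi,
                upper_closed=False,
            )
        )
    return ClassificationScheme(
        name=name,
        source="cohort quantiles",
        variable=spec.variable,
        classes=tuple(classes),
        kind="quantile",
        metadata={
            "probabilities": list(spec.probabilities),
            "percentile_definition": "linear interpolation between order statistics",
            "cuts": [float(c) for c in cuts],
        },
    )


# --------------------------------------------------------------------------
# Config round-trip
# --------------------------------------------------------------------------

def _bound_to_json(x: float):
    if x == NEG_INF:
        return "-inf"
    if x == POS_INF:
        return "+inf"
    return x


def _bound_from_json(x) -> float:
    if isinstance(x, str):
        s = x.strip().lower()
        if s in ("-inf", "-infinity"):
            return NEG_INF
        if s in ("+inf", "inf", "infinity"):
            return POS_INF
        return float(x)
    if x is None:
        raise SchemeError("interval bound may not be null; use '-inf'/'+inf'")
    return float(x)


def scheme_to_dict(scheme: ClassificationScheme) -> dict:
    return {
        "name": scheme.name,
        "source": scheme.source,
        "variable": scheme.variable,
        "kind": scheme.kind,
        "metadata": dict(scheme.metadata),
        "classes": [
            {
                "label": c.label,
                "lower": _bound_to_json(c.lower),
                "lower_closed": c.lower_closed,
                "upper": _bound_to_json(c.upper),
                "upper_closed": c.upper_closed,
            }
            for c in scheme.classes
        ],
    }


def _scheme_from_dict(d: dict) -> ClassificationScheme:
    classes = [
        IntervalClass(
            label=str(c["label"]),
            lower=_bound_from_json(c["lower"]),
            lower_closed=bool(c["lower_closed"]),
            upper=_bound_from_json(c["upper"]),
            upper_closed=bool(c["upper_closed"]),
        )
        for c in d["classes"]
    ]
    repair = d.get("repair")
    metadata = dict(d.get("metadata", {}))
    if repair == "extend_left":
        classes = _repair_extend_left(classes)
        metadata["repair"] = "extend_left applied to close printed gaps"
    elif repair is not None:
        raise SchemeError(f"unknown repair directive {repair!r}")
    return ClassificationScheme(
        name=str(d["name"]),
        source=str(d.get("source", "config")),
        variable=str(d["variable"]),
        classes=tuple(classes),
        kind=str(d.get("kind", "fixed")),
        metadata=metadata,
    )


def _repair_extend_left(classes: list[IntervalClass]) -> list[IntervalClass]:
    """Close gaps by extending each class's lower bound down to the previous
    class's upper bound (with complementary closure)."""
    repaired = [classes[0]]
    for cls in classes[1:]:
        prev = repaired[-1]
        gap = cls.lower > prev.upper or (
            cls.lower == prev.upper and not cls.lower_closed and not prev.upper_closed
        )
        if gap:
            cls = IntervalClass(
                cls.label, prev.upper, not prev.upper_closed, cls.upper, cls.upper_closed
            )
        repaired.append(cls)
    return repaired


def load_schemes(path) -> list[ClassificationScheme]:
    """Load user-defined schemes from a YAML or JSON config file.

    The file holds a list of scheme mappings (or ``{"schemes": [...]}``).
    Every scheme is validated against the same partition invariants as the
    built-ins; a printed gap can be closed with ``repair: extend_left``.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if isinstance(data, dict):
        data = data.get("schemes", [])
    if not isinstance(data, list) or not data:
        raise SchemeError(f"no schemes found in {path}")
    return [_scheme_from_dict(d) for d in data]


def save_schemes(schemes, path) -> None:
    """Serialise schemes to YAML (or JSON when the suffix is .json)."""
    payload = {"schemes": [scheme_to_dict(s) for s in schemes]}
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    else:
        p.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
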