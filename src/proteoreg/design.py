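"""Environmental factor space and the designed experiment.

The experiment varies five culture-medium factors for *Chlamydomonas
reinhardtii*: acetate concentration, light intensity, ammonium and nitrate
concentrations (continuous) and CO2 concentration (ordinal, two modalities:
ambient air 0.035% vs saturating 1.5%).  A 32-run design of experiments —
a two-level fractional factorial augmented with center points and axial-type
points — covers the factor space so that linear, quadratic and second-order
interaction effects are estimable.

This module represents factor specifications and design tables, codes the
design into model-term columns (linear / quadratic / interaction / ordinal),
checks factor collinearity, and detects replicate run groups that supply
pure-error degrees of freedom for lack-of-fit testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorSpec",
    "DesignTable",
    "CodedMatrix",
    "DesignValidationError",
    "builtin_factors",
    "builtin_design",
    "load_design",
    "candidate_terms",
    "parse_term",
    "code_settings",
    "code_design",
    "collinearity",
    "replicate_groups",
    "pure_error_df",
]


class DesignValidationError(ValueError):
    """A design file or table violates the factor specification."""


@dataclass(frozen=True)
class FactorSpec:
    """One environmental factor: continuous range or ordinal modalities."""

    name: str
    kind: str  # "continuous" | "ordinal"
    low: float | None = None
    high: float | None = None
    modalities: tuple[float, ...] | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.low is None or self.high is None or not self.low < self.high:
                raise DesignValidationError(
                    f"continuous factor {self.name!r} needs low < high"
                )
        elif self.kind == "ordinal":
            if self.modalities is None or len(set(self.modalities)) < 2:
                raise DesignValidationError(
                    f"ordinal factor {self.name!r} needs >=2 distinct modalities"
                )
            if list(self.modalities) != sorted(self.modalities):
                raise DesignValidationError(
                    f"ordinal factor {self.name!r}: modalities must be ascending"
                )
        else:
            raise DesignValidationError(f"unknown factor kind {self.kind!r}")

    def validate_value(self, value: float) -> None:
        if self.kind == "continuous":
            if not (self.low <= value <= self.high):
                raise DesignValidationError(
                    f"{self.name}={value} outside range [{self.low}, {self.high}]"
                )
        else:
            if value not in self.modalities:
                raise DesignValidationError(
                    f"{self.name}={value} not in modalities {self.modalities}"
                )


@dataclass
class DesignTable:
    """Runs x factors settings table with factor metadata."""

    run_ids: list[str]
    settings: pd.DataFrame  # index = run_ids, columns = factor names
    factors: list[FactorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.run_ids)) != len(self.run_ids):
            dupes = sorted({r for r in self.run_ids if self.run_ids.count(r) > 1})
            raise DesignValidationError(f"duplicate run ids: {dupes}")
        names = [f.name for f in self.factors]
        if list(self.settings.columns) != names:
            raise DesignValidationError(
                f"settings columns {list(self.settings.columns)} != factors {names}"
            )
        if self.settings.isna().any().any():
            bad = self.settings.isna().stack()
            cell = bad[bad].index[0]
            raise DesignValidationError(f"missing cell at run {cell[0]}, factor {cell[1]}")
        for spec in self.factors:
            for rid, value in self.settings[spec.name].items():
                spec.validate_value(float(value))

    @property
    def n_runs(self) -> int:
        return len(self.run_ids)

    def factor(self, name: str) -> FactorSpec:
        for spec in self.factors:
            if spec.name == name:
                return spec
        raise KeyError(name)

    @property
    def continuous_names(self) -> list[str]:
        return [f.name for f in self.factors if f.kind == "continuous"]

    @property
    def ordinal_names(self) -> list[str]:
        return [f.name for f in self.factors if f.kind == "ordinal"]


@dataclass
class CodedMatrix:
    """Model-term columns built from a coded design.

    ``term_meta`` maps each column name to ``(kind, factors)`` where kind is
    one of intercept / linear / quadratic / interaction_cc / ordinal_main /
    interaction_co.
    """

    columns: pd.DataFrame
    term_meta: dict[str, tuple[str, tuple[str, ...]]]

    @property
    def values(self) -> np.ndarray:
        return self.columns.to_numpy(dtype=float)


# --------------------------------------------------------------------------
# Built-in 32-run design
# --------------------------------------------------------------------------

#: factor columns: acetate (g/L), light (umol photons m-2 s-1),
#: nh4 (mM), no3 (mM), co2 (%, ordinal)
_BUILTIN_ROWS: list[tuple[str, float, float, float, float, float]] = [
    ("1", 0, 200, 0, 20, 1.5),
    ("2", 0, 200, 0, 10, 1.5),
    ("3", 0.5, 200, 0, 0, 1.5),
    ("4", 0.5, 100, 7.5, 10, 1.5),
    ("5", 1, 200, 0, 20, 0.035),
    ("6", 1, 0, 15, 0, 1.5),
    ("8", 1, 0, 0, 0, 0.035),
    ("9", 0, 0, 15, 20, 1.5),
    ("13", 0, 100, 0, 0, 1.5),
    ("15", 0, 0, 0, 0, 0.035),
    ("16", 1, 200, 15, 0, 1.5),
    ("19", 1, 0, 0, 20, 1.5),
    ("20", 1, 200, 15, 20, 0.035),
    ("21", 0.5, 100, 7.5, 10, 0.035),
    ("22", 1, 0, 15, 0, 0.035),
    ("23", 0, 200, 15, 20, 0.035),
    ("24", 1, 0, 0, 0, 1.5),
    ("25", 0, 200, 15, 0, 0.035),
    ("27", 1, 200, 15, 0, 0.035),
    ("29", 0, 0, 7.5, 0, 1.5),
    ("30", 0, 0, 15, 20, 0.035),
    ("31", 0, 0, 15, 0, 0.035),
    ("32", 0, 200, 0, 20, 0.035),
    ("33", 0.5, 200, 15, 10, 1.5),
    ("34", 1, 0, 15, 20, 0.035),
    ("35", 1, 200, 15, 20, 1.5),
    ("36", 0, 0, 0, 20, 0.035),
    ("37", 1, 200, 0, 0, 0.035),
    ("39", 0.5, 100, 7.5, 10, 0.035),
    ("40", 0, 200, 0, 0, 0.035),
    ("41", 0.5, 100, 7.5, 10, 1.5),
    ("42", 0.5, 100, 7.5, 10, 1.5),
]

FACTOR_NAMES = ("acetate", "light", "nh4", "no3", "co2")


def builtin_factors() -> list[FactorSpec]:
    """Factor specifications of the built-in experiment."""
    return [
        FactorSpec("acetate", "continuous", 0.0, 1.0, unit="g.L-1"),
        FactorSpec("light", "continuous", 0.0, 200.0, unit="umol_photons.m-2.s-1"),
        FactorSpec("nh4", "continuous", 0.0, 15.0, unit="mM"),
        FactorSpec("no3", "continuous", 0.0, 20.0, unit="mM"),
        FactorSpec("co2", "ordinal", modalities=(0.035, 1.5), unit="%"),
    ]


def builtin_design() -> DesignTable:
    """The packaged 32-run design of experiments."""
    run_ids = [r[0] for r in _BUILTIN_ROWS]
    settings = pd.DataFrame(
        [r[1:] for r in _BUILTIN_ROWS],
        index=run_ids,
        columns=list(FACTOR_NAMES),
        dtype=float,
    )
    return DesignTable(run_ids=run_ids, settings=settings, factors=builtin_factors())


def load_design(path, factor_specs: list[FactorSpec] | None = None) -> DesignTable:
    """Read a delimited design file (columns: run_id + factor names)."""
    if factor_specs is None:
        factor_specs = builtin_factors()
    table = pd.read_csv(path, sep=None, engine="python", dtype={"run_id": str})
    if "run_id" not in table.columns:
        raise DesignValidationError("design file must have a 'run_id' column")
    names = [f.name for f in factor_specs]
    unknown = [c for c in table.columns if c not in names and c != "run_id"]
    if unknown:
        raise DesignValidationError(f"unknown factor columns: {unknown}")
    absent = [n for n in names if n not in table.columns]
    if absent:
        raise DesignValidationError(f"design file lacks factor columns: {absent}")
    run_ids = [str(r) for r in table["run_id"]]
    settings = table[names].astype(float)
    settings.index = run_ids
    return DesignTable(run_ids=run_ids, settings=settings, factors=factor_specs)


def write_design(design: DesignTable, path) -> None:
    out = design.settings.copy()
    out.insert(0, "run_id", design.run_ids)
    out.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Term coding
# --------------------------------------------------------------------------

def candidate_terms(design: DesignTable) -> list[str]:
    """Full second-order candidate set: linear, quadratic, continuous x
    continuous interactions, ordinal main effect and continuous x ordinal
    interactions (19 terms for the built-in 4+1 factor design)."""
    cont = design.continuous_names
    ords = design.ordinal_names
    terms = list(cont)
    terms += [f"{c}^2" for c in cont]
    terms += [f"{a}:{b}" for a, b in itertools.combinations(cont, 2)]
    for o in ords:
        terms.append(o)
        terms += [f"{c}:{o}" for c in cont]
    return terms


def parse_term(term: str, design: DesignTable) -> tuple[str, tuple[str, ...]]:
    """Classify a term string -> (kind, constituent factor names)."""
    cont = set(design.continuous_names)
    ords = set(design.ordinal_names)
    if term == "1":
        return "intercept", ()
    if term.endswith("^2"):
        base = term[:-2]
        if base not in cont:
            raise KeyError(f"unknown factor in term {term!r}")
        return "quadratic", (base,)
    if ":" in term:
        a, b = term.split(":", 1)
        for name in (a, b):
            if name not in cont | ords:
                raise KeyError(f"unknown factor in term {term!r}")
        if b in ords or a in ords:
            c, o = (a, b) if b in ords else (b, a)
            return "interaction_co", (c, o)
        return "interaction_cc", (a, b)
    if term in cont:
        return "linear", (term,)
    if term in ords:
        return "ordinal_main", (term,)
    raise KeyError(f"unknown term {term!r}")


def _coded_parent(
    settings: pd.DataFrame, spec: FactorSpec, scaling: str
) -> np.ndarray:
    x = settings[spec.name].to_numpy(dtype=float)
    if spec.kind == "ordinal":
        # binary code: 0 for the lowest modality, 1 for the highest
        return (x == spec.modalities[-1]).astype(float)
    if scaling == "raw":
        return x
    if scaling == "unit":
        return (x - spec.low) / (spec.high - spec.low)
    if scaling == "standardized":
        return (x - x.mean()) / x.std(ddof=1)
    raise ValueError(f"unknown scaling {scaling!r}")


def code_settings(
    settings: pd.DataFrame,
    factors: list[FactorSpec],
    terms: list[str],
    scaling: str = "unit",
    center_polynomials: bool = False,
    intercept: bool = False,
) -> CodedMatrix:
    """Code arbitrary factor settings (rows) into model-term columns.

    With ``standardized`` scaling the mean/variance are taken over the rows
    provided, so new points should be coded against the fitting design; the
    default ``unit`` coding maps each factor range to [0, 1] independently
    of the rows and is safe for prediction grids.
    """
    by_name = {f.name: f for f in factors}
    cont = {f.name for f in factors if f.kind == "continuous"}
    ords = {f.name for f in factors if f.kind == "ordinal"}

    def classify(term: str) -> tuple[str, tuple[str, ...]]:
        if term == "1":
            return "intercept", ()
        if term.endswith("^2"):
            base = term[:-2]
            if base not in cont:
                raise KeyError(f"unknown factor in term {term!r}")
            return "quadratic", (base,)
        if ":" in term:
            a, b = term.split(":", 1)
            for name in (a, b):
                if name not in cont | ords:
                    raise KeyError(f"unknown factor in term {term!r}")
            if a in ords or b in ords:
                c, o = (a, b) if b in ords else (b, a)
                return "interaction_co", (c, o)
            return "interaction_cc", (a, b)
        if term in cont:
            return "linear", (term,)
        if term in ords:
            return "ordinal_main", (term,)
        raise KeyError(f"unknown term {term!r}")

    n = len(settings)
    cols: dict[str, np.ndarray] = {}
    meta: dict[str, tuple[str, tuple[str, ...]]] = {}
    if intercept:
        cols["1"] = np.ones(n)
        meta["1"] = ("intercept", ())
    for term in terms:
        kind, parents = classify(term)
        if term in cols:
            raise ValueError(f"duplicate term {term!r}")
        if kind == "intercept":
            cols["1"] = np.ones(n)
        elif kind in ("linear", "ordinal_main"):
            cols[term] = _coded_parent(settings, by_name[parents[0]], scaling)
        elif kind == "quadratic":
            parent = _coded_parent(settings, by_name[parents[0]], scaling)
            if center_polynomials:
                parent = parent - parent.mean()
            cols[term] = parent**2
        else:  # interaction_cc / interaction_co
            a = _coded_parent(settings, by_name[parents[0]], scaling)
            b = _coded_parent(settings, by_name[parents[1]], scaling)
            cols[term] = a * b
        meta[term] = (kind, parents)
    frame = pd.DataFrame(cols, index=settings.index)
    return CodedMatrix(columns=frame, term_meta=meta)


def code_design(
    design: DesignTable,
    terms: list[str] | None = None,
    scaling: str = "unit",
    center_polynomials: bool = False,
    intercept: bool = False,
) -> CodedMatrix:
    """Build model-term columns from the design.

    Continuous factors are coded per ``scaling`` (raw, unit [0,1], or
    standardized); the ordinal factor is coded 0/1 by ascending modality.
    Quadratic and interaction columns are elementwise products of their
    coded parents; ``center_polynomials`` squares (x - mean) instead of x.
    """
    if terms is None:
        terms = candidate_terms(design)
    for term in terms:
        parse_term(term, design)  # validates against this design's factors
    return code_settings(
        design.settings, design.factors, terms, scaling=scaling,
        center_polynomials=center_polynomials, intercept=intercept,
    )


# --------------------------------------------------------------------------
# Collinearity and replicate structure
# --------------------------------------------------------------------------

def collinearity(design: DesignTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson R (and two-sided p) among factor columns.

    The ordinal factor enters as its 0/1 code; Pearson R is invariant to
    that affine choice.  Raises on a zero-variance factor column.
    """
    if design.n_runs < 3:
        raise ValueError("collinearity needs >=3 runs")
    coded = code_design(design, terms=[f.name for f in design.factors], scaling="raw")
    X = coded.values
    names = list(coded.columns.columns)
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"zero-variance factor column {name!r}")
    p = len(names)
    R = np.eye(p)
    P = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            r, pv = stats.pearsonr(X[:, i], X[:, j])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = pv
    return (
        pd.DataFrame(R, index=names, columns=names),
        pd.DataFrame(P, index=names, columns=names),
    )


def replicate_groups(design: DesignTable) -> list[list[str]]:
    """Groups of runs with identical settings (size >= 2), for pure error.

    Grouping uses exact equality of settings; design files are expected to
    carry exact printed values.  Groups and members are returned in sorted
    order so the partition is invariant to row permutation.
    """
    buckets: dict[tuple[float, ...], list[str]] = {}
    for rid in design.run_ids:
        key = tuple(float(v) for v in design.settings.loc[rid])
        buckets.setdefault(key, []).append(rid)
    groups = [sorted(g) for g in buckets.values() if len(g) >= 2]
    groups.sort(key=lambda g: g[0])
    return groups


def pure_error_df(design: DesignTable) -> int:
    """Pure-error degrees of freedom: sum of (group size - 1)."""
    return sum(len(g) - 1 for g in replicate_groups(design))
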