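"""Synthetic abundance data with known response-surface ground truth.

Generates variables-x-runs abundance matrices over a design from a
second-order response-surface model

    y = b0 + sum b_i x_i + sum b_ii x_i^2 + sum b_ij x_i x_j
        + b_CO2 CO2 + sum b_iCO2 x_i CO2 + e,    e ~ N(0, sigma^2)

with block structure of co-regulated variables (clusters sharing a term
signature with small coefficient jitter), homoscedastic Gaussian noise per
variable, and sporadic missing values masked completely at random.  The
ground truth is retained so every downstream stage (screening, clustering,
profiling, per-variable modeling) can be tested by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CodedMatrix, DesignTable, candidate_terms, code_design

__all__ = [
    "VariableTruth",
    "TruthModel",
    "AbundanceMatrix",
    "make_truth",
    "simulate",
    "write_matrix",
    "read_matrix",
]

MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class VariableTruth:
    """Ground truth for one biological variable."""

    var_id: str
    var_class: str  # "spot" | "assay"
    cluster: int
    intercept: float
    terms: tuple[tuple[str, float], ...]  # (term, coefficient) on the coded scale
    noise_sd: float
    missing_rate: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")


@dataclass
class TruthModel:
    """Per-variable ground-truth coefficients, noise and cluster labels."""

    variables: list[VariableTruth]
    scaling: str = "unit"

    def __getitem__(self, var_id: str) -> VariableTruth:
        for v in self.variables:
            if v.var_id == var_id:
                return v
        raise KeyError(var_id)

    @property
    def cluster_labels(self) -> dict[str, int]:
        return {v.var_id: v.cluster for v in self.variables}

    def to_json(self) -> str:
        payload = [
            {
                "var_id": v.var_id,
                "var_class": v.var_class,
                "cluster": v.cluster,
                "intercept": v.intercept,
                "terms": [[t, b] for t, b in v.terms],
                "noise_sd": v.noise_sd,
                "missing_rate": v.missing_rate,
            }
            for v in self.variables
        ]
        return json.dumps({"scaling": self.scaling, "variables": payload}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthModel":
        doc = json.loads(text)
        variables = [
            VariableTruth(
                var_id=d["var_id"],
                var_class=d["var_class"],
                cluster=d["cluster"],
                intercept=d["intercept"],
                terms=tuple((t, float(b)) for t, b in d["terms"]),
                noise_sd=d["noise_sd"],
                missing_rate=d["missing_rate"],
            )
            for d in doc["variables"]
        ]
        return cls(variables=variables, scaling=doc["scaling"])


@dataclass
class AbundanceMatrix:
    """Variables x runs abundance matrix with a missing-value mask.

    ``data`` holds NaN at masked cells; ``var_class`` maps each variable to
    "spot" or "assay".
    """

    data: pd.DataFrame  # index = variable ids, columns = run ids
    var_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise ValueError("matrix must have at least one variable")
        if self.data.index.duplicated().any():
            dupes = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise ValueError(f"duplicate variable ids: {dupes}")
        if not self.var_class:
            self.var_class = {v: "spot" for v in self.data.index}
        n_obs = self.data.notna().sum(axis=1)
        if (n_obs < 3).any():
            bad = list(self.data.index[n_obs < 3])
            raise ValueError(f"variables with <3 non-missing values: {bad}")

    @property
    def variables(self) -> list[str]:
        return list(self.data.index)

    @property
    def run_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def subset(self, var_ids: list[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(
            data=self.data.loc[var_ids].copy(),
            var_class={v: self.var_class[v] for v in var_ids},
        )

    def of_class(self, var_class: str) -> "AbundanceMatrix":
        ids = [v for v in self.variables if self.var_class[v] == var_class]
        return self.subset(ids)


# --------------------------------------------------------------------------
# Truth generation
# --------------------------------------------------------------------------

def make_truth(
    n_vars: int = 135,
    n_clusters: int = 8,
    effect_size_range: tuple[float, float] = (0.5, 2.0),
    noise_sd: float = 0.1,
    missing_rate: float = 0.0,
    seed: int = 0,
    design: DesignTable | None = None,
    n_assays: int = 0,
    terms_per_cluster: tuple[int, int] = (2, 4),
    scaling: str = "unit",
) -> TruthModel:
    """Draw a TruthModel with clustered term signatures.

    Variables within a cluster share the same active terms with coefficients
    jittered by at most 10%, emulating blocks of co-regulated proteins.  An
    ``effect_size_range`` of (0, 0) yields the pure-noise null.  The last
    ``n_assays`` variables are flagged "assay" (simulated identically but
    screened with assay-class criteria downstream).
    """
    if n_clusters > n_vars:
        raise ValueError("n_clusters must be <= n_vars")
    from .design import builtin_design

    if design is None:
        design = builtin_design()
    universe = candidate_terms(design)
    if not universe:
        raise ValueError("empty term universe")
    rng = np.random.default_rng(seed)
    lo, hi = effect_size_range

    signatures: list[tuple[tuple[str, float], ...]] = []
    for _ in range(n_clusters):
        k = int(rng.integers(terms_per_cluster[0], terms_per_cluster[1] + 1))
        k = min(k, len(universe))
        chosen = sorted(rng.choice(len(universe), size=k, replace=False))
        sig = []
        for idx in chosen:
            magnitude = rng.uniform(lo, hi)
            sign = rng.choice([-1.0, 1.0])
            sig.append((universe[idx], sign * magnitude))
        signatures.append(tuple(sig))

    # deal variables round-robin so every cluster is non-empty
    labels = [(i % n_clusters) + 1 for i in range(n_vars)]
    variables = []
    for i in range(n_vars):
        cluster = labels[i]
        base = signatures[cluster - 1]
        jitter = rng.uniform(-0.1, 0.1, size=len(base))
        terms = tuple(
            (t, b * (1.0 + j)) for (t, b), j in zip(base, jitter)
        )
        is_assay = i >= n_vars - n_assays
        var_id = f"assay{i - (n_vars - n_assays) + 1}" if is_assay else f"spot{i + 1}"
        variables.append(
            VariableTruth(
                var_id=var_id,
                var_class="assay" if is_assay else "spot",
                cluster=cluster,
                intercept=float(rng.uniform(5.0, 10.0)),
                terms=terms,
                noise_sd=noise_sd,
                missing_rate=missing_rate,
            )
        )
    return TruthModel(variables=variables, scaling=scaling)


def truth_surface(design: DesignTable, truth: TruthModel) -> pd.DataFrame:
    """Deterministic model surface (no noise, no mask) for each variable."""
    coded: CodedMatrix = code_design(
        design, terms=candidate_terms(design), scaling=truth.scaling
    )
    rows = {}
    for v in truth.variables:
        y = np.full(design.n_runs, v.intercept, dtype=float)
        for term, b in v.terms:
            y = y + b * coded.columns[term].to_numpy()
        rows[v.var_id] = y
    return pd.DataFrame.from_dict(rows, orient="index", columns=design.run_ids)


def simulate(design: DesignTable, truth: TruthModel, seed: int = 0) -> AbundanceMatrix:
    """Simulate an abundance matrix: surface + N(0, sigma^2) noise + MCAR mask."""
    rng = np.random.default_rng(seed)
    surface = truth_surface(design, truth)
    n_runs = design.n_runs
    data = surface.copy()
    for v in truth.variables:
        noise = rng.normal(0.0, v.noise_sd, size=n_runs) if v.noise_sd > 0 else 0.0
        data.loc[v.var_id] = surface.loc[v.var_id].to_numpy() + noise
    for v in truth.variables:
        if v.missing_rate > 0:
            mask = rng.random(n_runs) < v.missing_rate
            # keep >=3 observed cells per variable
            if mask.sum() > n_runs - 3:
                keep = rng.choice(np.flatnonzero(mask), size=mask.sum() - (n_runs - 3),
                                  replace=False)
                mask[keep] = False
            row = data.loc[v.var_id].to_numpy(dtype=float)
            row[mask] = np.nan
            data.loc[v.var_id] = row
    var_class = {v.var_id: v.var_class for v in truth.variables}
    return AbundanceMatrix(data=data, var_class=var_class)


# --------------------------------------------------------------------------
# I/O: delimited text, variables as rows, runs as columns
# --------------------------------------------------------------------------

def write_matrix(matrix: AbundanceMatrix, path, missing_token: str = MISSING_TOKEN) -> None:
    out = matrix.data.copy()
    out.insert(0, "class", [matrix.var_class[v] for v in matrix.variables])
    out.index.name = "variable"
    out.to_csv(path, sep="\t", na_rep=missing_token)


def read_matrix(path, missing_token: str = MISSING_TOKEN) -> AbundanceMatrix:
    table = pd.read_csv(path, sep="\t", index_col="variable",
                        na_values=[missing_token], keep_default_na=False)
    if table.index.duplicated().any():
        dupes = sorted(set(table.index[table.index.duplicated()]))
        raise ValueError(f"duplicate variable ids: {dupes}")
    if "class" in table.columns:
        var_class = {str(v): str(c) for v, c in table["class"].items()}
        table = table.drop(columns=["class"])
    else:
        var_class = {str(v): "spot" for v in table.index}
    try:
        data = table.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in abundance matrix: {exc}") from exc
    data.index = [str(v) for v in table.index]
    data.columns = [str(c) for c in table.columns]
    return AbundanceMatrix(data=data, var_class=var_class)
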