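"""Initial four-strategy screening of environmentally regulated variables.

Before clustering and modeling, each biological variable is screened for a
relevant influence of the environment by four complementary strategies and
a 3-of-4 vote:

1. one single-factor, one-latent-factor PLSR per continuous factor and CO2
   stratum (8 models); pass if the latent factor explains enough of the
   variable's variance in at least one model;
2. one MLR per continuous factor on {x, x^2, x*CO2} (4 models); pass on
   whole-model significance in at least one;
3. one PLSR per CO2 stratum on all four continuous factors at a class-
   specific latent-factor count (2 models); pass on cumulative variance
   explained;
4. one MLR on all linear, quadratic and x*CO2 terms (1 model); pass on
   whole-model significance.

Protein spots and additional assays are screened independently with
class-specific thresholds.  No multiplicity correction is applied at this
stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignTable
from .pls import nipals_pls
from .response_surface import fit_mlr
from .simulate import AbundanceMatrix

__all__ = [
    "ScreeningCriteria",
    "DEFAULT_CRITERIA",
    "strategy1",
    "strategy2",
    "strategy3",
    "strategy4",
    "screen",
]


@dataclass(frozen=True)
class ScreeningCriteria:
    """Class-specific screening thresholds (3-of-4 vote by default)."""

    s1_threshold: float = 0.30
    s1_no3_threshold: float = 0.30  # spots use a relaxed 0.19 for nitrate models
    s2_p: float = 0.05
    s3_threshold: float = 0.30
    s3_n_factors: int = 2
    s4_p: float = 0.05
    votes_required: int = 3
    p_kind: str = "whole_model"  # or "best_effect"

    def __post_init__(self) -> None:
        for name in ("s1_threshold", "s1_no3_threshold", "s2_p", "s3_threshold", "s4_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must be in (0, 1)")
        if self.votes_required not in (1, 2, 3, 4):
            raise ValueError("votes_required must be 1..4")


DEFAULT_CRITERIA: dict[str, ScreeningCriteria] = {
    "spot": ScreeningCriteria(
        s1_threshold=0.30, s1_no3_threshold=0.19, s2_p=0.075,
        s3_threshold=0.30, s3_n_factors=2, s4_p=0.10,
    ),
    "assay": ScreeningCriteria(
        s1_threshold=0.30, s1_no3_threshold=0.30, s2_p=0.05,
        s3_threshold=0.65, s3_n_factors=4, s4_p=0.05,
    ),
}


def _strata(design: DesignTable) -> dict[float, list[str]]:
    """Run ids grouped by ordinal (CO2) modality."""
    ords = design.ordinal_names
    if len(ords) != 1:
        raise ValueError("screening expects exactly one ordinal factor")
    col = design.settings[ords[0]]
    return {mod: list(col.index[col == mod]) for mod in sorted(col.unique())}


def _stratum_blocks(
    matrix: AbundanceMatrix, design: DesignTable, run_ids: list[str],
    variables: list[str],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Complete-case X (continuous factors) and Y blocks within a stratum.

    Variables constant within the stratum are dropped from the Y block
    (their variance explained there is undefined); the returned variable
    list reflects the columns of Y.
    """
    sub = matrix.data.loc[variables, run_ids]
    keep = [r for r in run_ids if sub[r].notna().all()]
    if len(keep) < 3:
        raise ValueError(f"stratum has {len(keep)} complete runs; need >=3")
    X = design.settings.loc[keep, design.continuous_names].to_numpy(dtype=float)
    block = sub[keep]
    varying = [v for v in variables if block.loc[v].nunique() > 1]
    Y = block.loc[varying].to_numpy(dtype=float).T  # runs x variables
    return X, Y, varying


def _usable(matrix: AbundanceMatrix) -> tuple[list[str], list[str]]:
    """Split variables into usable and zero-variance (auto-failed) sets."""
    usable, degenerate = [], []
    for v in matrix.variables:
        vals = matrix.data.loc[v].dropna()
        if vals.nunique() < 2:
            degenerate.append(v)
        else:
            usable.append(v)
    if degenerate:
        warnings.warn(
            f"zero-variance variables auto-failed: {degenerate}", stacklevel=3
        )
    return usable, degenerate


def strategy1(
    matrix: AbundanceMatrix, design: DesignTable, criteria: ScreeningCriteria
) -> pd.DataFrame:
    """Single-factor, one-latent-factor PLSRs per CO2 stratum (8 models).

    For a single-predictor one-factor PLS the per-response variance
    explained equals the squared within-stratum Pearson correlation with
    the factor.  The pass threshold is relaxed for the nitrate models when
    the class criteria say so.
    """
    usable, degenerate = _usable(matrix)
    strata = _strata(design)
    metric = pd.Series(0.0, index=matrix.variables)
    passed = pd.Series(False, index=matrix.variables)
    for factor in design.continuous_names:
        threshold = (
            criteria.s1_no3_threshold if factor == "no3" else criteria.s1_threshold
        )
        for _, run_ids in strata.items():
            X, Y, varying = _stratum_blocks(matrix, design, run_ids, usable)
            j = design.continuous_names.index(factor)
            x = X[:, [j]]
            if np.ptp(x) == 0:
                raise ValueError(f"factor {factor!r} constant within stratum")
            model = nipals_pls(x, Y, 1)
            varexp = model.var_explained[0]
            for v, ve in zip(varying, varexp):
                metric[v] = max(metric[v], float(ve))
                if ve >= threshold:
                    passed[v] = True
    metric[degenerate] = np.nan
    return pd.DataFrame({"metric": metric, "passed": passed})


def _mlr_p(
    matrix: AbundanceMatrix, design: DesignTable, terms: list[str],
    criteria: ScreeningCriteria,
) -> pd.Series:
    """Per-variable whole-model (or best-effect) MLR p-value for one model."""
    out = pd.Series(np.nan, index=matrix.variables)
    for v in matrix.variables:
        y = matrix.data.loc[v]
        y.index = matrix.run_ids
        try:
            model = fit_mlr(y, design, terms, response_id=v)
        except (ValueError, np.linalg.LinAlgError):
            continue  # zero variance / singular: leave NaN (auto-fail)
        if criteria.p_kind == "best_effect":
            out[v] = min(model.effect_p.values()) if model.effect_p else np.nan
        else:
            out[v] = model.p_whole_model
    return out


def strategy2(
    matrix: AbundanceMatrix, design: DesignTable, criteria: ScreeningCriteria
) -> pd.DataFrame:
    """Per-factor MLRs on {x, x^2, x*CO2} (4 models); min p vs cutoff."""
    ord_name = design.ordinal_names[0]
    min_p = pd.Series(np.nan, index=matrix.variables)
    for factor in design.continuous_names:
        terms = [factor, f"{factor}^2", f"{factor}:{ord_name}"]
        p = _mlr_p(matrix, design, terms, criteria)
        min_p = np.fmin(min_p, p)
    passed = min_p <= criteria.s2_p
    return pd.DataFrame({"metric": min_p, "passed": passed.fillna(False)})


def strategy3(
    matrix: AbundanceMatrix, design: DesignTable, criteria: ScreeningCriteria
) -> pd.DataFrame:
    """All-continuous-factor PLSR per CO2 stratum at the class's factor count."""
    usable, degenerate = _usable(matrix)
    strata = _strata(design)
    metric = pd.Series(0.0, index=matrix.variables)
    for _, run_ids in strata.items():
        X, Y, varying = _stratum_blocks(matrix, design, run_ids, usable)
        a = min(criteria.s3_n_factors, min(X.shape[0] - 1, X.shape[1]))
        model = nipals_pls(X, Y, a)
        cum = model.cumulative_var_explained()
        for v, ve in zip(varying, cum):
            metric[v] = max(metric[v], float(ve))
    passed = metric >= criteria.s3_threshold
    metric[degenerate] = np.nan
    passed[degenerate] = False
    return pd.DataFrame({"metric": metric, "passed": passed})


def strategy4(
    matrix: AbundanceMatrix, design: DesignTable, criteria: ScreeningCriteria,
    include_ordinal_main: bool = False,
) -> pd.DataFrame:
    """One MLR per variable on all linear, quadratic and x*CO2 terms."""
    ord_name = design.ordinal_names[0]
    cont = design.continuous_names
    terms = list(cont) + [f"{c}^2" for c in cont] + [f"{c}:{ord_name}" for c in cont]
    if include_ordinal_main:
        terms.append(ord_name)
    if design.n_runs < len(terms) + 2:
        raise ValueError("too few runs for the strategy-4 model")
    p = _mlr_p(matrix, design, terms, criteria)
    passed = p <= criteria.s4_p
    return pd.DataFrame({"metric": p, "passed": passed.fillna(False)})


def screen(
    matrix: AbundanceMatrix,
    design: DesignTable,
    criteria: dict[str, ScreeningCriteria] | None = None,
) -> pd.DataFrame:
    """Run all four strategies per variable class and apply the 3-of-4 vote.

    Returns a report with per-strategy metrics (max variance explained for
    the PLSR strategies, min p for the MLR ones), pass flags, vote counts
    and the selected flag.  Spots and assays are screened independently
    with their class criteria.
    """
    if criteria is None:
        criteria = DEFAULT_CRITERIA
    frames = []
    for var_class in sorted(set(matrix.var_class.values())):
        sub = matrix.of_class(var_class)
        crit = criteria[var_class]
        s1 = strategy1(sub, design, crit)
        s2 = strategy2(sub, design, crit)
        s3 = strategy3(sub, design, crit)
        s4 = strategy4(sub, design, crit)
        votes = (
            s1["passed"].astype(int) + s2["passed"].astype(int)
            + s3["passed"].astype(int) + s4["passed"].astype(int)
        )
        frames.append(pd.DataFrame({
            "variable": sub.variables,
            "class": var_class,
            "s1_metric": s1["metric"], "s1_pass": s1["passed"],
            "s2_metric": s2["metric"], "s2_pass": s2["passed"],
            "s3_metric": s3["metric"], "s3_pass": s3["passed"],
            "s4_metric": s4["metric"], "s4_pass": s4["passed"],
            "votes": votes,
            "selected": votes >= crit.votes_required,
        }))
    report = pd.concat(frames)
    return report.loc[matrix.variables].reset_index(drop=True)
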