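"""Characterization of environmental regulation within and across clusters.

Four views of the co-regulation structure:

* PCA over all biological variables on the pairwise-complete correlation
  matrix, with per-component variance proportions, loadings and run scores;
* one PLSR per cluster on the five environmental predictors (continuous
  factors + 0/1-coded CO2) with the latent-factor count selected by
  leave-one-out PRESS and van der Voet tests, summarized as VIP scores and
  coefficient signs (sign reported where VIP > 1);
* pairwise Pearson correlations among cluster members (pairwise method,
  no imputation);
* ANCOVA per cluster: the environmental response-surface terms plus the
  variable identity (effect-coded categorical) and identity x environment
  interactions, so each variable's regulation is compared to the cluster
  average; a significant interaction flags the variable as diverging from
  the common regulation for that factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable, candidate_terms, code_design
from .pls import nipals_pls, pls_coefficient_signs, select_n_factors, vip
from .simulate import AbundanceMatrix

__all__ = [
    "PCAResult",
    "AncovaModel",
    "pca",
    "in_cluster_plsr",
    "correlation_matrix",
    "ancova",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    proportions: np.ndarray  # percent of variability per component
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # runs x components


@dataclass
class AncovaModel:
    cluster_id: int
    r2: float
    r2_adjusted: float
    rmse_f: float
    f_whole_model: float
    p_whole_model: float
    coefficients: dict[str, float]
    divergence: pd.DataFrame  # (variable, factor) -> beta, p, flag
    n: int
    k: int


def pca(matrix: AbundanceMatrix) -> PCAResult:
    """PCA on the pairwise-complete correlation matrix of the variables.

    Scores are computed from per-variable standardized data with missing
    cells contributing 0 (the mean).  Loading signs are fixed so each
    component's largest-magnitude loading is positive.
    """
    if len(matrix.variables) < 2:
        raise ValueError("PCA needs >=2 variables")
    wide = matrix.data.T  # runs x variables
    corr = wide.corr(min_periods=2)
    if corr.isna().any().any():
        bad = corr.isna().stack()
        pair = bad[bad].index[0]
        raise ValueError(f"correlation undefined for pair {pair}")
    eigval, eigvec = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| entry positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    proportions = 100.0 * eigval / eigval.sum()
    comp_names = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=matrix.variables, columns=comp_names)
    z = ((wide - wide.mean()) / wide.std(ddof=1)).fillna(0.0)
    scores = pd.DataFrame(z.to_numpy() @ eigvec, index=wide.index, columns=comp_names)
    return PCAResult(
        eigenvalues=eigval, proportions=proportions,
        loadings=loadings, scores=scores,
    )


def _environment_block(
    matrix: AbundanceMatrix, design: DesignTable
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Complete-case X (4 continuous + 0/1 CO2) and Y blocks over runs."""
    predictors = design.continuous_names + design.ordinal_names
    coded = code_design(design, terms=predictors, scaling="raw")
    sub = matrix.data
    keep = [r for r in design.run_ids if sub[r].notna().all()]
    if len(keep) < 3:
        raise ValueError("fewer than 3 complete runs")
    X = coded.columns.loc[keep].to_numpy(dtype=float)
    Y = sub[keep].to_numpy(dtype=float).T
    return X, Y, predictors


def in_cluster_plsr(
    matrix_cluster: AbundanceMatrix,
    design: DesignTable,
    a_max: int = 5,
    alpha: float = 0.10,
    seed: int | None = 0,
    vip_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Cluster-level PLSR: VIP per environmental factor + coefficient sign.

    All cluster members are joint responses; the latent-factor count is
    chosen by LOO PRESS + van der Voet (search range ``a_max``).  The sign
    of the (response-averaged) PLS coefficient is reported only for factors
    whose VIP exceeds ``vip_cutoff``.
    """
    X, Y, predictors = _environment_block(matrix_cluster, design)
    a_max = min(a_max, min(X.shape[0] - 1, X.shape[1]))
    selection = select_n_factors(X, Y, a_max, alpha=alpha, seed=seed)
    model = nipals_pls(X, Y, selection.chosen)
    scores = vip(model)
    signs = pls_coefficient_signs(model)
    mean_coef = model.coef.mean(axis=1)
    out = pd.DataFrame(
        {
            "vip": scores,
            "sign": [
                int(np.sign(mean_coef[j])) if scores[j] > vip_cutoff else 0
                for j in range(len(predictors))
            ],
            "n_factors": selection.chosen,
        },
        index=predictors,
    )
    out.attrs["selection"] = selection
    out.attrs["signs_full"] = signs
    return out


def correlation_matrix(
    matrix_cluster: AbundanceMatrix, min_shared: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson R and two-sided p among cluster variables.

    Computed by the pairwise method without imputation; pairs with fewer
    than ``min_shared`` shared non-missing runs are flagged undefined (NaN).
    """
    variables = matrix_cluster.variables
    p = len(variables)
    R = np.eye(p)
    P = np.zeros((p, p))
    data = matrix_cluster.data
    for i in range(p):
        for j in range(i + 1, p):
            a = data.loc[variables[i]]
            b = data.loc[variables[j]]
            shared = a.notna() & b.notna()
            if shared.sum() < min_shared:
                R[i, j] = R[j, i] = np.nan
                P[i, j] = P[j, i] = np.nan
                continue
            r, pv = stats.pearsonr(a[shared], b[shared])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = pv
    return (
        pd.DataFrame(R, index=variables, columns=variables),
        pd.DataFrame(P, index=variables, columns=variables),
    )


def ancova(
    matrix_cluster: AbundanceMatrix,
    design: DesignTable,
    cluster_id: int = 0,
    p_cutoff: float = 0.05,
    coding: str = "effect",
    scaling: str = "unit",
) -> AncovaModel:
    """Divergence detection within one cluster by analysis of covariance.

    Cluster members are standardized and stacked in long format (one row
    per variable x run).  The model holds the full second-order
    environmental terms, variable-identity main effects and identity x
    {continuous factors, CO2} interactions.  Identity is effect-coded
    (sum-to-zero) by default so each interaction measures a variable's
    deviation from the cluster-average regulation; a deviation with
    p <= ``p_cutoff`` flags that (variable, factor) pair as divergent, with
    its standardized coefficient (beta-weight) reported.
    """
    variables = matrix_cluster.variables
    v = len(variables)
    env_terms = candidate_terms(design)
    coded = code_design(design, terms=env_terms, scaling=scaling)
    cont = design.continuous_names
    ords = design.ordinal_names
    inter_factors = cont + ords

    # per-variable standardization over non-missing cells
    std_rows = {}
    for var in variables:
        row = matrix_cluster.data.loc[var]
        obs = row.dropna()
        sd = obs.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"variable {var!r} is constant; cannot standardize")
        std_rows[var] = (row - obs.mean()) / sd

    # long-format response and design matrix
    y_parts, env_parts, ident_parts = [], [], []
    for m, var in enumerate(variables):
        row = std_rows[var]
        keep = row.notna()
        runs = [r for r in design.run_ids if keep[r]]
        y_parts.append(row[runs].to_numpy(dtype=float))
        env_parts.append(coded.columns.loc[runs].to_numpy(dtype=float))
        ident = np.zeros((len(runs), v))
        ident[:, m] = 1.0
        ident_parts.append(ident)
    y = np.concatenate(y_parts)
    env = np.vstack(env_parts)
    ident_full = np.vstack(ident_parts)  # indicator coding, v columns

    if coding == "effect":
        # sum-to-zero: column m -> indicator_m - indicator_v (last is reference)
        ident_x = ident_full[:, : v - 1] - ident_full[:, [v - 1]]
    elif coding == "dummy":
        ident_x = ident_full[:, : v - 1]
    else:
        raise ValueError(f"unknown identity coding {coding!r}")

    factor_cols = {
        f: coded.columns[f].to_numpy(dtype=float) for f in inter_factors
    }
    run_pos = {r: i for i, r in enumerate(design.run_ids)}

    blocks = [np.ones((len(y), 1)), env]
    col_names = ["1"] + env_terms
    if v > 1:
        blocks.append(ident_x)
        col_names += [f"id[{variables[m]}]" for m in range(v - 1)]
        for f in inter_factors:
            fvals = np.concatenate([
                np.array([
                    factor_cols[f][run_pos[r]]
                    for r in design.run_ids
                    if std_rows[var].notna()[r]
                ])
                for var in variables
            ])
            blocks.append(ident_x * fvals[:, None])
            col_names += [f"id[{variables[m]}]:{f}" for m in range(v - 1)]
    X = np.hstack(blocks)

    n, ncol = X.shape
    k = ncol - 1
    if n - k - 1 <= 0:
        raise ValueError("too few observations for the ANCOVA term set")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < ncol:
        raise np.linalg.LinAlgError("rank-deficient ANCOVA design matrix")
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    ybar = y.mean()
    sst = float(((y - ybar) ** 2).sum())
    ssm = float(((fitted - ybar) ** 2).sum())
    r2 = ssm / sst
    r2_adj = 1.0 - (sse / (n - k - 1)) / (sst / (n - 1))
    rmse_f = float(np.sqrt(sse / (n - k - 1)))
    mse = sse / (n - k - 1)
    if mse > 0:
        f_whole = (ssm / k) / mse
        p_whole = float(stats.f.sf(f_whole, k, n - k - 1))
    else:
        f_whole, p_whole = np.inf, 0.0

    xtx_inv = np.linalg.inv(X.T @ X)

    def contrast_test(c: np.ndarray) -> tuple[float, float]:
        est = float(c @ beta)
        var_est = float(c @ xtx_inv @ c) * mse
        if var_est <= 0:
            return est, 0.0 if est != 0 else 1.0
        t = est / np.sqrt(var_est)
        return est, float(2 * stats.t.sf(abs(t), n - k - 1))

    sdy = float(np.std(y, ddof=1))
    rows = []
    if v > 1:
        for f in inter_factors:
            base = col_names.index(f"id[{variables[0]}]:{f}")
            cols = list(range(base, base + v - 1))
            for m, var in enumerate(variables):
                c = np.zeros(ncol)
                if coding == "effect":
                    if m < v - 1:
                        c[cols[m]] = 1.0
                    else:
                        for cc in cols:
                            c[cc] = -1.0
                else:
                    if m < v - 1:
                        c[cols[m]] = 1.0
                    else:
                        continue  # reference deviation not identified under dummy
                est, pval = contrast_test(c)
                # standardized coefficient: scale by the sd of the implied column
                col_vals = X[:, cols] @ c[cols] if coding == "effect" else X[:, cols[m]]
                sdx = float(np.std(col_vals, ddof=1))
                beta_w = est * sdx / sdy if sdy > 0 else np.nan
                rows.append({
                    "variable": var, "factor": f, "beta_weight": beta_w,
                    "p": pval, "divergent": pval <= p_cutoff,
                })
    divergence = pd.DataFrame(
        rows, columns=["variable", "factor", "beta_weight", "p", "divergent"]
    )
    coefficients = dict(zip(col_names, (float(b) for b in beta)))
    return AncovaModel(
        cluster_id=cluster_id, r2=r2, r2_adjusted=r2_adj, rmse_f=rmse_f,
        f_whole_model=float(f_whole), p_whole_model=p_whole,
        coefficients=coefficients, divergence=divergence, n=n, k=k,
    )
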