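"""Co-regulation clustering of biological variables.

Variables (protein spots, then spots + assays) are standardized, missing
values are imputed by conditional-mean (regression) prediction from a
pairwise covariance matrix, and the variables are clustered by Ward's
minimum-variance agglomerative method with runs as the feature axis.
Cutting the dendrogram at k groups yields the co-regulated clusters used by
downstream profiling; re-clustering with assays appended co-assigns each
assay to a protein cluster by pattern similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .simulate import AbundanceMatrix

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "standardize",
    "impute_missing",
    "ward_cluster",
    "cut",
    "coassign",
]


@dataclass
class Dendrogram:
    """Agglomerative merge history for m leaves (m-1 merges)."""

    linkage: np.ndarray  # scipy linkage matrix
    leaves: list[str]  # leaf ids in input order
    method: str = "ward"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.leaves[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Newick-like text with merge heights as branch lengths."""
        m = len(self.leaves)
        heights = {i: 0.0 for i in range(m)}
        labels = {i: self.leaves[i] for i in range(m)}
        for step, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            node = m + step
            la = self.linkage[a - m, 2] if a >= m else 0.0
            lb = self.linkage[b - m, 2] if b >= m else 0.0
            labels[node] = (
                f"({labels[a]}:{h - la:.6g},{labels[b]}:{h - lb:.6g})"
            )
            heights[node] = h
        return labels[2 * m - 2] + ";"


@dataclass
class ClusterAssignment:
    """Variable id -> cluster label 1..k."""

    labels: dict[str, int]
    k: int

    def members(self, cluster: int) -> list[str]:
        return [v for v, c in self.labels.items() if c == cluster]

    def to_frame(self, var_class: dict[str, str] | None = None) -> pd.DataFrame:
        rows = {
            "variable": list(self.labels),
            "cluster": [self.labels[v] for v in self.labels],
        }
        if var_class is not None:
            rows["class"] = [var_class.get(v, "spot") for v in self.labels]
        return pd.DataFrame(rows)


def standardize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each variable to mean 0, variance 1 over its non-missing cells."""
    data = matrix.data.copy()
    for v in matrix.variables:
        row = data.loc[v]
        obs = row.dropna()
        sd = obs.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"variable {v!r} is constant; cannot standardize")
        data.loc[v] = (row - obs.mean()) / sd
    return AbundanceMatrix(data=data, var_class=dict(matrix.var_class))


def impute_missing(matrix: AbundanceMatrix, ridge_scale: float = 1e-8) -> AbundanceMatrix:
    """Impute missing cells by regression prediction from observed variables.

    A single covariance matrix is built by the pairwise method over the
    whole data set.  For each run with missing variables M and observed
    variables O the imputation is the conditional mean

        y_M = mu_M + Sigma_MO Sigma_OO^-1 (y_O - mu_O),

    with Sigma_OO ridge-regularized (eps = ridge_scale * trace/dim) when
    ill-conditioned.  Observed cells are preserved exactly.
    """
    data = matrix.data.copy()
    # pairwise covariance / means over non-missing cells (variables as columns)
    wide = data.T  # runs x variables
    cov = wide.cov(min_periods=2).to_numpy()
    if np.isnan(cov).any():
        raise ValueError("pairwise covariance not estimable for some variable pair")
    mu = wide.mean().to_numpy()
    var_index = {v: i for i, v in enumerate(matrix.variables)}

    for run in data.columns:
        col = data[run]
        missing = [v for v in matrix.variables if pd.isna(col[v])]
        if not missing:
            continue
        observed = [v for v in matrix.variables if not pd.isna(col[v])]
        if not observed:
            raise ValueError(f"run {run!r} has all variables missing")
        mi = [var_index[v] for v in missing]
        oi = [var_index[v] for v in observed]
        s_oo = cov[np.ix_(oi, oi)]
        s_mo = cov[np.ix_(mi, oi)]
        if np.linalg.cond(s_oo) > 1e12:
            eps = ridge_scale * np.trace(s_oo) / len(oi)
            s_oo = s_oo + eps * np.eye(len(oi))
        resid = col[observed].to_numpy(dtype=float) - mu[oi]
        pred = mu[mi] + s_mo @ np.linalg.solve(s_oo, resid)
        for v, value in zip(missing, pred):
            data.loc[v, run] = value
    return AbundanceMatrix(data=data, var_class=dict(matrix.var_class))


def ward_cluster(matrix: AbundanceMatrix) -> Dendrogram:
    """Ward minimum-variance agglomerative clustering of the variables.

    Requires a complete (post-imputation) matrix; runs are the feature
    axis.  Merge heights are the Ward distances on Euclidean geometry and
    are non-decreasing.
    """
    if len(matrix.variables) < 2:
        raise ValueError("clustering needs >=2 variables")
    X = matrix.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix has missing cells; impute before clustering")
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(linkage=Z, leaves=list(matrix.variables), method="ward")


def cut(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into k groups (removing the k-1 highest merges).

    Labels are renumbered 1..k by first appearance in leaf order so the
    assignment is deterministic.
    """
    m = len(dendrogram.leaves)
    if not 1 <= k <= m:
        raise ValueError(f"k={k} outside [1, {m}]")
    raw = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf, lab in zip(dendrogram.leaves, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[leaf] = relabel[lab]
    return ClusterAssignment(labels=labels, k=len(relabel))


def coassign(
    matrix_with_assays: AbundanceMatrix, k: int,
) -> ClusterAssignment:
    """Joint re-clustering of spots + assays; assays inherit cluster labels.

    The matrix is standardized, imputed and Ward-clustered as a whole, so
    each assay lands in the protein cluster whose abundance pattern it
    shares.
    """
    prepared = impute_missing(standardize(matrix_with_assays))
    return cut(ward_cluster(prepared), k)
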