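"""Per-variable response-surface modeling of abundance vs environment.

Each biological variable y is modeled over the designed experiment by the
second-order equation

    y^ = b0 + sum b_i x_i + sum b_ii x_i^2 + sum b_ij x_i x_j
         + b_CO2 CO2 + sum b_iCO2 x_i CO2 + e

where x_i are the continuous factors (coded to [0, 1] by default) and CO2 is
the 0/1-coded ordinal factor.  Terms are chosen by forward stepwise selection
under the corrected Akaike information criterion (AICc); the selected model
is then fit by ordinary least squares with a complete diagnostic block:
R2, adjusted R2, fitting RMSE, response average scale, whole-model ANOVA F,
per-effect extra-sum-of-squares F, lack-of-fit vs pure-error F (replicate
runs permitting), and standardized coefficients (beta-weights).  Models are
cross-validated by the k-fold method (k = 4) reporting the uncorrected
cross-validation RMSE, and one-factor prediction profiles evaluate the
fitted surface along a factor grid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    DesignTable,
    candidate_terms,
    code_settings,
    replicate_groups,
)

__all__ = [
    "FittedModel",
    "CVResult",
    "aicc",
    "stepwise_aicc",
    "fit_mlr",
    "effect_significance_table",
    "kfold_cv",
    "profile",
    "fit_all",
]


@dataclass
class FittedModel:
    """One response's term set, coefficients, beta-weights and diagnostics."""

    response_id: str
    terms: list[str]
    intercept: float
    coefficients: dict[str, float]
    beta_weights: dict[str, float]
    r2: float
    r2_adjusted: float
    rmse_f: float
    response_average_scale: float
    f_whole_model: float
    p_whole_model: float
    effect_f: dict[str, float]
    effect_p: dict[str, float]
    lack_of_fit: dict[str, float] | None  # f, p, ss_lof, ss_pure, df_lof, df_pure
    n: int
    k: int
    scaling: str
    center_polynomials: bool
    run_ids: list[str] = field(default_factory=list)
    design: DesignTable | None = None

    def predict_settings(self, settings: pd.DataFrame) -> np.ndarray:
        """Evaluate the fitted equation at raw factor settings (rows)."""
        if self.design is None:
            raise ValueError("model carries no design; cannot code new settings")
        coded = code_settings(
            settings, self.design.factors, self.terms,
            scaling=self.scaling, center_polynomials=self.center_polynomials,
        )
        y = np.full(len(settings), self.intercept)
        for term in self.terms:
            y = y + self.coefficients[term] * coded.columns[term].to_numpy()
        return y

    def to_dict(self) -> dict:
        return {
            "response_id": self.response_id,
            "terms": self.terms,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "beta_weights": self.beta_weights,
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
            "rmse_f": self.rmse_f,
            "response_average_scale": self.response_average_scale,
            "f_whole_model": self.f_whole_model,
            "p_whole_model": self.p_whole_model,
            "effect_f": self.effect_f,
            "effect_p": self.effect_p,
            "lack_of_fit": self.lack_of_fit,
            "n": self.n,
            "k": self.k,
            "scaling": self.scaling,
        }


@dataclass
class CVResult:
    """k-fold cross-validation of a fixed term set."""

    response_id: str
    folds: dict[str, int]  # run id -> fold label (0..k-1)
    per_fold_rmse_cv: list[float]
    per_fold_train_r2: list[float]
    per_fold_train_r2_adjusted: list[float]
    per_fold_train_rmse_f: list[float]
    pooled_rmse_cv: float
    k: int
    seed: int | None


# --------------------------------------------------------------------------
# Least-squares core
# --------------------------------------------------------------------------

def _design_matrix(
    design: DesignTable, terms: list[str], run_ids: list[str],
    scaling: str, center_polynomials: bool,
) -> np.ndarray:
    coded = code_settings(
        design.settings.loc[run_ids], design.factors, terms,
        scaling=scaling, center_polynomials=center_polynomials,
    )
    X = np.column_stack([np.ones(len(run_ids))] +
                        [coded.columns[t].to_numpy() for t in terms])
    return X


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares fit; returns (coefficients, fitted values, SSE)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient regressor matrix")
    fitted = X @ beta
    resid = y - fitted
    return beta, fitted, float(resid @ resid)


def aicc(sse: float, n: int, n_terms: int, sse_floor: float = 0.0) -> float:
    """Corrected Akaike information criterion for a Gaussian linear model.

    The parameter count k' includes the intercept and the error variance
    (so k' = n_terms + 2), following the information-criterion convention of
    counting every estimated parameter.
    """
    kprime = n_terms + 2
    if n - kprime - 1 <= 0:
        return np.inf
    sse_eff = max(sse, sse_floor, 1e-300)
    return n * np.log(sse_eff / n) + 2 * kprime + 2 * kprime * (kprime + 1) / (
        n - kprime - 1
    )


def _complete_runs(y: pd.Series, design: DesignTable) -> tuple[np.ndarray, list[str]]:
    ys = y.reindex(design.run_ids)
    keep = [rid for rid in design.run_ids if pd.notna(ys[rid])]
    return ys[keep].to_numpy(dtype=float), keep


def stepwise_aicc(
    y: pd.Series,
    design: DesignTable,
    candidates: list[str] | None = None,
    scaling: str = "unit",
    center_polynomials: bool = False,
    purge: bool = True,
    lookahead: bool = True,
) -> list[str]:
    """Forward stepwise selection with minimum AICc as stopping rule.

    Starts from the intercept-only model; at each step adds the candidate
    term that most lowers AICc, and stops when no addition lowers it.  Runs
    with missing response are dropped.  Candidates that would exhaust the
    residual degrees of freedom are skipped.

    With ``purge`` (default) a backward pass then removes any term whose
    removal lowers AICc further.  Forward search can walk through a term
    that later additions make redundant (candidate columns such as x and
    x^2 are correlated over the design); the purge eliminates exactly those
    terms, keeping the result governed by the same AICc minimum.

    When no single addition lowers AICc, pairs of candidates are tried
    before stopping (``lookahead``, default on): a linear + quadratic pair
    whose contributions nearly cancel over the design can be invisible to
    one-term steps yet jointly explain the response.
    """
    if candidates is None:
        candidates = candidate_terms(design)
    yv, run_ids = _complete_runs(pd.Series(y), design)
    n = len(yv)
    sst = float(((yv - yv.mean()) ** 2).sum())
    # floor keeps AICc comparisons meaningful once an (essentially) exact
    # fit is reached: further terms then only add penalty
    floor = max(sst, 1.0) * 1e-14

    def score(terms: list[str]) -> float:
        if n - (len(terms) + 2) - 1 <= 0:
            return np.inf
        X = _design_matrix(design, terms, run_ids, scaling, center_polynomials)
        try:
            _, _, sse = _ols(X, yv)
        except np.linalg.LinAlgError:
            return np.inf
        return aicc(sse, n, len(terms), floor)

    selected: list[str] = []
    best_aicc = aicc(sst, n, 0, floor)
    remaining = list(candidates)
    while remaining:
        trial_scores = [(score(selected + [t]), t) for t in remaining]
        trial_scores = [ts for ts in trial_scores if np.isfinite(ts[0])]
        if trial_scores:
            trial_scores.sort(key=lambda t: (t[0], candidates.index(t[1])))
            best_score, best_term = trial_scores[0]
            if best_score < best_aicc:
                selected.append(best_term)
                remaining.remove(best_term)
                best_aicc = best_score
                continue
        if not lookahead or len(remaining) < 2:
            break
        pair_scores = [
            (score(selected + [a, b]), (a, b))
            for a, b in itertools.combinations(remaining, 2)
        ]
        pair_scores = [ps for ps in pair_scores if np.isfinite(ps[0])]
        if not pair_scores:
            break
        pair_scores.sort(
            key=lambda t: (t[0], candidates.index(t[1][0]),
                           candidates.index(t[1][1]))
        )
        pair_score, pair = pair_scores[0]
        if pair_score < best_aicc:
            selected.extend(pair)
            remaining.remove(pair[0])
            remaining.remove(pair[1])
            best_aicc = pair_score
        else:
            break

    if purge:
        improved = True
        while improved and selected:
            improved = False
            drop_scores = [
                (score([t for t in selected if t != cand]), cand)
                for cand in selected
            ]
            drop_scores.sort(key=lambda t: (t[0], candidates.index(t[1])))
            if drop_scores[0][0] < best_aicc:
                best_aicc = drop_scores[0][0]
                selected.remove(drop_scores[0][1])
                improved = True
    return selected


def fit_mlr(
    y: pd.Series,
    design: DesignTable,
    terms: list[str],
    response_id: str = "y",
    scaling: str = "unit",
    center_polynomials: bool = False,
) -> FittedModel:
    """Ordinary least squares fit with the full diagnostic block.

    Diagnostics follow the standard response-surface formulas: R2 as the
    model-to-total sum-of-squares ratio, adjusted R2 and RMSE_F with
    denominator n - k - 1 (k = number of coefficients apart from the
    intercept), whole-model F = MS_model / MS_error, per-effect F by
    refitting without the effect (extra sum of squares, 1 df), lack-of-fit
    F = MS_lof / MS_pure over replicate groups, and beta-weights
    b_j * sd(x_j) / sd(y).
    """
    yv, run_ids = _complete_runs(pd.Series(y), design)
    n = len(yv)
    k = len(terms)
    if n - k - 1 <= 0:
        raise ValueError(f"too few runs (n={n}) for {k} terms")
    X = _design_matrix(design, terms, run_ids, scaling, center_polynomials)
    beta, fitted, sse = _ols(X, yv)

    ybar = yv.mean()
    sst = float(((yv - ybar) ** 2).sum())
    ssm = float(((fitted - ybar) ** 2).sum())
    if sst <= 0:
        raise ValueError(f"response {response_id!r} has zero variance")
    r2 = ssm / sst
    r2_adj = 1.0 - (sse / (n - k - 1)) / (sst / (n - 1))
    rmse_f = float(np.sqrt(sse / (n - k - 1)))
    avg_scale = float(ybar - yv.min())

    if k > 0:
        mse = sse / (n - k - 1)
        if mse > 0:
            f_whole = (ssm / k) / mse
            p_whole = float(stats.f.sf(f_whole, k, n - k - 1))
        else:
            f_whole, p_whole = np.inf, 0.0
    else:
        f_whole, p_whole = np.nan, np.nan

    effect_f: dict[str, float] = {}
    effect_p: dict[str, float] = {}
    mse = sse / (n - k - 1)
    for term in terms:
        reduced = [t for t in terms if t != term]
        Xr = _design_matrix(design, reduced, run_ids, scaling, center_polynomials)
        _, _, sse_r = _ols(Xr, yv)
        if mse > 0:
            f_eff = (sse_r - sse) / mse
            effect_f[term] = float(max(f_eff, 0.0))
            effect_p[term] = float(stats.f.sf(max(f_eff, 0.0), 1, n - k - 1))
        else:
            effect_f[term] = np.inf if sse_r > sse else 0.0
            effect_p[term] = 0.0 if sse_r > sse else 1.0

    lof = _lack_of_fit(design, run_ids, yv, sse, n, k)

    coefs = {t: float(b) for t, b in zip(terms, beta[1:])}
    sdy = yv.std(ddof=1)
    betas = {
        t: float(coefs[t] * X[:, i + 1].std(ddof=1) / sdy)
        for i, t in enumerate(terms)
    }
    return FittedModel(
        response_id=response_id, terms=list(terms), intercept=float(beta[0]),
        coefficients=coefs, beta_weights=betas, r2=r2, r2_adjusted=r2_adj,
        rmse_f=rmse_f, response_average_scale=avg_scale,
        f_whole_model=float(f_whole), p_whole_model=float(p_whole),
        effect_f=effect_f, effect_p=effect_p, lack_of_fit=lof,
        n=n, k=k, scaling=scaling, center_polynomials=center_polynomials,
        run_ids=run_ids, design=design,
    )


def _lack_of_fit(
    design: DesignTable, run_ids: list[str], yv: np.ndarray,
    sse: float, n: int, k: int,
) -> dict[str, float] | None:
    """Split SSE into pure error (within replicate groups) and lack of fit."""
    present = set(run_ids)
    y_by_run = dict(zip(run_ids, yv))
    ss_pure = 0.0
    df_pure = 0
    for group in replicate_groups(design):
        members = [r for r in group if r in present]
        if len(members) < 2:
            continue
        vals = np.array([y_by_run[r] for r in members])
        ss_pure += float(((vals - vals.mean()) ** 2).sum())
        df_pure += len(members) - 1
    df_lof = (n - k - 1) - df_pure
    if df_pure == 0 or df_lof <= 0:
        return None
    ss_lof = max(sse - ss_pure, 0.0)
    ms_pure = ss_pure / df_pure
    ms_lof = ss_lof / df_lof
    if ms_pure <= 0:
        f = np.inf if ms_lof > 0 else np.nan
        p = 0.0 if ms_lof > 0 else np.nan
    else:
        f = ms_lof / ms_pure
        p = float(stats.f.sf(f, df_lof, df_pure))
    return {
        "f": float(f), "p": float(p), "ss_lof": ss_lof, "ss_pure": ss_pure,
        "df_lof": df_lof, "df_pure": df_pure,
    }


# --------------------------------------------------------------------------
# Summary table, cross-validation, profiles
# --------------------------------------------------------------------------

def effect_significance_table(
    models: list[FittedModel],
    design: DesignTable | None = None,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Variables x candidate-effects matrix of beta-weights.

    A cell holds the beta-weight when the effect was selected and its ANOVA
    p-value is <= ``p_cutoff``, and NaN otherwise (effect not selected or
    not significant) — the tabular equivalent of a significance heat map.
    """
    if design is None:
        design = models[0].design
    columns = candidate_terms(design)
    table = pd.DataFrame(
        np.nan, index=[m.response_id for m in models], columns=columns
    )
    for m in models:
        for term in m.terms:
            if m.effect_p[term] <= p_cutoff:
                table.loc[m.response_id, term] = m.beta_weights[term]
    return table


def assign_folds(
    run_ids: list[str], k: int = 4, seed: int | None = 0
) -> dict[str, int]:
    """Seeded random partition into k folds with sizes as equal as possible."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(run_ids))
    folds: dict[str, int] = {}
    for pos, idx in enumerate(order):
        folds[run_ids[idx]] = pos % k
    return folds


def kfold_cv(
    y: pd.Series,
    design: DesignTable,
    terms: list[str],
    k: int = 4,
    seed: int | None = 0,
    folds: dict[str, int] | None = None,
    response_id: str = "y",
    scaling: str = "unit",
    center_polynomials: bool = False,
) -> CVResult:
    """k-fold cross-validation of a fixed term set.

    The term set is held fixed; for each fold the model is refit on the
    other k-1 folds and RMSE_CV = sqrt(sum (y_v - y^_v)^2 / v) is computed
    over the v held-out runs without degrees-of-freedom correction.  Folds
    default to a seeded balanced random partition; a user-supplied fold
    assignment reproduces externally defined subsets.
    """
    yv, run_ids = _complete_runs(pd.Series(y), design)
    n = len(yv)
    if n < 2 * k:
        raise ValueError(f"need n >= 2k runs (n={n}, k={k})")
    if folds is None:
        folds = assign_folds(run_ids, k=k, seed=seed)
    labels = sorted(set(folds[r] for r in run_ids))
    if len(labels) != k:
        raise ValueError(f"fold assignment covers {len(labels)} folds, expected {k}")
    y_by_run = dict(zip(run_ids, yv))

    per_rmse, per_r2, per_r2a, per_rmsef = [], [], [], []
    pooled_sq = 0.0
    for lab in labels:
        test = [r for r in run_ids if folds[r] == lab]
        train = [r for r in run_ids if folds[r] != lab]
        if len(train) < len(terms) + 2:
            raise ValueError(
                f"fold {lab}: {len(train)} training runs too few for "
                f"{len(terms)} terms"
            )
        ytr = np.array([y_by_run[r] for r in train])
        Xtr = _design_matrix(design, terms, train, scaling, center_polynomials)
        beta, fitted, sse = _ols(Xtr, ytr)
        ntr, kk = len(train), len(terms)
        sst = float(((ytr - ytr.mean()) ** 2).sum())
        per_r2.append(1.0 - sse / sst if sst > 0 else np.nan)
        per_r2a.append(
            1.0 - (sse / (ntr - kk - 1)) / (sst / (ntr - 1)) if sst > 0 else np.nan
        )
        per_rmsef.append(float(np.sqrt(sse / (ntr - kk - 1))))
        Xte = _design_matrix(design, terms, test, scaling, center_polynomials)
        yte = np.array([y_by_run[r] for r in test])
        errs = yte - Xte @ beta
        pooled_sq += float(errs @ errs)
        per_rmse.append(float(np.sqrt((errs @ errs) / len(test))))
    return CVResult(
        response_id=response_id,
        folds={r: folds[r] for r in run_ids},
        per_fold_rmse_cv=per_rmse,
        per_fold_train_r2=per_r2,
        per_fold_train_r2_adjusted=per_r2a,
        per_fold_train_rmse_f=per_rmsef,
        pooled_rmse_cv=float(np.sqrt(pooled_sq / n)),
        k=k, seed=seed,
    )


def profile(
    model: FittedModel,
    factor: str,
    grid: np.ndarray,
    fixed_settings: dict[str, float],
) -> pd.DataFrame:
    """Predicted response along one factor's grid, other factors fixed.

    Evaluates the fitted equation; grid points outside the factor's design
    range are still evaluated but flagged with an extrapolation warning.
    """
    if model.design is None:
        raise ValueError("model carries no design")
    spec = model.design.factor(factor)
    grid = np.asarray(grid, dtype=float)
    if spec.kind == "continuous" and (
        grid.min() < spec.low or grid.max() > spec.high
    ):
        warnings.warn(
            f"grid for {factor!r} extends outside [{spec.low}, {spec.high}]; "
            "predictions are extrapolations", stacklevel=2,
        )
    rows = []
    for g in grid:
        row = dict(fixed_settings)
        row[factor] = float(g)
        rows.append(row)
    names = [f.name for f in model.design.factors]
    settings = pd.DataFrame(rows)[names]
    yhat = model.predict_settings(settings)
    return pd.DataFrame({factor: grid, "prediction": yhat})


def fit_all(
    matrix,
    design: DesignTable,
    scaling: str = "unit",
    center_polynomials: bool = False,
) -> list[FittedModel]:
    """Stepwise-select and fit one model per variable of an abundance matrix."""
    models = []
    for var in matrix.variables:
        y = matrix.data.loc[var]
        y.index = matrix.run_ids
        terms = stepwise_aicc(
            y, design, scaling=scaling, center_polynomials=center_polynomials
        )
        models.append(
            fit_mlr(y, design, terms, response_id=var, scaling=scaling,
                    center_polynomials=center_polynomials)
        )
    return models
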