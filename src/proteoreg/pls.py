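"""Multi-response partial least squares regression (NIPALS).

PLSR projects predictors and responses onto shared latent factors that
maximize covariance.  Both blocks are autoscaled (centered, unit variance per
column) before fitting.  The number of latent factors is chosen by
leave-one-out PRESS (prediction error sum of squares) coupled to van der
Voet T2 randomization tests: the selected model is the most parsimonious one
whose predictions are not significantly worse than the PRESS-minimal model.
Variable importance in projection (VIP, Wold's formulation) summarizes each
predictor's contribution to the explained response variance across factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLSModel",
    "FactorSelection",
    "nipals_pls",
    "loo_press",
    "van_der_voet_select",
    "select_n_factors",
    "vip",
    "pls_coefficient_signs",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass
class PLSModel:
    """Fitted NIPALS PLS model on autoscaled blocks.

    W, P (p x A): X-weights and X-loadings; Q (q x A): Y-loadings;
    T (n x A): scores.  ``var_explained`` (A x q) holds per-factor fractions
    of each response's variance; ``coef`` (p x q) is the regression matrix on
    the autoscaled scale.
    """

    n_factors: int
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    var_explained: np.ndarray
    coef: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray

    @property
    def n_predictors(self) -> int:
        return self.W.shape[0]

    @property
    def n_responses(self) -> int:
        return self.Q.shape[0]

    def cumulative_var_explained(self) -> np.ndarray:
        """Per-response cumulative fraction of variance explained (length q)."""
        return self.var_explained.sum(axis=0)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Predict responses on the original scale."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        Xs = (X_new - self.x_mean) / self.x_std
        return Xs @ self.coef * self.y_std + self.y_mean


@dataclass
class FactorSelection:
    """PRESS curve and the van der Voet choice of latent-factor count."""

    press: np.ndarray  # PRESS per candidate A (1..A_max)
    p_values: np.ndarray  # vs the PRESS-minimal model
    a_min_press: int
    chosen: int
    alpha: float
    seed: int | None


def _autoscale(M: np.ndarray, label: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    mean = M.mean(axis=0)
    std = M.std(axis=0, ddof=1)
    if np.any(std == 0):
        bad = list(np.flatnonzero(std == 0))
        raise ValueError(f"zero-variance {label} column(s) at index {bad}")
    return (M - mean) / std, mean, std


def nipals_pls(X: np.ndarray, Y: np.ndarray, A: int) -> PLSModel:
    """Fit an A-factor PLS model by NIPALS with deflation.

    X (n x p) and Y (n x q) are autoscaled internally and must be complete.
    The single-response case short-circuits each factor's weight vector to
    the closed form w proportional to X'y.
    """
    Xs, x_mean, x_std = _autoscale(X, "X")
    Ys, y_mean, y_std = _autoscale(Y, "Y")
    n, p = Xs.shape
    q = Ys.shape[1]
    max_a = min(n - 1, p)
    if not 1 <= A <= max_a:
        raise ValueError(f"A={A} outside [1, min(n-1, p)={max_a}]")

    ss_tot = (Ys**2).sum(axis=0)  # = n-1 per autoscaled column
    Xd, Yd = Xs.copy(), Ys.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((q, A))
    T = np.zeros((n, A))
    var_explained = np.zeros((A, q))

    for a in range(A):
        if q == 1:
            w = Xd.T @ Yd[:, 0]
            norm = np.linalg.norm(w)
            if norm < 1e-300:
                raise ValueError(f"X block exhausted at factor {a + 1}")
            w /= norm
            t = Xd @ w
        else:
            u = Yd[:, int(np.argmax((Yd**2).sum(axis=0)))].copy()
            w = np.zeros(p)
            for _ in range(_NIPALS_MAX_ITER):
                w_new = Xd.T @ u
                norm = np.linalg.norm(w_new)
                if norm < 1e-300:
                    raise ValueError(f"X block exhausted at factor {a + 1}")
                w_new /= norm
                t = Xd @ w_new
                tt = t @ t
                if tt < 1e-300:
                    raise ValueError(f"degenerate score at factor {a + 1}")
                qv = Yd.T @ t / tt
                qq = qv @ qv
                if qq < 1e-300:
                    break  # Y block exhausted; keep current direction
                u = Yd @ qv / qq
                if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                    w = w_new
                    break
                w = w_new
            t = Xd @ w
        tt = t @ t
        qv = Yd.T @ t / tt
        pv = Xd.T @ t / tt
        Xd = Xd - np.outer(t, pv)
        Yd = Yd - np.outer(t, qv)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pv, qv, t
        var_explained[a] = tt * qv**2 / ss_tot

    # B = W (P'W)^-1 Q'  on the autoscaled scale
    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSModel(
        n_factors=A, W=W, P=P, Q=Q, T=T, var_explained=var_explained,
        coef=coef, x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
    )


def loo_press(
    X: np.ndarray, Y: np.ndarray, A_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out PRESS per candidate factor count.

    Returns ``(press, sq_residuals)`` where press[a-1] = PRESS(a) and
    sq_residuals[i, a-1] is run i's squared prediction error (summed over
    responses, original scale) under the a-factor model refit without run i.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out PRESS needs >=3 runs")
    if A_max >= n:
        raise ValueError("A_max must be < number of runs")
    sq = np.zeros((n, A_max))
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, Ytr = X[keep], Y[keep]
        for a in range(1, A_max + 1):
            model = nipals_pls(Xtr, Ytr, a)
            err = Y[i] - model.predict(X[i])[0]
            sq[i, a - 1] = float(err @ err)
    return sq.sum(axis=0), sq


_EXHAUSTIVE_LIMIT = 14  # enumerate all 2^n sign assignments up to this n


def van_der_voet_select(
    sq_residuals: np.ndarray,
    alpha: float = 0.10,
    seed: int | None = 0,
    n_draws: int = 10_000,
) -> FactorSelection:
    """Choose the latent-factor count by van der Voet randomization tests.

    ``sq_residuals`` is the (n x A_max) matrix of per-run squared prediction
    errors from :func:`loo_press`.  Each candidate A is compared to the
    PRESS-minimal model by sign-flip resampling of the paired residual
    differences (exhaustive enumeration when n <= 14, otherwise ``n_draws``
    seeded draws); the chosen A* is the smallest candidate whose p-value
    exceeds ``alpha``.
    """
    sq = np.asarray(sq_residuals, dtype=float)
    n, a_max = sq.shape
    press = sq.sum(axis=0)
    a_min = int(np.argmin(press))
    p_values = np.ones(a_max)
    tol = 1e-12
    for a in range(a_max):
        if a == a_min:
            p_values[a] = 1.0
            continue
        d = sq[:, a] - sq[:, a_min]
        observed = abs(d.sum())
        if n <= _EXHAUSTIVE_LIMIT:
            codes = np.arange(2**n, dtype=np.int64)
            signs = ((codes[:, None] >> np.arange(n)) & 1) * 2.0 - 1.0
            stats_null = np.abs(signs @ d)
            p_values[a] = float(np.mean(stats_null >= observed - tol))
        else:
            rng = np.random.default_rng(seed)
            signs = rng.choice([-1.0, 1.0], size=(n_draws, n))
            stats_null = np.abs(signs @ d)
            p_values[a] = float(np.mean(stats_null >= observed - tol))
    candidates = np.flatnonzero(p_values > alpha)
    chosen = int(candidates[0]) + 1 if candidates.size else a_min + 1
    return FactorSelection(
        press=press, p_values=p_values, a_min_press=a_min + 1,
        chosen=chosen, alpha=alpha, seed=seed,
    )


def select_n_factors(
    X: np.ndarray, Y: np.ndarray, A_max: int,
    alpha: float = 0.10, seed: int | None = 0,
) -> FactorSelection:
    """Convenience wrapper: LOO PRESS followed by van der Voet selection."""
    _, sq = loo_press(X, Y, A_max)
    return van_der_voet_select(sq, alpha=alpha, seed=seed)


def vip(model: PLSModel) -> np.ndarray:
    """Wold's variable importance in projection per predictor.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )
    where SSY_a is the response variance explained by factor a (summed over
    responses).  Satisfies sum_j VIP_j^2 = p.
    """
    ssy = model.var_explained.sum(axis=1)  # per factor, summed over responses
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    w_norm2 = (model.W**2) / (model.W**2).sum(axis=0)
    p = model.n_predictors
    return np.sqrt(p * (w_norm2 @ ssy) / total)


def pls_coefficient_signs(model: PLSModel) -> np.ndarray:
    """Sign (-1, 0, +1) of the PLS coefficients per predictor x response."""
    return np.sign(model.coef).astype(int)
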