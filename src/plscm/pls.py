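"""Univariate-response partial least squares by NIPALS, uncentered by default.

The variables here are all on the same percentage scale, so the model is fit
with *no preprocessing*: neither centering nor autoscaling.  Sums of squares
are then taken about the origin, and the first latent variable (LV) absorbs
the direction from the origin to the vector of variable means — typically
more than 90% of the X-block sum of squares in immunophenotype matrices.
Autoscaling is deliberately unavailable: it would inflate noise variables to
the same magnitude as the discriminative ones.  Centering remains available
as a flag, mainly so the fit can be cross-checked against conventional PLS
implementations.

Each LV is a linear combination of the observed variables; the model keeps
the weight, score and loading matrices plus a per-LV explained-variance
ledger for the X and y blocks (partial and accumulated percentages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    ConvergenceError,
    DegenerateDirectionError,
    UndefinedVarianceError,
)

__all__ = [
    "VarianceLedger",
    "PLSModel",
    "fit_pls",
    "predict",
    "explained_variance",
    "select_n_components",
]

# NIPALS iteration control.  With a univariate response the inner loop
# converges in a single pass; the tolerance is kept for safety.
_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass(frozen=True)
class VarianceLedger:
    """Per-LV explained variance (%) for the X and y blocks.

    ``*_partial[a]`` is the share of block sum of squares removed by
    component ``a`` alone; ``*_total[a]`` is the running sum.  Sums of
    squares are about the origin when the model is uncentered, about the
    mean otherwise.
    """

    x_partial: np.ndarray
    x_total: np.ndarray
    y_partial: np.ndarray
    y_total: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x_partial", "x_total", "y_partial", "y_total"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))

    @property
    def n_components(self) -> int:
        return len(self.x_partial)

    def as_table(self) -> "list[dict]":
        """Rows in the layout of a per-LV variance table (partial/total, X/y)."""
        return [
            {
                "latent_variable": a + 1,
                "x_partial": float(self.x_partial[a]),
                "x_total": float(self.x_total[a]),
                "y_partial": float(self.y_partial[a]),
                "y_total": float(self.y_total[a]),
            }
            for a in range(self.n_components)
        ]


@dataclass
class PLSModel:
    """Fitted PLS model with A components.

    Attributes
    ----------
    weights : (p, A) array
        Unit-norm NIPALS weight vectors, one column per component.
    x_scores : (n, A) array
        Score vectors ``T``; mutually orthogonal.
    x_loadings : (p, A) array
        X-block loadings ``P``.
    y_loadings : (A,) array
        Regression of the (deflated) response on each score.
    coefficients : (p,) array
        Composite regression vector ``b = W (P'W)^-1 q`` mapping the raw
        (or centered) X to the calculated response.
    centering_enabled : bool
        False by default: all inner products are about the origin.
    column_means, y_mean
        Stored only when centering is enabled.
    variance_ledger : VarianceLedger
        Per-LV explained variance for both blocks.
    """

    n_components: int
    weights: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    centering_enabled: bool
    column_means: np.ndarray
    y_mean: float
    variance_ledger: VarianceLedger

    @property
    def n_variables(self) -> int:
        return len(self.coefficients)


def _as_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(y) != X.shape[0]:
        raise ValueError(f"y length {len(y)} != X rows {X.shape[0]}")
    return X, y


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    center: bool = False,
) -> PLSModel:
    """Fit a NIPALS PLS model with a single (binary-coded) response.

    Parameters
    ----------
    X
        Subjects x variables matrix (no missing values).
    y
        Response vector; for class modeling a 0/1 code, but any numeric
        response is accepted.
    n_components
        Number of latent variables A, ``1 <= A <= min(n, p)``.
    center
        When False (default) no preprocessing is applied and all sums of
        squares are about the origin.  When True, X columns and y are
        mean-centered first (the conventional PLS1 setting).

    Returns
    -------
    PLSModel
        Deterministic fit; sign indeterminacy is resolved by flipping each
        component so its largest-magnitude weight entry is positive.
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    A = int(n_components)
    if A < 1 or A > min(n, p):
        raise ValueError(f"n_components must be in [1, {min(n, p)}], got {A}")
    if np.unique(y).size < 2:
        raise ValueError("response must take at least two distinct values")

    if center:
        col_means = X.mean(axis=0)
        y_mean = float(y.mean())
        Xr = X - col_means
        yr = y - y_mean
    else:
        col_means = np.zeros(p)
        y_mean = 0.0
        Xr = X.copy()
        yr = y.copy()

    ssx_tot = float(np.sum(Xr * Xr))
    ssy_tot = float(np.sum(yr * yr))
    if ssx_tot == 0.0:
        raise DegenerateDirectionError("X block has zero sum of squares")
    if ssy_tot == 0.0:
        raise UndefinedVarianceError("response has zero sum of squares")

    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    x_part = np.zeros(A)
    y_part = np.zeros(A)

    for a in range(A):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= 1e-300 or not np.isfinite(nw):
            raise DegenerateDirectionError(
                f"component {a + 1}: weight direction has zero norm "
                "(X residual carries no covariance with the response)"
            )
        w /= nw
        # univariate-y NIPALS: iterate w <- X'y-style updates until stable
        for _ in range(_NIPALS_MAX_ITER):
            t = Xr @ w
            tt = float(t @ t)
            if tt <= 1e-300:
                raise DegenerateDirectionError(
                    f"component {a + 1}: score vector has zero norm"
                )
            c = float(yr @ t) / tt
            # refreshed weight from the response-projected scores
            w_new = Xr.T @ yr * c
            n_new = np.linalg.norm(w_new)
            if n_new <= 1e-300:
                raise DegenerateDirectionError(
                    f"component {a + 1}: degenerate weight update"
                )
            w_new /= n_new
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        else:
            raise ConvergenceError(
                f"component {a + 1} did not converge in {_NIPALS_MAX_ITER} iterations"
            )

        # sign convention: largest-|w| entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xr @ w
        tt = float(t @ t)
        p_a = Xr.T @ t / tt
        q_a = float(yr @ t) / tt

        W[:, a] = w
        T[:, a] = t
        P[:, a] = p_a
        q[a] = q_a

        # deflation removes rank-one pieces whose SS are exactly the
        # per-component explained sums of squares
        x_part[a] = tt * float(p_a @ p_a) / ssx_tot * 100.0
        y_part[a] = q_a * q_a * tt / ssy_tot * 100.0
        Xr = Xr - np.outer(t, p_a)
        yr = yr - t * q_a

    # composite coefficients: T = X W (P'W)^-1, yhat = T q = X b
    R = W @ np.linalg.solve(P.T @ W, np.eye(A))
    b = R @ q

    ledger = VarianceLedger(
        x_partial=x_part,
        x_total=np.cumsum(x_part),
        y_partial=y_part,
        y_total=np.cumsum(y_part),
    )
    return PLSModel(
        n_components=A,
        weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=q,
        coefficients=b,
        centering_enabled=bool(center),
        column_means=col_means,
        y_mean=y_mean,
        variance_ledger=ledger,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Calculated response for new rows: ``X b`` (plus intercept if centered)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_variables:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_variables}"
        )
    if model.centering_enabled:
        return model.y_mean + (X_new - model.column_means) @ model.coefficients
    return X_new @ model.coefficients


def transform(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Project new rows onto the model's score space: ``T_new = X R``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_variables:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_variables}"
        )
    R = model.weights @ np.linalg.solve(
        model.x_loadings.T @ model.weights, np.eye(model.n_components)
    )
    if model.centering_enabled:
        return (X_new - model.column_means) @ R
    return X_new @ R


def explained_variance(model: PLSModel, X: np.ndarray, y: np.ndarray) -> VarianceLedger:
    """Recompute the per-LV variance ledger from residual sums of squares.

    Equivalent to the ledger stored on the model (asserted in tests); kept
    as a separate entry point so the decomposition can be audited against
    any (X, y) the model was fitted on.
    """
    X, y = _as_xy(X, y)
    if model.centering_enabled:
        Xr = X - model.column_means
        yr = y - model.y_mean
    else:
        Xr = X.copy()
        yr = y.copy()
    ssx_tot = float(np.sum(Xr * Xr))
    ssy_tot = float(np.sum(yr * yr))
    if ssx_tot == 0.0 or ssy_tot == 0.0:
        raise UndefinedVarianceError("zero total sum of squares")

    A = model.n_components
    x_part = np.zeros(A)
    y_part = np.zeros(A)
    ssx_prev, ssy_prev = ssx_tot, ssy_tot
    for a in range(A):
        t = model.x_scores[:, a]
        Xr = Xr - np.outer(t, model.x_loadings[:, a])
        yr = yr - t * model.y_loadings[a]
        ssx_now = float(np.sum(Xr * Xr))
        ssy_now = float(np.sum(yr * yr))
        x_part[a] = (ssx_prev - ssx_now) / ssx_tot * 100.0
        y_part[a] = (ssy_prev - ssy_now) / ssy_tot * 100.0
        ssx_prev, ssy_prev = ssx_now, ssy_now

    return VarianceLedger(
        x_partial=x_part,
        x_total=np.cumsum(x_part),
        y_partial=y_part,
        y_total=np.cumsum(y_part),
    )


def _fit_max_feasible(X, y, A_max: int, center: bool) -> PLSModel:
    """Fit with the largest A <= A_max for which no component degenerates
    (a response explained exactly by fewer components leaves nothing for
    the rest — a natural stopping point, not an error, during selection)."""
    for A in range(A_max, 0, -1):
        try:
            return fit_pls(X, y, A, center=center)
        except DegenerateDirectionError:
            if A == 1:
                raise
    raise AssertionError("unreachable")


def knee_from_partials(y_partial: np.ndarray, knee_points: float = 5.0) -> int:
    """Knee rule: keep the components before the first marginal y-block
    contribution under ``knee_points`` percentage points (at least 1)."""
    y_partial = np.asarray(y_partial, dtype=float)
    for a, part in enumerate(y_partial):
        if part < knee_points:
            return max(1, a)
    return len(y_partial)


def select_n_components(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int,
    criterion: str = "explained_variance_knee",
    center: bool = False,
    knee_points: float = 5.0,
) -> int:
    """Choose the number of latent variables.

    ``explained_variance_knee`` fits A_max components and returns the
    largest A before the first component whose marginal y-block explained
    variance falls below ``knee_points`` percentage points (never below 1).
    ``loo_cv`` returns the A in 1..A_max minimizing leave-one-out squared
    prediction error.
    """
    X, y = _as_xy(X, y)
    A_max = int(A_max)
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    A_max = min(A_max, min(X.shape))

    if criterion == "explained_variance_knee":
        model = _fit_max_feasible(X, y, A_max, center)
        return knee_from_partials(model.variance_ledger.y_partial, knee_points)

    if criterion == "loo_cv":
        n = X.shape[0]
        press = np.zeros(A_max)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            Xi, yi = X[mask], y[mask]
            a_cap = min(A_max, min(Xi.shape))
            model = _fit_max_feasible(Xi, yi, a_cap, center)
            a_cap = model.n_components
            # predictions with the first a components, for every a, from one fit
            T_new = transform(model, X[i : i + 1])[0]
            cum = np.cumsum(T_new * model.y_loadings)
            base = model.y_mean if model.centering_enabled else 0.0
            for a in range(A_max):
                pred = base + cum[min(a, a_cap - 1)]
                press[a] += (pred - y[i]) ** 2
        # smallest A whose PRESS is within numerical tolerance of the best;
        # avoids inflating A on error differences at machine precision
        best = press.min()
        ok = press <= best * (1 + 1e-10) + 1e-12
        return int(np.argmax(ok)) + 1

    raise ValueError(f"unknown criterion {criterion!r}")
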