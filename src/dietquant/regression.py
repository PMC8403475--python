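"""Transformation-free linear regression between compositions.

Both the predictor ``X`` (n x D_x, e.g. expected biomass fractions) and the
outcome ``Y`` (n x D_y, e.g. relative read abundances) live on the unit
simplex. The model is

    E[y_i] = x_i B,

where ``B`` is a D_x x D_y *transition matrix*: entries in [0, 1] and unit
row sums, so predictions stay on the simplex without any log-ratio
transform. Entry ``B[j, k]`` reads directly as the share of predictor
component ``j`` that ends up in outcome component ``k``; a diagonal near 1
means the outcome mirrors the predictor.

``B`` is estimated by minimising the Kullback–Leibler divergence

    D(B) = sum_i sum_k y_ik log(y_ik / mu_ik),  mu_i = x_i B,  0 log 0 = 0,

with an EM-style multiplicative update (multiply by the gradient-weighted
responsibilities, renormalise rows) that preserves the constraints and
never increases the objective. Inference is nonparametric: a permutation
test for overall linear dependence, percentile bootstrap intervals for the
coefficients, and leave-one-out cross-validation for out-of-sample fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TableValidationError, validate_composition

# floor applied to model means before dividing/logging; guards mu=0 cells
# that carry positive observed mass
_MU_FLOOR = 1e-12


def _as_matrix(m, name: str) -> tuple[np.ndarray, list, list]:
    """Coerce a DataFrame/array to a float ndarray plus row/column labels."""
    if isinstance(m, pd.DataFrame):
        values = m.to_numpy(dtype=float)
        rows, cols = list(m.index), list(m.columns)
    else:
        values = np.asarray(m, dtype=float)
        if values.ndim != 2:
            raise TableValidationError(f"{name} must be 2-D")
        rows = list(range(values.shape[0]))
        cols = list(range(values.shape[1]))
    if values.size == 0:
        raise TableValidationError(f"{name} is empty")
    if (values < 0).any():
        raise TableValidationError(f"{name} has negative entries")
    sums = values.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        i = int(np.argmax(np.abs(sums - 1.0)))
        raise TableValidationError(
            f"{name} row {rows[i]!r} sums to {sums[i]:.6g}; rows must lie on the simplex"
        )
    return values / sums[:, None], rows, cols


def kl_divergence(Y: np.ndarray, M: np.ndarray) -> float:
    """KL divergence sum_i sum_k y log(y/mu) with the 0*log(0)=0 convention."""
    M = np.maximum(M, _MU_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(Y > 0, Y * np.log(np.where(Y > 0, Y, 1.0) / M), 0.0)
    return float(terms.sum())


@dataclass
class RegressionFit:
    """Result of fitting the compositional regression."""

    B: pd.DataFrame
    objective: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray
    unidentified_rows: list = field(default_factory=list)

    def as_arrays(self) -> tuple[np.ndarray, float]:
        return self.B.to_numpy(), self.objective


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float
    n_perm: int


@dataclass
class BootstrapResult:
    lower: pd.DataFrame
    upper: pd.DataFrame
    level: float
    n_boot: int
    n_degenerate_redraws: int
    seed: int | None


@dataclass
class CVResult:
    predicted: pd.DataFrame
    observed: pd.DataFrame
    euclidean_error: pd.Series
    abs_error: pd.DataFrame
    rmse: float


def _em_fit_batch(
    Yb: np.ndarray,
    Xb: np.ndarray,
    tol: float,
    max_iter: int,
    B0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the multiplicative updates on a batch of problems at once.

    ``Yb`` (batch, n, D_y) and ``Xb`` (batch, n, D_x) hold one regression
    problem per batch entry; all start from ``B0``. Used to vectorise
    permutation, bootstrap and leave-one-out refits, which share shapes.
    Returns the fitted B stack and final objectives.
    """
    n_batch, _, d_x = Xb.shape
    d_y = Yb.shape[2]
    B = np.broadcast_to(B0, (n_batch, d_x, d_y)).copy()
    pos = Yb > 0
    ylogy = np.where(pos, Yb * np.log(np.where(pos, Yb, 1.0)), 0.0).sum(axis=(1, 2))
    Xt = np.swapaxes(Xb, 1, 2)

    def objectives(Bm: np.ndarray) -> np.ndarray:
        M = np.maximum(Xb @ Bm, _MU_FLOOR)
        return np.maximum(0.0, ylogy - np.where(pos, Yb * np.log(M), 0.0).sum(axis=(1, 2)))

    obj = objectives(B)
    active = np.ones(n_batch, dtype=bool)
    for _ in range(max_iter):
        M = np.maximum(Xb @ B, _MU_FLOOR)
        cand = B * (Xt @ np.where(pos, Yb / M, 0.0))
        rows = cand.sum(axis=2, keepdims=True)
        cand = np.where(rows > 0, cand / np.where(rows > 0, rows, 1.0), B)
        new_obj = objectives(cand)
        improved = new_obj <= obj
        accept = active & improved
        B[accept] = cand[accept]
        done = active & (~improved | (obj - new_obj < tol))
        obj = np.where(accept, new_obj, obj)
        active &= ~done
        if not active.any():
            break
    return B, obj


def _em_fit(
    Y: np.ndarray,
    X: np.ndarray,
    tol: float,
    max_iter: int,
    B0: np.ndarray,
) -> tuple[np.ndarray, list[float], bool]:
    B = B0.copy()
    pos = Y > 0
    ylogy = float(np.where(pos, Y * np.log(np.where(pos, Y, 1.0)), 0.0).sum())

    def objective(Bm: np.ndarray) -> float:
        M = np.maximum(X @ Bm, _MU_FLOOR)
        # clamp away float negatives: KL is non-negative by definition
        return max(0.0, ylogy - float(np.where(pos, Y * np.log(M), 0.0).sum()))

    trace = [objective(B)]
    converged = False
    for _ in range(max_iter):
        M = np.maximum(X @ B, _MU_FLOOR)
        R = np.where(pos, Y / M, 0.0)
        cand = B * (X.T @ R)
        rows = cand.sum(axis=1, keepdims=True)
        # a predictor absent from every sample gives a zero update row;
        # leave that row at its current (uninformed) value
        cand = np.where(rows > 0, cand / np.where(rows > 0, rows, 1.0), B)
        obj = objective(cand)
        if obj <= trace[-1]:
            B = cand
            trace.append(obj)
            if trace[-2] - trace[-1] < tol:
                converged = True
                break
        else:
            # numerically stalled at the optimum; keep the better iterate
            converged = True
            break
    return B, trace, converged


def fit(
    Y,
    X,
    *,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    init: np.ndarray | None = None,
) -> RegressionFit:
    """Estimate the row-stochastic transition matrix ``B`` for ``Y ~ X B``.

    Parameters
    ----------
    Y, X
        Compositions with matching row order (samples); DataFrames keep
        their taxon labels on ``B``.
    tol
        Stop when the KL objective improves by less than this.
    max_iter
        Iteration cap for the multiplicative updates.
    init
        Optional starting ``B`` (defaults to uniform rows 1/D_y, which is
        deterministic and interior so no coefficient is pinned at zero).
    """
    Ya, y_rows, y_cols = _as_matrix(Y, "Y")
    Xa, x_rows, x_cols = _as_matrix(X, "X")
    if Ya.shape[0] != Xa.shape[0]:
        raise TableValidationError(
            f"Y has {Ya.shape[0]} rows but X has {Xa.shape[0]}"
        )
    n, d_x = Xa.shape
    d_y = Ya.shape[1]
    if n < d_x:
        warnings.warn(
            f"n={n} samples < {d_x} predictor components; B may be unidentifiable",
            stacklevel=2,
        )
    if init is None:
        B0 = np.full((d_x, d_y), 1.0 / d_y)
    else:
        B0 = np.asarray(init, dtype=float)
        if B0.shape != (d_x, d_y):
            raise TableValidationError(f"init must have shape {(d_x, d_y)}")
        B0 = B0 / B0.sum(axis=1, keepdims=True)
    unidentified = [x_cols[j] for j in np.flatnonzero(Xa.sum(axis=0) == 0)]
    B, trace, converged = _em_fit(Ya, Xa, tol, max_iter, B0)
    return RegressionFit(
        B=pd.DataFrame(B, index=x_cols, columns=y_cols),
        objective=trace[-1],
        n_iter=len(trace) - 1,
        converged=converged,
        objective_trace=np.asarray(trace),
        unidentified_rows=unidentified,
    )


def predict(B, X) -> pd.DataFrame:
    """Predicted outcome compositions ``x_i B`` (rows close on the simplex)."""
    Xa, x_rows, x_cols = _as_matrix(X, "X")
    Ba = B.to_numpy(dtype=float) if isinstance(B, pd.DataFrame) else np.asarray(B, float)
    cols = list(B.columns) if isinstance(B, pd.DataFrame) else list(range(Ba.shape[1]))
    if Ba.shape[0] != Xa.shape[1]:
        raise TableValidationError(
            f"B has {Ba.shape[0]} rows but X has {Xa.shape[1]} components"
        )
    return pd.DataFrame(Xa @ Ba, index=x_rows, columns=cols)


def independence_divergence(Y) -> float:
    """KL divergence of the best sample-independent model (column means)."""
    Ya, _, _ = _as_matrix(Y, "Y")
    M0 = np.tile(Ya.mean(axis=0), (Ya.shape[0], 1))
    return kl_divergence(Ya, M0)


def permutation_test(
    Y,
    X,
    *,
    n_perm: int = 1000,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> PermutationResult:
    """Permutation test for overall linear dependence of ``Y`` on ``X``.

    The statistic is the divergence reduction T = D0 - D(B_hat), where D0
    is the KL divergence of the independence model (every sample predicted
    by the column-mean composition of Y). Permutations shuffle the row
    order of X against a fixed Y and refit; ties count as >= so the
    p-value (1 + #{T_perm >= T_obs}) / (1 + n_perm) is conservative.
    """
    Ya, _, _ = _as_matrix(Y, "Y")
    Xa, _, _ = _as_matrix(X, "X")
    n = Ya.shape[0]
    if n != Xa.shape[0]:
        raise TableValidationError("Y and X need the same number of rows")
    if n < 3:
        raise TableValidationError("permutation test needs at least 3 samples")
    rng = np.random.default_rng(seed)
    d_y = Ya.shape[1]
    B0 = np.full((Xa.shape[1], d_y), 1.0 / d_y)
    d_indep = independence_divergence(Y)

    Xb = np.empty((n_perm + 1, n, Xa.shape[1]))
    Xb[0] = Xa
    for b in range(n_perm):
        Xb[b + 1] = Xa[rng.permutation(n)]
    Yb = np.broadcast_to(Ya, (n_perm + 1, n, d_y))
    _, objs = _em_fit_batch(Yb, Xb, tol, max_iter, B0)
    stats = d_indep - objs
    observed = float(stats[0])
    permuted = stats[1:]
    p = (1.0 + np.count_nonzero(permuted >= observed)) / (1.0 + n_perm)
    return PermutationResult(observed=observed, permuted=permuted, p_value=p, n_perm=n_perm)


def bootstrap_ci(
    Y,
    X,
    *,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> BootstrapResult:
    """Percentile bootstrap intervals for every coefficient of ``B``.

    Samples (rows) are resampled with replacement and the model refitted.
    Resamples in which a predictor component vanishes everywhere leave the
    corresponding B row unidentified; such draws are redrawn and counted.
    """
    Ya, _, y_cols = _as_matrix(Y, "Y")
    Xa, _, x_cols = _as_matrix(X, "X")
    if Ya.shape[0] != Xa.shape[0]:
        raise TableValidationError("Y and X need the same number of rows")
    n = Ya.shape[0]
    rng = np.random.default_rng(seed)
    d_y = Ya.shape[1]
    B0 = np.full((Xa.shape[1], d_y), 1.0 / d_y)
    identified = Xa.sum(axis=0) > 0
    redraws = 0
    indices = np.empty((n_boot, n), dtype=np.intp)
    for b in range(n_boot):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            cols_ok = (Xa[idx].sum(axis=0) > 0) | ~identified
            if cols_ok.all():
                break
            redraws += 1
        indices[b] = idx
    fits, _ = _em_fit_batch(Ya[indices], Xa[indices], tol, max_iter, B0)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(fits, alpha, axis=0)
    hi = np.quantile(fits, 1.0 - alpha, axis=0)
    return BootstrapResult(
        lower=pd.DataFrame(lo, index=x_cols, columns=y_cols),
        upper=pd.DataFrame(hi, index=x_cols, columns=y_cols),
        level=level,
        n_boot=n_boot,
        n_degenerate_redraws=redraws,
        seed=seed,
    )


def loocv(Y, X, *, tol: float = 1e-8, max_iter: int = 10_000) -> CVResult:
    """Leave-one-out cross-validation of the compositional regression.

    Each sample is predicted from a model fitted without it; the output
    table is suitable for a predicted-vs-observed 1:1 plot. RMSE is the
    root mean square over all sample x taxon cells.
    """
    Ya, y_rows, y_cols = _as_matrix(Y, "Y")
    Xa, _, _ = _as_matrix(X, "X")
    if Ya.shape[0] != Xa.shape[0]:
        raise TableValidationError("Y and X need the same number of rows")
    n, d_x = Xa.shape
    if n - 1 < d_x:
        warnings.warn(
            "held-out fits have fewer samples than predictor components; "
            "LOOCV predictions may be under-determined",
            stacklevel=2,
        )
    B0 = np.full((d_x, Ya.shape[1]), 1.0 / Ya.shape[1])
    keep = np.array([[j for j in range(n) if j != i] for i in range(n)], dtype=np.intp)
    fits, _ = _em_fit_batch(Ya[keep], Xa[keep], tol, max_iter, B0)
    preds = np.einsum("ij,ijk->ik", Xa, fits)
    predicted = pd.DataFrame(preds, index=y_rows, columns=y_cols)
    observed = pd.DataFrame(Ya, index=y_rows, columns=y_cols)
    diff = preds - Ya
    return CVResult(
        predicted=predicted,
        observed=observed,
        euclidean_error=pd.Series(np.linalg.norm(diff, axis=1), index=y_rows),
        abs_error=pd.DataFrame(np.abs(diff), index=y_rows, columns=y_cols),
        rmse=float(np.sqrt(np.mean(diff**2))),
    )


def validate_transition_matrix(B: pd.DataFrame, atol: float = 1e-9) -> None:
    """Raise unless ``B`` has entries in [0, 1] and unit row sums."""
    values = B.to_numpy(dtype=float)
    if (values < -atol).any() or (values > 1 + atol).any():
        raise TableValidationError("transition matrix entries outside [0, 1]")
    if np.any(np.abs(values.sum(axis=1) - 1.0) > atol):
        raise TableValidationError("transition matrix rows must sum to 1")
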