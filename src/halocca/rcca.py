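"""Regularized canonical correlation analysis (RCCA).

Canonical correlation analysis finds paired linear combinations — canonical
variates — of two variable sets (here: environmental variables and community
features) that are maximally correlated.  With few samples and many, often
collinear, features the within-set correlation matrices are singular; ridge
regularization shrinks them toward the identity, ``R + λI``, which keeps the
problem well posed while staying on the unit-free correlation scale.

The fit solves the symmetric eigenproblem

    (Rxx + λx I)^(-1/2) Rxy (Ryy + λy I)^(-1) Ryx (Rxx + λx I)^(-1/2)

whose eigenvectors give the environmental weights; feature weights follow as
``(Ryy + λy I)^(-1) Ryx w_x`` (normalized).  Reported canonical correlations
are the empirical Pearson correlations of the paired variates, which under
regularization can differ slightly from the eigenvalue square roots.

Structure correlations — the Pearson correlation between each original
variable and a canonical variate — are the coordinates of the correlation
circle biplot; variables whose first two squared structure correlations sum
to less than the inner-circle radius squared (default 0.5² = 25% variance
explained) are flagged as dimmed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AbundanceMatrix, EnvTable

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "RCCAResult",
    "CVGrid",
    "standardize_columns",
    "drop_constant_columns",
    "rcca_fit",
    "loo_cv_select",
    "variable_variate_correlation",
    "variance_explained",
    "dimming_mask",
    "biplot_data",
    "fit_env_features",
]

#: Default one-dimensional ridge grid; the CV search uses its Cartesian square.
DEFAULT_LAMBDA_GRID = (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 0.5, 1.0)

_EIG_FLOOR = -1e-8


@dataclass
class RCCAResult:
    """Fitted RCCA: correlations, weights, variates and biplot ingredients.

    ``x_*`` refers to the environmental set, ``y_*`` to the feature set.
    ``rho`` holds the K = min(p, q) canonical correlations in descending
    order; ``x_structure``/``y_structure`` are the per-variable Pearson
    correlations with each variate (p×K and q×K); ``ve_x``/``ve_y`` the mean
    squared structure correlation over the first ``min(2, K)`` variates.
    """

    lambda_x: float
    lambda_y: float
    rho: np.ndarray
    x_weights: pd.DataFrame
    y_weights: pd.DataFrame
    x_variates: pd.DataFrame
    y_variates: pd.DataFrame
    x_structure: pd.DataFrame
    y_structure: pd.DataFrame
    ve_x: float = field(default=np.nan)
    ve_y: float = field(default=np.nan)

    @property
    def n_variates(self) -> int:
        return len(self.rho)


@dataclass
class CVGrid:
    """Leave-one-out scores over a (λx, λy) grid and the selected pair."""

    frame: pd.DataFrame  # columns: lambda_x, lambda_y, loo_score
    selected: tuple[float, float]

    @property
    def best_score(self) -> float:
        row = self.frame[
            (self.frame["lambda_x"] == self.selected[0])
            & (self.frame["lambda_y"] == self.selected[1])
        ]
        return float(row["loo_score"].iloc[0])


def drop_constant_columns(M: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance columns, warning with their names."""
    sd = M.std(axis=0, ddof=1)
    constant = list(M.columns[(sd == 0) | sd.isna()])
    if constant:
        warnings.warn(f"dropping constant column(s): {constant}", stacklevel=2)
        M = M.drop(columns=constant)
    return M


def standardize_columns(M: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to sample sd 1 (n−1 denominator)."""
    if M.shape[0] < 3:
        raise ValueError("standardization needs at least 3 samples")
    sd = M.std(axis=0, ddof=1)
    bad = list(M.columns[(sd == 0) | sd.isna()])
    if bad:
        raise ValueError(f"constant column(s) cannot be standardized: {bad}")
    return (M - M.mean(axis=0)) / sd


def _inv_sqrt(A: np.ndarray, lam: float) -> np.ndarray:
    """(A + λI)^(-1/2) via eigendecomposition; refuses a singular matrix at λ=0."""
    w, E = np.linalg.eigh(A + lam * np.eye(A.shape[0]))
    tol = 1e-10 * max(w.max(), 1.0)
    if w.min() < tol:
        raise np.linalg.LinAlgError(
            "within-set correlation matrix is singular; "
            "use a positive regularization lambda"
        )
    return (E / np.sqrt(w)) @ E.T


def _solve_regularized(B: np.ndarray, lam: float, rhs: np.ndarray) -> np.ndarray:
    Breg = B + lam * np.eye(B.shape[0])
    w = np.linalg.eigvalsh(Breg)
    if w.min() < 1e-10 * max(w.max(), 1.0):
        raise np.linalg.LinAlgError(
            "within-set correlation matrix is singular; "
            "use a positive regularization lambda"
        )
    return np.linalg.solve(Breg, rhs)


def _weights_from_corr(
    Rxx: np.ndarray,
    Ryy: np.ndarray,
    Rxy: np.ndarray,
    lambda_x: float,
    lambda_y: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the RCCA eigenproblem on the smaller side; return (Wx, Wy, eigvals)."""
    p, q = Rxy.shape
    if p > q:
        Wy, Wx, eig = _weights_from_corr(Ryy, Rxx, Rxy.T, lambda_y, lambda_x)
        return Wx, Wy, eig
    K = p  # p <= q
    Ainv_sqrt = _inv_sqrt(Rxx, lambda_x)
    BinvRyx = _solve_regularized(Ryy, lambda_y, Rxy.T)
    M = Ainv_sqrt @ Rxy @ BinvRyx @ Ainv_sqrt
    M = (M + M.T) / 2.0
    eigvals, E = np.linalg.eigh(M)
    if not np.isfinite(eigvals).all():
        raise np.linalg.LinAlgError("eigendecomposition produced non-finite values")
    order = np.argsort(eigvals)[::-1][:K]
    eigvals = eigvals[order]
    if eigvals.min() < _EIG_FLOOR:
        raise np.linalg.LinAlgError(f"negative eigenvalue {eigvals.min():g} in RCCA")
    eigvals = np.clip(eigvals, 0.0, 1.0)
    Wx = Ainv_sqrt @ E[:, order]
    Wy = BinvRyx @ Wx
    # normalize feature weights to unit (regularized) variance, wy' (Ryy+λI) wy = 1
    Byy = Ryy + lambda_y * np.eye(q)
    norms = np.sqrt(np.einsum("jk,jl,lk->k", Wy, Byy, Wy))
    norms[norms == 0] = 1.0
    Wy = Wy / norms
    return Wx, Wy, eigvals


def _pearson_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise cross-correlation matrix cor(A_j, B_k)."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = np.sqrt((Ac**2).sum(axis=0))
    sb = np.sqrt((Bc**2).sum(axis=0))
    sa[sa == 0] = np.nan
    sb[sb == 0] = np.nan
    return (Ac.T @ Bc) / np.outer(sa, sb)


def rcca_fit(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    lambda_x: float = 0.0,
    lambda_y: float = 0.0,
) -> RCCAResult:
    """Fit RCCA of a standardized environmental matrix X against features Y.

    Both matrices must be column-standardized (see :func:`standardize_columns`)
    and share the same sample rows.  ``lambda_x``/``lambda_y`` ≥ 0 are the
    ridge weights added to the within-set correlation matrices; λ = 0 requires
    the corresponding correlation matrix to be invertible (it never is when
    samples do not outnumber that set's variables).

    The sign of each weight/variate pair is fixed so the largest-magnitude
    element of the environmental weight vector is positive, making repeated
    fits bit-identical.
    """
    if lambda_x < 0 or lambda_y < 0:
        raise ValueError("regularization weights must be >= 0")
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same samples")
    if n < 3:
        raise ValueError("RCCA needs at least 3 samples")
    Xv = X.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    if not (np.isfinite(Xv).all() and np.isfinite(Yv).all()):
        raise ValueError("RCCA input contains non-finite values")
    Rxx = np.corrcoef(Xv, rowvar=False).reshape(Xv.shape[1], Xv.shape[1])
    Ryy = np.corrcoef(Yv, rowvar=False).reshape(Yv.shape[1], Yv.shape[1])
    Rxy = _pearson_columns(Xv, Yv)
    Wx, Wy, _ = _weights_from_corr(Rxx, Ryy, Rxy, lambda_x, lambda_y)
    U = Xv @ Wx
    V = Yv @ Wy

    # deterministic sign convention: largest-|.| env weight positive per variate
    for k in range(Wx.shape[1]):
        j = int(np.argmax(np.abs(Wx[:, k])))
        if Wx[j, k] < 0:
            Wx[:, k] *= -1
            Wy[:, k] *= -1
            U[:, k] *= -1
            V[:, k] *= -1

    rho = np.array(
        [_pearson_columns(U[:, [k]], V[:, [k]])[0, 0] for k in range(U.shape[1])]
    )
    rho = np.nan_to_num(rho, nan=0.0)
    # order variates by empirical canonical correlation, descending (stable)
    order = np.argsort(-rho, kind="stable")
    rho = rho[order]
    Wx, Wy, U, V = Wx[:, order], Wy[:, order], U[:, order], V[:, order]

    Cx = _pearson_columns(Xv, U)
    Cy = _pearson_columns(Yv, V)
    K = U.shape[1]
    cols = [f"CV{k + 1}" for k in range(K)]
    result = RCCAResult(
        lambda_x=float(lambda_x),
        lambda_y=float(lambda_y),
        rho=rho,
        x_weights=pd.DataFrame(Wx, index=X.columns, columns=cols),
        y_weights=pd.DataFrame(Wy, index=Y.columns, columns=cols),
        x_variates=pd.DataFrame(U, index=X.index, columns=cols),
        y_variates=pd.DataFrame(V, index=Y.index, columns=cols),
        x_structure=pd.DataFrame(Cx, index=X.columns, columns=cols),
        y_structure=pd.DataFrame(Cy, index=Y.columns, columns=cols),
    )
    d = min(2, K)
    result.ve_x, result.ve_y = variance_explained(result, d=d)
    return result


def loo_cv_select(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    grid: list[tuple[float, float]] | None = None,
) -> CVGrid:
    """Select (λx, λy) by leave-one-out correlation of first-variate projections.

    For each grid pair, every sample in turn is held out; the remaining
    samples are standardized and fitted, and the held-out sample (standardized
    with the training statistics) is projected onto the first pair of weight
    vectors.  The score is the Pearson correlation between the n held-out
    environmental and feature projections.  Pairs whose fits fail (e.g. λ = 0
    with a singular correlation matrix) or whose projections are degenerate
    score −1.  Ties are broken toward the smallest (λx, λy) lexicographically.

    ``X`` and ``Y`` are raw (unstandardized) numeric matrices with identical
    sample rows.
    """
    if grid is None:
        grid = list(itertools.product(DEFAULT_LAMBDA_GRID, DEFAULT_LAMBDA_GRID))
    grid = list(grid)
    if not grid:
        raise ValueError("empty regularization grid")
    n = X.shape[0]
    if n < 5:
        raise ValueError("leave-one-out selection needs at least 5 samples")
    Xv = X.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)

    # Per-fold correlation matrices are λ-independent: precompute them once.
    folds = []
    for i in range(n):
        keep = np.arange(n) != i
        Xt, Yt = Xv[keep], Yv[keep]
        mx, my = Xt.mean(axis=0), Yt.mean(axis=0)
        sx, sy = Xt.std(axis=0, ddof=1), Yt.std(axis=0, ddof=1)
        if (sx == 0).any() or (sy == 0).any():
            raise ValueError("constant column within a leave-one-out fold")
        Xs, Ys = (Xt - mx) / sx, (Yt - my) / sy
        Rxx = np.corrcoef(Xs, rowvar=False).reshape(Xs.shape[1], Xs.shape[1])
        Ryy = np.corrcoef(Ys, rowvar=False).reshape(Ys.shape[1], Ys.shape[1])
        Rxy = _pearson_columns(Xs, Ys)
        xo = (Xv[i] - mx) / sx
        yo = (Yv[i] - my) / sy
        folds.append((Rxx, Ryy, Rxy, xo, yo))

    rows = []
    for lx, ly in grid:
        u = np.empty(n)
        v = np.empty(n)
        failed = False
        for i, (Rxx, Ryy, Rxy, xo, yo) in enumerate(folds):
            try:
                Wx, Wy, _ = _weights_from_corr(Rxx, Ryy, Rxy, lx, ly)
            except np.linalg.LinAlgError:
                failed = True
                break
            # orient the fold's first pair consistently (largest-|.| env weight > 0)
            j = int(np.argmax(np.abs(Wx[:, 0])))
            s = 1.0 if Wx[j, 0] >= 0 else -1.0
            u[i] = s * (xo @ Wx[:, 0])
            v[i] = s * (yo @ Wy[:, 0])
        if failed:
            warnings.warn(
                f"fit failed at lambda=({lx:g}, {ly:g}); score set to -1", stacklevel=2
            )
            score = -1.0
        elif np.std(u) == 0 or np.std(v) == 0:
            warnings.warn(
                f"degenerate held-out projections at lambda=({lx:g}, {ly:g})",
                stacklevel=2,
            )
            score = -1.0
        else:
            score = float(np.corrcoef(u, v)[0, 1])
            if not np.isfinite(score):
                score = -1.0
        rows.append((float(lx), float(ly), score))

    frame = pd.DataFrame(rows, columns=["lambda_x", "lambda_y", "loo_score"])
    best = frame["loo_score"].max()
    winners = frame[frame["loo_score"] == best].sort_values(
        ["lambda_x", "lambda_y"], kind="stable"
    )
    selected = (float(winners["lambda_x"].iloc[0]), float(winners["lambda_y"].iloc[0]))
    return CVGrid(frame=frame, selected=selected)


def variable_variate_correlation(result: RCCAResult, variable_name: str, k: int) -> float:
    """Structure correlation of one original variable with variate ``k`` (1-based)."""
    if not 1 <= k <= result.n_variates:
        raise ValueError(f"variate index {k} out of range 1..{result.n_variates}")
    col = f"CV{k}"
    if variable_name in result.x_structure.index:
        return float(result.x_structure.at[variable_name, col])
    if variable_name in result.y_structure.index:
        return float(result.y_structure.at[variable_name, col])
    raise KeyError(f"unknown variable {variable_name!r}")


def variance_explained(result: RCCAResult, d: int = 2) -> tuple[float, float]:
    """Mean over variables of the summed squared structure correlations, k ≤ d."""
    if d > result.n_variates:
        raise ValueError(f"d={d} exceeds the {result.n_variates} available variates")
    if d == 0:
        return 0.0, 0.0
    cols = [f"CV{k + 1}" for k in range(d)]
    ve_x = float((result.x_structure[cols] ** 2).sum(axis=1).mean())
    ve_y = float((result.y_structure[cols] ** 2).sum(axis=1).mean())
    return ve_x, ve_y


def dimming_mask(result: RCCAResult, radius: float = 0.5) -> pd.Series:
    """Correlation-circle dimming: True where the first two squared structure
    correlations sum to strictly less than ``radius²`` (a point exactly on the
    inner circle stays shown).  Indexed by (set, variable)."""
    if result.n_variates < 2:
        raise ValueError("dimming requires at least two variates")
    rows = []
    for name, struct in (("env", result.x_structure), ("feature", result.y_structure)):
        r2 = struct["CV1"] ** 2 + struct["CV2"] ** 2
        for var, val in r2.items():
            rows.append(((name, var), bool(val < radius**2)))
    index = pd.MultiIndex.from_tuples([r[0] for r in rows], names=["set", "variable"])
    return pd.Series([r[1] for r in rows], index=index, name="dimmed")


def biplot_data(result: RCCAResult, radius: float = 0.5) -> pd.DataFrame:
    """Correlation-circle coordinates: one row per variable with its set
    (env/feature), structure correlations with variates 1 and 2, and the
    dimmed flag."""
    if result.n_variates < 2:
        raise ValueError("biplot requires at least two variates")
    mask = dimming_mask(result, radius=radius)
    rows = []
    for name, struct in (("env", result.x_structure), ("feature", result.y_structure)):
        for var in struct.index:
            rows.append(
                {
                    "variable": var,
                    "set": name,
                    "dim1": float(struct.at[var, "CV1"]),
                    "dim2": float(struct.at[var, "CV2"]),
                    "dimmed": bool(mask[(name, var)]),
                }
            )
    return pd.DataFrame(rows)


def fit_env_features(
    env: EnvTable,
    features: AbundanceMatrix,
    lambda_x: float | None = None,
    lambda_y: float | None = None,
    cv: bool = False,
    grid: list[tuple[float, float]] | None = None,
) -> tuple[RCCAResult, CVGrid | None]:
    """Convenience pipeline: align samples, drop incomplete samples and
    constant columns, optionally select λ by leave-one-out CV, standardize and
    fit.

    Samples present in only one table are dropped silently (intersection);
    samples with missing environmental values are dropped with a warning.
    Returns the fitted result and the CV grid (None unless ``cv``).
    """
    shared = [s for s in env.samples if s in set(features.samples)]
    incomplete = set(env.incomplete_samples)
    if incomplete & set(shared):
        warnings.warn(
            f"dropping sample(s) with missing environmental values: "
            f"{sorted(incomplete & set(shared))}",
            stacklevel=2,
        )
        shared = [s for s in shared if s not in incomplete]
    X = env.env.loc[shared]
    Y = features.frame.loc[shared]
    X = drop_constant_columns(X)
    Y = drop_constant_columns(Y)
    cvgrid = None
    if cv:
        cvgrid = loo_cv_select(X, Y, grid=grid)
        lambda_x, lambda_y = cvgrid.selected
    if lambda_x is None or lambda_y is None:
        raise ValueError("either pass lambda_x and lambda_y or set cv=True")
    result = rcca_fit(
        standardize_columns(X), standardize_columns(Y), lambda_x, lambda_y
    )
    return result, cvgrid
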