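"""Multi-task regression models: single-task elastic net, joint row-sparse
regression, and tree-guided group lasso.

All fitting operates on standardized inputs (see :mod:`sctfa.preprocess`);
the objective uses the un-halved residual sum of squares

    sum_i (y_i - X b_i)^T (y_i - X b_i) + lambda * Omega(B)

where for the tree-guided model Omega(B) = sum_j sum_v w_v ||B[j, G_v]||_2
over the nodes v of a task tree. Because the node groups form a laminar
family, the proximal operator of Omega is computed exactly by one
leaves-to-root pass of group soft-thresholding, which lets us minimize the
objective with an (objective-monotone) accelerated proximal-gradient scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .preprocess import SplitSpec, Standardizer
from .trees import TaskTree

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 10).tolist())
DEFAULT_STL_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10).tolist())


@dataclass
class FitResult:
    """Fitted coefficient matrix plus everything needed to reuse it."""

    B: np.ndarray  # p x k, standardized scale
    model_kind: str  # {stl, omtl, tree}
    lam: float = 0.0
    alpha: float | None = None
    tree: TaskTree | None = None
    x_scaler: Standardizer | None = None
    y_scaler: Standardizer | None = None
    split: SplitSpec | None = None
    feature_ids: list[str] | None = None
    cell_ids: list[str] | None = None
    objective_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True
    residual_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.B)):
            raise ValueError("coefficient matrix contains non-finite entries")


@dataclass
class CvResult:
    """Grid search record for one hyperparameter."""

    grid: np.ndarray
    fold_losses: np.ndarray  # n_grid x n_folds mean squared validation error
    mean_losses: np.ndarray
    selected: float
    fold_assignment: np.ndarray  # fold index per training gene
    seed: int


# ---------------------------------------------------------------------------
# penalty, objective, proximal operator


def _penalty_value(B: np.ndarray, groups: list[tuple[np.ndarray, float]]) -> float:
    total = 0.0
    for idx, w in groups:
        total += w * float(np.sqrt((B[:, idx] ** 2).sum(axis=1)).sum())
    return total


def tree_objective(
    X: np.ndarray, Y: np.ndarray, B: np.ndarray, tree: TaskTree, lam: float
) -> float:
    """Residual sum of squares plus the weighted tree-group penalty."""
    X, Y, B = np.asarray(X), np.asarray(Y), np.asarray(B)
    if X.shape[0] != Y.shape[0] or X.shape[1] != B.shape[0] or Y.shape[1] != B.shape[1]:
        raise ValueError(
            f"dimension mismatch: X {X.shape}, Y {Y.shape}, B {B.shape}"
        )
    if Y.shape[1] != tree.k:
        raise ValueError(f"tree has {tree.k} tasks but Y has {Y.shape[1]} columns")
    resid = Y - X @ B
    return float((resid**2).sum()) + lam * _penalty_value(B, tree.penalty_groups())


def prox_tree_norm(
    V: np.ndarray, groups: list[tuple[np.ndarray, float]], tau: float
) -> np.ndarray:
    """Exact prox of ``tau * sum_v w_v ||row[G_v]||_2`` applied to every row of V.

    ``groups`` must be ordered leaves-to-root (ascending subtree); each pass
    group-soft-thresholds the columns of one node's leaf set.
    """
    B = np.array(V, dtype=float, copy=True)
    for idx, w in groups:
        sub = B[:, idx]
        norms = np.sqrt((sub**2).sum(axis=1))
        thr = tau * w
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(norms > thr, 1.0 - thr / np.where(norms > 0, norms, 1.0), 0.0)
        B[:, idx] = sub * scale[:, None]
    return B


def _spectral_norm_sq(X: np.ndarray) -> float:
    """Largest eigenvalue of X^T X via power iteration (deterministic start)."""
    p = X.shape[1]
    rng = np.random.default_rng(0)
    v = rng.standard_normal(p)
    v /= np.linalg.norm(v)
    ev = 0.0
    for _ in range(200):
        w = X.T @ (X @ v)
        norm = np.linalg.norm(w)
        if norm == 0:
            return 0.0
        v_new = w / norm
        if abs(norm - ev) <= 1e-12 * max(1.0, ev):
            ev = norm
            break
        ev, v = norm, v_new
    return float(ev)


def _fista(
    X: np.ndarray,
    Y: np.ndarray,
    groups: list[tuple[np.ndarray, float]],
    lam: float,
    ridge: float = 0.0,
    B0: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, list[float], bool]:
    """Monotone FISTA for RSS + ridge*||B||_F^2 + lam * group penalty."""
    n, p = X.shape
    k = Y.shape[1]
    L = 2.0 * _spectral_norm_sq(X) + 2.0 * ridge
    if L == 0:
        return np.zeros((p, k)), [float((Y**2).sum())], True
    step = 1.0 / (L * 1.0000001)

    def objective(B: np.ndarray) -> float:
        resid = Y - X @ B
        val = float((resid**2).sum()) + ridge * float((B**2).sum())
        return val + lam * _penalty_value(B, groups)

    Xt = X.T
    B = np.zeros((p, k)) if B0 is None else np.array(B0, dtype=float, copy=True)
    Z = B.copy()
    t = 1.0
    f_best = objective(B)
    history = [f_best]
    stall = 0
    converged = False
    for _ in range(max_iter):
        grad = 2.0 * (Xt @ (X @ Z - Y)) + 2.0 * ridge * Z
        candidate = prox_tree_norm(Z - step * grad, groups, step * lam)
        f_cand = objective(candidate)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        if f_cand <= f_best:
            B_new, f_new = candidate, f_cand
        else:  # monotone safeguard: keep the best iterate
            B_new, f_new = B, f_best
        Z = B_new + (t / t_next) * (candidate - B_new) + ((t - 1.0) / t_next) * (B_new - B)
        rel_change = abs(f_best - f_new) / max(1.0, abs(f_best))
        stall = stall + 1 if rel_change <= tol else 0
        B, f_best, t = B_new, f_new, t_next
        history.append(f_best)
        if stall >= 5:
            converged = True
            break
    return B, history, converged


# ---------------------------------------------------------------------------
# fitting front-ends


def _least_squares(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return B


def lambda_max_upper_bound(X: np.ndarray, Y: np.ndarray, tree: TaskTree) -> float:
    """A lambda at or above which B = 0 is optimal.

    From the stationarity condition at B = 0: the penalty dominates the root
    group alone, Omega(row) >= w_root ||row||_2, so its dual norm is at most
    ||.||_2 / w_root and any lambda >= max_j 2 ||(X^T Y)_j||_2 / w_root keeps
    the zero matrix optimal.
    """
    w_root = tree.weights[tree.root]
    g = X.T @ Y
    return float(2.0 * np.sqrt((g**2).sum(axis=1)).max() / w_root)


def fit_tree_guided(
    X: np.ndarray,
    Y: np.ndarray,
    tree: TaskTree,
    lam: float,
    max_iter: int = 1000,
    tol: float = 1e-6,
    B0: np.ndarray | None = None,
) -> FitResult:
    """Minimize the tree-guided group-lasso objective by proximal gradient."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if Y.shape[1] != tree.k:
        raise ValueError(f"tree has {tree.k} tasks but Y has {Y.shape[1]} columns")
    if lam == 0.0:
        B = _least_squares(X, Y)
        obj = tree_objective(X, Y, B, tree, 0.0)
        return FitResult(B=B, model_kind="tree", lam=0.0, tree=tree,
                         objective_history=[obj], n_iter=0, converged=True)
    groups = tree.penalty_groups()
    B, history, converged = _fista(
        X, Y, groups, lam, B0=B0, max_iter=max_iter, tol=tol
    )
    if len(history) >= 2 and history[-1] > history[0] + 1e-12 * max(1.0, abs(history[0])):
        raise RuntimeError(
            f"objective increased from {history[0]:.6g} to {history[-1]:.6g}"
        )
    resid = Y - X @ B
    return FitResult(
        B=B,
        model_kind="tree",
        lam=float(lam),
        tree=tree,
        objective_history=history,
        n_iter=len(history) - 1,
        converged=converged,
        residual_variance=resid.var(axis=0, ddof=1),
    )


def fit_omtl(
    X: np.ndarray,
    Y: np.ndarray,
    alpha: float,
    ridge: float = 0.0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    B0: np.ndarray | None = None,
) -> FitResult:
    """Joint row-sparse regression: RSS + alpha * sum_j ||beta^j||_2.

    ``ridge`` adds an optional quadratic term ``ridge * ||B||_F^2`` to
    emulate the multi-response elastic-net family; the default 0 is the
    plain row-group objective.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if alpha < 0 or ridge < 0:
        raise ValueError("alpha and ridge must be nonnegative")
    k = Y.shape[1]
    if alpha == 0.0 and ridge == 0.0:
        B = _least_squares(X, Y)
        obj = float(((Y - X @ B) ** 2).sum())
        return FitResult(B=B, model_kind="omtl", lam=0.0, alpha=0.0,
                         objective_history=[obj], n_iter=0, converged=True)
    groups = [(np.arange(k), 1.0)]
    B, history, converged = _fista(
        X, Y, groups, alpha, ridge=ridge, B0=B0, max_iter=max_iter, tol=tol
    )
    resid = Y - X @ B
    return FitResult(
        B=B,
        model_kind="omtl",
        lam=float(alpha),
        alpha=float(alpha),
        objective_history=history,
        n_iter=len(history) - 1,
        converged=converged,
        residual_variance=resid.var(axis=0, ddof=1),
    )


def omtl_objective(X: np.ndarray, Y: np.ndarray, B: np.ndarray, alpha: float,
                   ridge: float = 0.0) -> float:
    resid = Y - X @ B
    row_norms = np.sqrt((B**2).sum(axis=1))
    return float((resid**2).sum()) + ridge * float((B**2).sum()) + alpha * float(row_norms.sum())


def fit_stl(
    X: np.ndarray,
    Y: np.ndarray,
    alpha_grid: tuple[float, ...] = DEFAULT_STL_ALPHA_GRID,
    cv: int = 5,
    seed: int = 0,
    max_iter: int = 5000,
    eps: float = 1e-3,
) -> FitResult:
    """Independent elastic-net regression per cell with cross-validated mixing.

    The mixing grid spans [0, 1] at step 0.1 (11 values); the penalty path is
    chosen per cell by ``cv``-fold cross-validation.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    # coordinate descent requires a strictly positive l1 component; 0 is
    # mapped to a numerically-ridge-like small value
    ratios = [max(r, 0.01) for r in alpha_grid]
    p, k = X.shape[1], Y.shape[1]
    B = np.zeros((p, k))
    splitter = KFold(n_splits=cv, shuffle=True, random_state=seed)
    for j in range(k):
        y = Y[:, j]
        if np.std(y) == 0:
            warnings.warn(f"task {j}: constant response, null model used", stacklevel=2)
            continue
        model = ElasticNetCV(
            l1_ratio=ratios, cv=splitter, fit_intercept=False, max_iter=max_iter, eps=eps
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        B[:, j] = model.coef_
    return FitResult(B=B, model_kind="stl", objective_history=[], converged=True)


def cross_validate_tree(
    X: np.ndarray,
    Y: np.ndarray,
    tree: TaskTree,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> CvResult:
    """Gene-wise k-fold cross-validation of lambda for the tree-guided model.

    The default grid covers [0, 1] at resolution 0.05 (21 values). The
    selected lambda minimizes the mean pooled squared validation error;
    ties break toward the smaller lambda.
    """
    grid = np.asarray(sorted(set(float(v) for v in lambda_grid)))
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"need at least {folds} training genes")
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(n, dtype=int)
    perm = rng.permutation(n)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        fold_of[chunk] = f

    losses = np.zeros((grid.size, folds))
    for f in range(folds):
        val = fold_of == f
        trn = ~val
        B_warm: np.ndarray | None = None
        # descend the grid so each fit warm-starts from a sparser solution
        for gi in range(grid.size - 1, -1, -1):
            lam = grid[gi]
            fit = fit_tree_guided(
                X[trn], Y[trn], tree, lam, max_iter=max_iter, tol=tol, B0=B_warm
            )
            B_warm = fit.B
            resid = Y[val] - X[val] @ fit.B
            losses[gi, f] = float((resid**2).mean())
    mean_losses = losses.mean(axis=1)
    selected = float(grid[int(np.argmin(mean_losses))])
    return CvResult(
        grid=grid,
        fold_losses=losses,
        mean_losses=mean_losses,
        selected=selected,
        fold_assignment=fold_of,
        seed=seed,
    )


def cross_validate_omtl(
    X: np.ndarray,
    Y: np.ndarray,
    alpha_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    seed: int = 0,
    ridge: float = 0.0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> CvResult:
    """Gene-wise k-fold cross-validation of the row-group penalty magnitude."""
    grid = np.asarray(sorted(set(float(v) for v in alpha_grid)))
    if grid.size == 0:
        raise ValueError("empty alpha grid")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(n, dtype=int)
    for f, chunk in enumerate(np.array_split(rng.permutation(n), folds)):
        fold_of[chunk] = f
    losses = np.zeros((grid.size, folds))
    for f in range(folds):
        val = fold_of == f
        trn = ~val
        B_warm: np.ndarray | None = None
        for gi in range(grid.size - 1, -1, -1):
            fit = fit_omtl(X[trn], Y[trn], grid[gi], ridge=ridge,
                           max_iter=max_iter, tol=tol, B0=B_warm)
            B_warm = fit.B
            resid = Y[val] - X[val] @ fit.B
            losses[gi, f] = float((resid**2).mean())
    mean_losses = losses.mean(axis=1)
    selected = float(grid[int(np.argmin(mean_losses))])
    return CvResult(grid=grid, fold_losses=losses, mean_losses=mean_losses,
                    selected=selected, fold_assignment=fold_of, seed=seed)


# ---------------------------------------------------------------------------
# prediction and evaluation


def predict(fit: FitResult, X_new: np.ndarray) -> np.ndarray:
    """Predictions on the response scale stored in the fit's standardizers."""
    X_new = np.asarray(X_new, dtype=float)
    if fit.x_scaler is not None:
        if X_new.shape[1] != fit.x_scaler.kept_columns.size and X_new.shape[1] != (
            fit.x_scaler.kept_columns.size + len(fit.x_scaler.dropped)
        ):
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, expected "
                f"{fit.x_scaler.kept_columns.size + len(fit.x_scaler.dropped)}"
            )
        if X_new.shape[1] == fit.x_scaler.kept_columns.size + len(fit.x_scaler.dropped):
            X_std = fit.x_scaler.transform(X_new)
        else:
            X_std = X_new
    else:
        if X_new.shape[1] != fit.B.shape[0]:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model expects {fit.B.shape[0]}"
            )
        X_std = X_new
    Y_std = X_std @ fit.B
    if fit.y_scaler is not None:
        return fit.y_scaler.inverse_transform(Y_std)
    return Y_std


def evaluate_per_cell(Y_hat: np.ndarray, Y_test: np.ndarray) -> np.ndarray:
    """Pearson correlation per cell between prediction and truth over test genes.

    Cells whose prediction (or truth) is constant get NaN, not 0.
    """
    Y_hat = np.asarray(Y_hat, dtype=float)
    Y_test = np.asarray(Y_test, dtype=float)
    if Y_hat.shape != Y_test.shape:
        raise ValueError(f"shape mismatch {Y_hat.shape} vs {Y_test.shape}")
    if Y_hat.shape[0] < 3:
        raise ValueError("need at least 3 test genes")
    hc = Y_hat - Y_hat.mean(axis=0)
    tc = Y_test - Y_test.mean(axis=0)
    denom = np.sqrt((hc**2).sum(axis=0) * (tc**2).sum(axis=0))
    out = np.full(Y_hat.shape[1], np.nan)
    ok = denom > 0
    out[ok] = (hc * tc).sum(axis=0)[ok] / denom[ok]
    return out
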