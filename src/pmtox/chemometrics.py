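"""Multivariate chemometrics: autoscaling, PCA with Wold cross-validated Q²,
hierarchical clustering, single-response OPLS-DA with VIP, and the 200×
label-permutation validation test.

PCA is a plain SVD on the scaled matrix.  Q² for PCA uses Wold element-wise
deletion: matrix cells are split into folds, each fold is held out in turn,
the model is refit by EM-style imputation on the remaining cells, and
Q²_k = 1 - PRESS_k / SS.  OPLS-DA follows the orthogonal-projections scheme
for a single response: orthogonal (class-irrelevant) variation is peeled off
X before one predictive component is extracted; VIP is computed on the
predictive component so that the mean squared VIP over variables is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ScaledMatrix",
    "PcaModel",
    "OplsdaModel",
    "PermutationReport",
    "autoscale",
    "fit_pca",
    "pca_q2",
    "hca",
    "fit_oplsda",
    "permutation_test",
]


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScaledMatrix:
    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    scaling_mode: str
    constant_columns: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def autoscale(X, mode: str = "unit_variance") -> ScaledMatrix:
    """Column-wise centering and scaling.

    ``unit_variance`` divides by the column standard deviation (ddof=1),
    ``pareto`` by its square root, ``none`` leaves values untouched.
    Constant columns are centered but scaled by 1 and flagged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if mode not in ("unit_variance", "pareto", "none"):
        raise ValueError(f"unknown scaling mode: {mode!r}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sds == 0)
    if mode == "none":
        return ScaledMatrix(X.copy(), np.zeros_like(means), np.ones_like(sds), mode, constant)
    divisor = np.where(sds == 0, 1.0, sds)
    if mode == "pareto":
        divisor = np.sqrt(divisor)
    return ScaledMatrix((X - means) / divisor, means, divisor, mode, constant)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    scores: np.ndarray
    loadings: np.ndarray  # p x k, orthonormal columns
    explained_variance_fraction: np.ndarray
    r2x_cum: float
    q2_cum: float | None = None


def fit_pca(X: ScaledMatrix | np.ndarray, n_components: int) -> PcaModel:
    """SVD-based PCA on a pre-scaled matrix; scores are U·S."""
    M = X.values if isinstance(X, ScaledMatrix) else np.asarray(X, dtype=float)
    n, p = M.shape
    max_k = min(n - 1, p)
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components must be in [1, {max_k}]")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float(np.sum(s**2))
    k = n_components
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PcaModel(
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T,
        explained_variance_fraction=frac,
        r2x_cum=float(frac.sum()),
    )


def _em_pca_impute(M: np.ndarray, missing: np.ndarray, k: int,
                   tol: float = 1e-9, max_iter: int = 200) -> np.ndarray:
    """Rank-k reconstruction of M with ``missing`` cells imputed by EM/SVD."""
    filled = M.copy()
    filled[missing] = 0.0
    prev = filled[missing].copy()
    recon = filled
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        recon = (U[:, :k] * s[:k]) @ Vt[:k]
        filled[missing] = recon[missing]
        if np.max(np.abs(filled[missing] - prev)) < tol if prev.size else True:
            break
        prev = filled[missing].copy()
    return recon


def pca_q2(X: ScaledMatrix | np.ndarray, n_components: int,
           n_folds: int = 7, seed: int = 0) -> np.ndarray:
    """Wold element-wise-deletion cross-validated Q² per cumulative component.

    Cells are assigned to folds by a seeded permutation; for each fold the
    held-out cells are predicted from a rank-k EM-imputation fit on the
    remaining cells, and Q²_k = 1 - PRESS_k / SS over the whole matrix.
    """
    M = X.values if isinstance(X, ScaledMatrix) else np.asarray(X, dtype=float)
    n, p = M.shape
    if n < n_folds:
        raise ValueError("need at least n_folds rows")
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(n * p) % n_folds
    ss = float(np.sum(M**2))
    q2 = np.empty(n_components)
    for k in range(1, n_components + 1):
        press = 0.0
        for f in range(n_folds):
            mask = (fold_of == f).reshape(n, p)
            recon = _em_pca_impute(M, mask, k)
            press += float(np.sum((M[mask] - recon[mask]) ** 2))
        q2[k - 1] = 1.0 - press / ss if ss > 0 else 0.0
    return q2


# ---------------------------------------------------------------------------
# hierarchical clustering


def hca(X, linkage: str = "ward", metric: str = "euclidean", k: int = 2):
    """Agglomerative clustering (Lance-Williams updates via scipy).

    Returns ``(labels, merge_tree)`` where labels are 1..k from cutting the
    tree at k clusters and merge_tree is the scipy linkage matrix.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError("k must not exceed the number of rows")
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage: {linkage!r}")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric: {metric!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    if n == 1:
        return np.array([1]), np.empty((0, 4))
    dists = pdist(X, metric=metric)
    tree = hierarchy.linkage(dists, method=linkage)
    labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    return labels, tree


# ---------------------------------------------------------------------------
# OPLS-DA


@dataclass
class OplsdaModel:
    predictive_scores: np.ndarray
    predictive_loadings: np.ndarray
    orthogonal_scores: np.ndarray
    orthogonal_loadings: np.ndarray
    weights: np.ndarray
    n_orthogonal: int
    r2x: float
    r2y: float
    q2: float
    vip: np.ndarray
    q_coef: float
    y_mean: float
    classes: tuple = ()


def _encode_labels(y) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist()), key=str))
    if len(classes) != 2:
        raise ValueError("OPLS-DA requires exactly two classes in y")
    return np.where(y == classes[0], -1.0, 1.0), classes


def _opls_core(X: np.ndarray, yc: np.ndarray, n_orthogonal: int):
    """O-PLS decomposition for a single centered response.

    Returns (t, p, q, w, T_o, P_o, W_o) with w the unit predictive weight
    vector in the orthogonally-filtered space.
    """
    Xd = X.copy()
    T_o, P_o, W_o = [], [], []
    for _ in range(n_orthogonal):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w = w / nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break  # no orthogonal variation left
        w_o = w_o / n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        T_o.append(t_o)
        P_o.append(p_o)
        W_o.append(w_o)
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("response carries no covariance with X")
    w = w / nw
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    to_mat = np.column_stack(T_o) if T_o else np.empty((X.shape[0], 0))
    po_mat = np.column_stack(P_o) if P_o else np.empty((X.shape[1], 0))
    wo_mat = np.column_stack(W_o) if W_o else np.empty((X.shape[1], 0))
    return t, p, q, w, to_mat, po_mat, wo_mat


def _opls_predict(Xnew: np.ndarray, w, q, wo_mat, po_mat) -> np.ndarray:
    Xd = Xnew.copy()
    for j in range(wo_mat.shape[1]):
        t_o = Xd @ wo_mat[:, j]
        Xd = Xd - np.outer(t_o, po_mat[:, j])
    return q * (Xd @ w)


def _venetian_folds(n: int, n_folds: int) -> list[np.ndarray]:
    idx = np.arange(n)
    return [idx[idx % n_folds == f] for f in range(n_folds)]


def fit_oplsda(X: ScaledMatrix | np.ndarray, y, n_orthogonal: int | str = 1,
               n_folds: int = 7) -> OplsdaModel:
    """Two-class OPLS-DA with one predictive component.

    Classes are encoded ±1 (decision boundary at 0).  Q² comes from
    venetian-blind row cross-validation (every ``n_folds``-th row held out);
    VIP is computed from the predictive weights only, so mean(VIP²) = 1.
    ``n_orthogonal="auto"`` adds orthogonal components while each improves
    Q² by at least 0.01 (up to min(n, p) - 1).
    """
    if n_orthogonal == "auto":
        M0 = X.values if isinstance(X, ScaledMatrix) else np.asarray(X, dtype=float)
        best = fit_oplsda(X, y, 0, n_folds)
        limit = min(M0.shape[0], M0.shape[1]) - 1
        for k in range(1, limit):
            cand = fit_oplsda(X, y, k, n_folds)
            if cand.q2 < best.q2 + 0.01 or cand.n_orthogonal < k:
                break
            best = cand
        return best
    M = X.values if isinstance(X, ScaledMatrix) else np.asarray(X, dtype=float)
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be non-negative")
    yc_raw, classes = _encode_labels(y)
    y_mean = float(yc_raw.mean())
    yc = yc_raw - y_mean
    n, p_dim = M.shape

    t, p, q, w, to_mat, po_mat, wo_mat = _opls_core(M, yc, n_orthogonal)

    ssx = float(np.sum(M**2))
    ssy = float(np.sum(yc**2))
    r2x_pred = float((t @ t) * (p @ p)) / ssx
    r2x_orth = sum(
        float((to_mat[:, j] @ to_mat[:, j]) * (po_mat[:, j] @ po_mat[:, j])) / ssx
        for j in range(to_mat.shape[1])
    )
    r2y = float(q**2 * (t @ t)) / ssy

    # venetian-blind CV for Q2
    press = 0.0
    for test_idx in _venetian_folds(n, min(n_folds, n)):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if len(set(yc_raw[train_idx].tolist())) < 2:
            continue
        ytr = yc_raw[train_idx] - yc_raw[train_idx].mean()
        tt, pp, qq, ww, _, ppo, wwo = _opls_core(M[train_idx], ytr, n_orthogonal)
        yhat = _opls_predict(M[test_idx], ww, qq, wwo, ppo) + yc_raw[train_idx].mean()
        press += float(np.sum((yc_raw[test_idx] - yhat) ** 2))
    q2 = 1.0 - press / ssy if ssy > 0 else 0.0

    vip = np.sqrt(p_dim) * np.abs(w)  # single predictive component, ||w|| = 1

    return OplsdaModel(
        predictive_scores=t,
        predictive_loadings=p,
        orthogonal_scores=to_mat,
        orthogonal_loadings=po_mat,
        weights=w,
        n_orthogonal=to_mat.shape[1],
        r2x=r2x_pred + r2x_orth,
        r2y=r2y,
        q2=q2,
        vip=vip,
        q_coef=float(q),
        y_mean=y_mean,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationReport:
    n_permutations: int
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    permuted_correlation: np.ndarray
    original_r2y: float
    original_q2: float
    q2_intercept: float
    valid: bool


def permutation_test(X: ScaledMatrix | np.ndarray, y, n_orthogonal: int = 1,
                     n_permutations: int = 200, seed: int = 0) -> PermutationReport:
    """Label-permutation overfitting check for OPLS-DA.

    Refits the model under ``n_permutations`` random reorderings of the class
    vector, recording R²Y and Q² of each, plus |Pearson r| between original
    and permuted ±1-encoded labels.  The Q² intercept is the value at
    correlation 0 of a least-squares line through the permuted points and the
    original model's point at correlation 1.  The model is declared valid when
    every permuted Q² falls below the original Q² and the intercept is
    negative.
    """
    M = X.values if isinstance(X, ScaledMatrix) else np.asarray(X, dtype=float)
    yc_raw, _ = _encode_labels(y)
    rng = np.random.default_rng(seed)
    original = fit_oplsda(M, yc_raw, n_orthogonal)

    r2s = np.empty(n_permutations)
    q2s = np.empty(n_permutations)
    cors = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(yc_raw)
        model = fit_oplsda(M, perm, n_orthogonal)
        r2s[i] = model.r2y
        q2s[i] = model.q2
        denom = np.std(yc_raw) * np.std(perm)
        cors[i] = abs(float(np.mean((yc_raw - yc_raw.mean()) * (perm - perm.mean())) / denom))

    xs = np.concatenate([cors, [1.0]])
    ys = np.concatenate([q2s, [original.q2]])
    slope, intercept = np.polyfit(xs, ys, 1)
    valid = bool(np.all(q2s < original.q2) and intercept < 0)
    return PermutationReport(
        n_permutations=n_permutations,
        permuted_r2y=r2s,
        permuted_q2=q2s,
        permuted_correlation=cors,
        original_r2y=original.r2y,
        original_q2=original.q2,
        q2_intercept=float(intercept),
        valid=valid,
    )
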