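"""Sparse multi-label attribute selection.

Learns a coefficient matrix W (features x labels) by minimizing

    ||XW - Y||_F^2 + alpha*tr(F L1 F^T) + beta*tr(F^T L2 F)
        + gamma1*||W||_{2,1} + gamma2*||W||_1,      F = XW,

where L1 is the Laplacian of the cosine label-similarity graph S and L2
the Laplacian of a symmetrized KNN instance-similarity graph C.  The
l2,1 term drives whole rows of W to zero (features shared across labels);
the l1 term sparsifies individual coefficients (label-specific features).
Features are then ranked by row l2 norm of W and the top-k retained.

The output matrix F is instantiated as the model prediction XW, making
the objective a function of W alone; a free latent F (optimized jointly,
as in some related formulations) is a possible extension point but not
implemented.  The optimizer is a monotone FISTA-style accelerated
proximal gradient: the composite prox of gamma1*||.||_{2,1} +
gamma2*||.||_1 is exact — entrywise soft-thresholding followed by
row-wise group shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist


def l21_norm(W: np.ndarray) -> float:
    """Sum of row Euclidean norms."""
    return float(np.sum(np.linalg.norm(W, axis=1)))


def l1_norm(W: np.ndarray) -> float:
    return float(np.sum(np.abs(W)))


def cosine_label_similarity(Y: np.ndarray) -> np.ndarray:
    """m x m cosine similarity between label columns of Y (unit diagonal)."""
    Y = np.asarray(Y, dtype=float)
    norms = np.linalg.norm(Y, axis=0)
    if np.any(norms == 0):
        raise ValueError("every label column needs at least one positive")
    S = (Y.T @ Y) / np.outer(norms, norms)
    np.fill_diagonal(S, 1.0)
    return S


def knn_instance_similarity(X: np.ndarray, k: int = 10,
                            bandwidth: float | None = None) -> np.ndarray:
    """Symmetrized KNN heat-kernel instance graph (zero diagonal).

    C[i, j] = exp(-d_ij^2 / (2 sigma^2)) if j is among the k nearest
    neighbours of i or vice versa, else 0; sigma defaults to the median
    pairwise distance.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError("need 1 <= k < n")
    D = squareform(pdist(X))
    if bandwidth is None:
        pos = D[np.triu_indices(n, 1)]
        bandwidth = float(np.median(pos)) if pos.size else 1.0
    if bandwidth == 0:
        bandwidth = 1.0
    W = np.exp(-(D ** 2) / (2 * bandwidth ** 2))
    # keep the k nearest neighbours of each row (excluding self)
    mask = np.zeros((n, n), dtype=bool)
    order = np.argsort(D + np.diag([np.inf] * n), axis=1)
    rows = np.repeat(np.arange(n), k)
    mask[rows, order[:, :k].ravel()] = True
    mask = mask | mask.T
    C = np.where(mask, W, 0.0)
    np.fill_diagonal(C, 0.0)
    return C


def laplacian(A: np.ndarray) -> np.ndarray:
    """Graph Laplacian L = D - A of a symmetric nonnegative matrix."""
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be square symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    return np.diag(A.sum(axis=1)) - A


@dataclass
class Hyperparams:
    alpha: float = 0.1
    beta: float = 0.1
    gamma1: float = 0.1  # weight of ||W||_{2,1}
    gamma2: float = 0.1  # weight of ||W||_1
    k_neighbors: int = 10

    def __post_init__(self):
        for nm in ("alpha", "beta", "gamma1", "gamma2"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be nonnegative")


def objective(X, Y, W, L1, L2, alpha, beta, gamma1, gamma2) -> float:
    """The full five-term objective with F = XW."""
    for g in (alpha, beta, gamma1, gamma2):
        if g < 0:
            raise ValueError("hyperparameters must be nonnegative")
    F = X @ W
    R = F - Y
    val = float(np.sum(R * R))
    if alpha:
        val += alpha * float(np.trace(F @ L1 @ F.T))
    if beta:
        val += beta * float(np.trace(F.T @ L2 @ F))
    val += gamma1 * l21_norm(W) + gamma2 * l1_norm(W)
    return val


def _smooth_grad(X, Y, W, L1, L2, alpha, beta, XtX, XtY, XtL2X):
    G = 2.0 * (XtX @ W - XtY)
    if alpha:
        G = G + 2.0 * alpha * (XtX @ W @ L1)
    if beta:
        G = G + 2.0 * beta * (XtL2X @ W)
    return G


def prox_l1_l21(W: np.ndarray, t1: float, t2: float) -> np.ndarray:
    """Prox of t2*||.||_1 then t1*||.||_{2,1} (exact for the nested pair)."""
    V = np.sign(W) * np.maximum(np.abs(W) - t2, 0.0)
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    scale = np.where(norms > 0, np.maximum(1.0 - t1 / np.maximum(norms, 1e-300), 0.0), 0.0)
    return V * scale


@dataclass
class SelectionResult:
    W: np.ndarray
    ranking: np.ndarray
    trace: list = field(default_factory=list)
    converged: bool = False
    L1: np.ndarray | None = None
    L2: np.ndarray | None = None
    hyperparams: Hyperparams | None = None

    @property
    def row_norms(self):
        return np.linalg.norm(self.W, axis=1)

    @property
    def support_size(self):
        return int(np.sum(self.row_norms > 0))


def solve(X, Y, hyperparams: Hyperparams | None = None, max_iter: int = 500,
          tol: float = 1e-7, seed: int = 0) -> SelectionResult:
    """Minimize the selection objective by monotone accelerated proximal
    gradient (FISTA with restart on objective increase).

    X must be column-standardized; Y is the n x m binary label matrix.
    Label columns with no positives are dropped (with a warning) before
    the similarity graph is built.  Returns W, the feature ranking and
    the (non-increasing) objective trace; non-convergence at ``max_iter``
    sets ``converged=False`` rather than raising.
    """
    hp = hyperparams or Hyperparams()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite (impute before solving)")
    if np.isin(Y, (0, 1)).all():  # binary labels: drop empty label columns
        keep = Y.sum(axis=0) > 0
        if not np.all(keep):
            import warnings
            warnings.warn("dropping label column(s) with no positives",
                          stacklevel=2)
            Y = Y[:, keep]
    n, d = X.shape
    m = Y.shape[1]

    if hp.alpha:
        # negative similarity (possible for continuous targets) carries no
        # edge; binary labels always give similarities in [0, 1]
        L1 = laplacian(np.clip(cosine_label_similarity(Y), 0.0, None))
    else:
        L1 = np.zeros((m, m))
    if hp.beta:
        k = min(hp.k_neighbors, n - 1)
        L2 = laplacian(knn_instance_similarity(X, k))
    else:
        L2 = np.zeros((n, n))

    XtX = X.T @ X
    XtY = X.T @ Y
    XtL2X = X.T @ L2 @ X if hp.beta else np.zeros((d, d))

    # Lipschitz constant of the smooth gradient
    eig_xtx = float(np.linalg.eigvalsh(XtX)[-1])
    eig_l1 = float(np.linalg.eigvalsh(L1)[-1]) if hp.alpha else 0.0
    eig_l2x = float(np.linalg.eigvalsh(XtL2X)[-1]) if hp.beta else 0.0
    L = 2.0 * eig_xtx * (1.0 + hp.alpha * eig_l1) + 2.0 * hp.beta * eig_l2x
    step = 1.0 / max(L, 1e-12)

    def fval(W):
        return objective(X, Y, W, L1, L2, hp.alpha, hp.beta, hp.gamma1, hp.gamma2)

    W = np.zeros((d, m))
    Z = W.copy()
    t_mom = 1.0
    trace = [fval(W)]
    converged = False
    for _ in range(max_iter):
        G = _smooth_grad(X, Y, Z, L1, L2, hp.alpha, hp.beta, XtX, XtY, XtL2X)
        W_new = prox_l1_l21(Z - step * G, step * hp.gamma1, step * hp.gamma2)
        f_new = fval(W_new)
        if f_new > trace[-1]:  # monotone safeguard: restart momentum
            G = _smooth_grad(X, Y, W, L1, L2, hp.alpha, hp.beta, XtX, XtY, XtL2X)
            W_new = prox_l1_l21(W - step * G, step * hp.gamma1, step * hp.gamma2)
            f_new = fval(W_new)
            t_mom = 1.0
            if f_new > trace[-1]:  # numerically stalled; keep the old iterate
                W_new, f_new = W, trace[-1]
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2))
        Z = W_new + ((t_mom - 1.0) / t_new) * (W_new - W)
        rel = abs(trace[-1] - f_new) / max(abs(trace[-1]), 1e-12)
        W, t_mom = W_new, t_new
        trace.append(f_new)
        if rel < tol:
            converged = True
            break

    ranking = rank_features(W)
    return SelectionResult(W=W, ranking=ranking, trace=trace,
                           converged=converged, L1=L1, L2=L2, hyperparams=hp)


def rank_features(W: np.ndarray) -> np.ndarray:
    """Feature indices by descending row l2 norm; ties -> lower index first."""
    norms = np.linalg.norm(np.asarray(W, dtype=float), axis=1)
    # stable sort on -norms keeps lower indices first among ties
    return np.argsort(-norms, kind="stable")


def select_top_k(ranking, k: int = 20, names=None):
    """First k entries of the ranking (as names when *names* is given)."""
    ranking = np.asarray(ranking)
    if not 1 <= k <= ranking.size:
        raise ValueError(f"k must lie in [1, {ranking.size}]")
    top = ranking[:k]
    if names is not None:
        return [names[i] for i in top]
    return top
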