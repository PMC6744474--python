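"""Sparse reduced-rank regression (RRR) of features on gene expression.

The model reconstructs a standardized feature matrix Y (n x q) from a
standardized expression matrix X (n x p) through a rank-r bottleneck:

    minimize  ||Y - X W V^T||_F^2 / (2n)
              + lambda * (alpha ||W||_1 + (1 - alpha)/2 ||W||_F^2)

with V (q x r) having orthonormal columns. The elastic-net penalty on the
encoder W makes the model select a small set of genes whose 2-D projection
(rank 2 by default) predicts all features at once. Optimization alternates
a W-step (per-component elastic-net regression of Y V on X; with V
orthonormal the full loss separates) and a V-step (orthogonal Procrustes
via the SVD of Y^T X W). The "relaxed" variant refits W without the
penalty on the selected support after convergence, then re-estimates V.

Initialization is the unpenalized reduced-rank fit (truncated SVD of the
least-squares prediction); iteration stops when the relative decrease of
the penalized loss falls below the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, Ridge
from sklearn.model_selection import KFold

__all__ = ["RRRConfig", "RRRModel", "fit_sparse_rrr", "cv_evaluate", "biplot_coordinates"]


@dataclass
class RRRConfig:
    rank: int = 2
    alpha: float = 0.5  # elastic-net mixing of the W penalty
    lam: float = 1.0  # overall penalty strength (glmnet lambda scale)
    relaxed: bool = True
    tol: float = 1e-6
    max_iter: int = 300


@dataclass
class RRRModel:
    W: np.ndarray  # genes x rank sparse encoder
    V: np.ndarray  # features x rank decoder, orthonormal columns
    config: RRRConfig
    loss_path: list = field(default_factory=list)

    @property
    def support(self) -> np.ndarray:
        """Indices of genes with a nonzero weight in any component."""
        return np.flatnonzero(np.any(self.W != 0, axis=1))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W @ self.V.T


def _check_standardized(M: np.ndarray, name: str, atol: float = 1e-6):
    if not np.allclose(M.mean(axis=0), 0.0, atol=atol):
        raise ValueError(f"{name} columns must be centered")
    sd = M.std(axis=0)
    if not np.allclose(sd[sd > 0], 1.0, atol=1e-3):
        raise ValueError(f"{name} columns must be standardized to unit variance")


def _penalty(W: np.ndarray, alpha: float, lam: float) -> float:
    return lam * (alpha * np.abs(W).sum() + 0.5 * (1 - alpha) * (W**2).sum())


def _loss(X, Y, W, V, alpha, lam) -> float:
    r = Y - X @ W @ V.T
    return float((r**2).sum() / (2 * X.shape[0]) + _penalty(W, alpha, lam))


def _w_step(X: np.ndarray, T: np.ndarray, alpha: float, lam: float) -> np.ndarray:
    """Elastic-net regression of each target column of T = Y V on X."""
    W = np.zeros((X.shape[1], T.shape[1]))
    if lam <= 0:
        W[:] = np.linalg.lstsq(X, T, rcond=None)[0]
        return W
    if alpha == 0:
        # pure ridge has the closed scikit-learn form
        model = Ridge(alpha=lam * X.shape[0], fit_intercept=False)
        model.fit(X, T)
        return model.coef_.T
    en = ElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=False, max_iter=10000, tol=1e-8
    )
    for j in range(T.shape[1]):
        en.fit(X, T[:, j])
        W[:, j] = en.coef_
    return W


def _v_step(X: np.ndarray, Y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes: V with orthonormal columns minimizing ||Y - XWV^T||."""
    M = Y.T @ (X @ W)
    U, _, Vt = np.linalg.svd(M, full_matrices=False)
    return U @ Vt


def _init_V(X: np.ndarray, Y: np.ndarray, rank: int) -> np.ndarray:
    B = np.linalg.lstsq(X, Y, rcond=None)[0]
    # right singular vectors of the least-squares prediction
    _, _, Vt = np.linalg.svd(X @ B, full_matrices=False)
    return Vt[:rank].T


def fit_sparse_rrr(X: np.ndarray, Y: np.ndarray, config: RRRConfig | None = None) -> RRRModel:
    """Fit the sparse RRR model by alternating W- and V-steps.

    X and Y must be column-standardized with the same row count; the
    penalized loss is checked to be non-increasing across iterations.
    """
    config = config or RRRConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if config.rank > min(X.shape[1], Y.shape[1]):
        raise ValueError("rank exceeds the smaller dimension")
    _check_standardized(X, "X")
    _check_standardized(Y, "Y")

    V = _init_V(X, Y, config.rank)
    W = np.zeros((X.shape[1], config.rank))
    losses = []
    prev = np.inf
    for _ in range(config.max_iter):
        W = _w_step(X, Y @ V, config.alpha, config.lam)
        V = _v_step(X, Y, W)
        cur = _loss(X, Y, W, V, config.alpha, config.lam)
        losses.append(cur)
        if prev - cur < config.tol * max(abs(prev), 1.0):
            break
        prev = cur

    if config.relaxed:
        sup = np.flatnonzero(np.any(W != 0, axis=1))
        if sup.size:
            Xs = X[:, sup]
            for _ in range(20):
                Ws = np.linalg.lstsq(Xs, Y @ V, rcond=None)[0]
                Wfull = np.zeros_like(W)
                Wfull[sup] = Ws
                V = _v_step(X, Y, Wfull)
            W = Wfull

    # identifiability: rotate so the training component scores X W are
    # decorrelated (the fit X W V^T is invariant under joint orthogonal
    # rotation; V stays orthonormal). Correlation biplots then obey the
    # unit-circle bound.
    Z = X @ W
    if Z.any():
        _, _, Rt = np.linalg.svd(Z, full_matrices=False)
        W = W @ Rt.T
        V = V @ Rt.T
    return RRRModel(W=W, V=V, config=config, loss_path=losses)


def cv_evaluate(
    X: np.ndarray,
    Y: np.ndarray,
    config: RRRConfig | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Cross-validated overall R-squared and per-component correlations.

    Per fold, the model is fit on the training rows and evaluated on the
    held-out rows: the R-squared of the Y reconstruction (pooled over
    folds, relative to ||Y||^2 of the standardized targets) and the Pearson
    correlation between the projected X W and Y V per component, averaged
    over folds. Folds on which a component has zero variance are skipped
    for that component with a warning.
    """
    import warnings

    config = config or RRRConfig()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    ss_res = 0.0
    ss_tot = 0.0
    comp_corrs: list[list[float]] = [[] for _ in range(config.rank)]
    for tr, te in kf.split(X):
        mu_x, sd_x = X[tr].mean(0), X[tr].std(0)
        mu_y, sd_y = Y[tr].mean(0), Y[tr].std(0)
        sd_x[sd_x == 0] = 1.0
        sd_y[sd_y == 0] = 1.0
        Xtr, Xte = (X[tr] - mu_x) / sd_x, (X[te] - mu_x) / sd_x
        Ytr, Yte = (Y[tr] - mu_y) / sd_y, (Y[te] - mu_y) / sd_y
        model = fit_sparse_rrr(Xtr, Ytr, config)
        pred = model.predict(Xte)
        ss_res += float(((Yte - pred) ** 2).sum())
        ss_tot += float((Yte**2).sum())
        zx = Xte @ model.W
        zy = Yte @ model.V
        for c in range(config.rank):
            if zx[:, c].std() == 0 or zy[:, c].std() == 0:
                warnings.warn(f"component {c}: zero variance on a fold, skipped")
                continue
            comp_corrs[c].append(float(np.corrcoef(zx[:, c], zy[:, c])[0, 1]))
    r2 = 1.0 - ss_res / ss_tot
    corrs = np.array([np.mean(c) if c else np.nan for c in comp_corrs])
    return float(r2), corrs


def biplot_coordinates(model: RRRModel, X: np.ndarray, Y: np.ndarray):
    """Correlations of selected genes and of all features with the two components.

    Returns ``(gene_coords, feature_coords)``: rows are the correlation
    vectors of each selected gene (resp. each feature) with the component
    scores X W; all vectors lie within the unit circle.
    """
    Z = X @ model.W
    if np.any(Z.std(axis=0) == 0):
        raise ValueError("zero-variance component: model is degenerate")
    sup = model.support
    gene_coords = np.array(
        [[np.corrcoef(X[:, g], Z[:, c])[0, 1] for c in range(Z.shape[1])] for g in sup]
    )
    feature_coords = np.array(
        [[np.corrcoef(Y[:, f], Z[:, c])[0, 1] for c in range(Z.shape[1])] for f in range(Y.shape[1])]
    )
    return gene_coords, feature_coords
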