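"""Pairwise cell-type discrimination and 2-D embeddings.

Cell types are compared pairwise with elastic-net regularized logistic
regression under nested cross-validation: an inner 5-fold loop picks the
regularization strength lambda by the one-standard-error rule on a
log-spaced path (the elastic-net mixing alpha is fixed at 0.5), and an
outer 10-times-repeated stratified 5-fold loop scores held-out accuracy.
Predictors are standardized inside every fit, and for density-map
predictors the principal-component reduction is fit on each outer training
set separately, so no information from a test cell reaches its fold's
PCA, scaling, or lambda choice.

t-SNE visualizations use the exact (non-approximate) gradient and a fixed
random initialization seed so repeated runs are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.metrics import log_loss
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

__all__ = [
    "FeatureMatrix",
    "ClassifierConfig",
    "build_morpho_features",
    "build_morpho_tsne_features",
    "preprocess_ephys",
    "pairwise_accuracy",
    "nested_cv_predictions",
    "fit_elastic_net_logreg",
    "tsne_embed",
]


@dataclass
class FeatureMatrix:
    """Cells x features with labels.

    ``X`` holds ready-to-use feature columns. When ``density_maps`` is set
    (cells x 10000 flattened maps), those are reduced to ``n_pc`` principal
    components *inside* each cross-validation fold and appended to ``X``.
    """

    X: np.ndarray
    labels: np.ndarray
    feature_names: list = field(default_factory=list)
    modality: str = "generic"
    density_maps: np.ndarray | None = None
    n_pc: int = 10

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X and labels disagree on the number of cells")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if self.density_maps is not None:
            self.density_maps = np.asarray(self.density_maps, dtype=float)
            if self.density_maps.shape[0] != self.X.shape[0]:
                raise ValueError("density_maps and X disagree on the number of cells")


@dataclass
class ClassifierConfig:
    alpha: float = 0.5  # elastic-net mixing: 1 = lasso, 0 = ridge
    inner_folds: int = 5
    outer_folds: int = 5
    outer_repeats: int = 10
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    seed: int = 43  # outer splitter seed
    inner_seed: int = 42

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.inner_folds < 2 or self.outer_folds < 2:
            raise ValueError("folds must be >= 2")


def build_morpho_features(
    maps: np.ndarray, stats: pd.DataFrame | np.ndarray, labels, n_pc: int = 10
) -> FeatureMatrix:
    """Combine density maps (fold-wise PCA to ``n_pc`` components) with morphometrics.

    ``maps`` is cells x bins**2 (flattened density maps); ``stats`` the 16
    morphometrics per cell. The PCA itself is deferred to the
    cross-validation loop; here the inputs are validated and packaged.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 3:
        maps = maps.reshape(maps.shape[0], -1)
    stats_arr = np.asarray(stats, dtype=float)
    if maps.shape[0] != stats_arr.shape[0]:
        raise ValueError("maps and stats must describe the same cells")
    if n_pc > min(maps.shape):
        raise ValueError(f"n_pc={n_pc} exceeds the rank bound {min(maps.shape)}")
    names = list(stats.columns) if isinstance(stats, pd.DataFrame) else [
        f"stat{i}" for i in range(stats_arr.shape[1])
    ]
    return FeatureMatrix(
        X=stats_arr,
        labels=np.asarray(labels),
        feature_names=names,
        modality="morphology",
        density_maps=maps,
        n_pc=n_pc,
    )


def build_morpho_tsne_features(maps: np.ndarray, stats: np.ndarray, n_pc: int = 10) -> np.ndarray:
    """20-dim morphology representation for t-SNE.

    Density maps and morphometrics are each reduced to ``n_pc`` principal
    components; each set is scaled by the standard deviation of its own
    PC1 so the two sets are roughly on the same scale, then stacked.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 3:
        maps = maps.reshape(maps.shape[0], -1)
    out = []
    for block in (maps, np.asarray(stats, dtype=float)):
        z = PCA(n_components=n_pc, svd_solver="full").fit_transform(block)
        out.append(z / z[:, 0].std())
    return np.hstack(out)


# ---------------------------------------------------------------------------
# ephys feature preprocessing

_TSNE_DROP = ("adp", "latency")


def preprocess_ephys(features: pd.DataFrame, purpose: str) -> pd.DataFrame:
    """Prepare the 13-feature table for embedding or classification.

    ``purpose='tsne'``: drop ADP and latency (zero-inflated / outlier-heavy
    columns), log-transform the adaptation index, z-score the remaining 11
    columns. ``purpose='classify'``: keep all 13 columns with the
    adaptation index and latency log-transformed (standardization happens
    inside the classifier fits).
    """
    df = features.copy()
    if df.isna().any().any():
        raise ValueError("feature table contains missing values")
    for col in ("adaptation_index", "latency") if purpose == "classify" else ("adaptation_index",):
        if (df[col] <= 0).any():
            raise ValueError(f"non-positive values in {col}: cannot log-transform")
        df[col] = np.log(df[col])
    if purpose == "tsne":
        df = df.drop(columns=list(_TSNE_DROP))
        sd = df.std(ddof=0)
        # constant columns up to floating-point rounding
        zero = sd.index[sd <= 1e-10 * (df.abs().mean() + 1.0)].tolist()
        if zero:
            raise ValueError(f"zero-variance feature columns: {zero}")
        df = (df - df.mean()) / sd
    elif purpose != "classify":
        raise ValueError("purpose must be 'tsne' or 'classify'")
    return df


# ---------------------------------------------------------------------------
# elastic-net logistic regression with nested CV


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return tuple((a - mu) / sd for a in (train, *others))


def _lambda_path(X: np.ndarray, y: np.ndarray, alpha: float, n: int, min_ratio: float):
    p = y.mean()
    resid = y - p
    lam_max = np.abs(X.T @ resid).max() / (len(y) * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n)


def fit_elastic_net_logreg(
    X: np.ndarray, y: np.ndarray, alpha: float, lam: float, model: LogisticRegression | None = None
) -> LogisticRegression:
    """Single elastic-net logistic fit at penalty ``lam`` (glmnet scale).

    The glmnet objective (1/n) sum(loss) + lam * (alpha |w|_1 +
    (1-alpha)/2 |w|^2) maps onto scikit-learn's C as C = 1/(n*lam).
    Passing ``model`` reuses it warm-started along a path.
    """
    C = 1.0 / (len(y) * lam)
    if model is None:
        model = LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            warm_start=True,
            max_iter=3000,
            tol=1e-5,
            random_state=0,
        )
    model.C = C
    model.fit(X, y)
    return model


def _choose_lambda_1se(Xtr, ytr, cfg: ClassifierConfig) -> float:
    """Inner-CV lambda by the one-standard-error rule on the deviance."""
    lambdas = _lambda_path(Xtr, ytr, cfg.alpha, cfg.n_lambda, cfg.lambda_min_ratio)
    skf = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True, random_state=cfg.inner_seed)
    losses = np.zeros((cfg.inner_folds, len(lambdas)))
    for f, (itr, ival) in enumerate(skf.split(Xtr, ytr)):
        Xi, Xv = _standardize(Xtr[itr], Xtr[ival])
        yi, yv = ytr[itr], ytr[ival]
        model = None
        for j, lam in enumerate(lambdas):
            model = fit_elastic_net_logreg(Xi, yi, cfg.alpha, lam, model)
            prob = model.predict_proba(Xv)[:, 1]
            losses[f, j] = log_loss(yv, prob, labels=[0, 1])
    mean = losses.mean(axis=0)
    se = losses.std(axis=0, ddof=1) / np.sqrt(cfg.inner_folds)
    best = int(np.argmin(mean))
    ok = np.flatnonzero(mean <= mean[best] + se[best])
    # lambdas are descending: the first qualifying index is the largest lambda
    return float(lambdas[ok[0]])


def nested_cv_predictions(fm: FeatureMatrix, type_a, type_b, cfg: ClassifierConfig | None = None):
    """Per-outer-fold nested-CV results for one type pair.

    Returns a list of dicts with keys ``test_idx``, ``y_true``, ``y_pred``,
    ``lambda_``, ``coef`` — one per outer split. Useful both for scoring
    and for auditing that held-out cells do not leak into the fits.
    """
    cfg = cfg or ClassifierConfig()
    mask = np.isin(fm.labels, [type_a, type_b])
    X = fm.X[mask]
    maps = fm.density_maps[mask] if fm.density_maps is not None else None
    y = (fm.labels[mask] == type_b).astype(int)
    for cls, n in zip([type_a, type_b], np.bincount(y, minlength=2)[[0, 1]]):
        if n < cfg.outer_folds:
            raise ValueError(f"class {cls!r} has {n} cells, fewer than {cfg.outer_folds} folds")
    rskf = RepeatedStratifiedKFold(
        n_splits=cfg.outer_folds, n_repeats=cfg.outer_repeats, random_state=cfg.seed
    )
    results = []
    for tr, te in rskf.split(X, y):
        Xtr, Xte = X[tr], X[te]
        if maps is not None:
            pca = PCA(n_components=fm.n_pc, svd_solver="randomized", random_state=0)
            ptr = pca.fit_transform(maps[tr])
            pte = pca.transform(maps[te])
            Xtr = np.hstack([Xtr, ptr])
            Xte = np.hstack([Xte, pte])
        lam = _choose_lambda_1se(Xtr, y[tr], cfg)
        Xtr_s, Xte_s = _standardize(Xtr, Xte)
        model = fit_elastic_net_logreg(Xtr_s, y[tr], cfg.alpha, lam)
        results.append(
            {
                "test_idx": te,
                "y_true": y[te],
                "y_pred": model.predict(Xte_s),
                "lambda_": lam,
                "coef": model.coef_.ravel().copy(),
            }
        )
    return results


def pairwise_accuracy(fm: FeatureMatrix, type_a, type_b, cfg: ClassifierConfig | None = None) -> float:
    """Mean held-out accuracy over all outer splits for one type pair."""
    res = nested_cv_predictions(fm, type_a, type_b, cfg)
    accs = [np.mean(r["y_true"] == r["y_pred"]) for r in res]
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# t-SNE


def tsne_embed(
    X: np.ndarray,
    perplexity: float = 15.0,
    seed: int = 42,
    early_exaggeration: float = 4.0,
) -> np.ndarray:
    """Exact-gradient t-SNE with random initialization at a fixed seed."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= 3 * perplexity:
        raise ValueError("perplexity too large for the sample size")
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        method="exact",
        init="random",
        random_state=seed,
        early_exaggeration=early_exaggeration,
    )
    return ts.fit_transform(X)
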