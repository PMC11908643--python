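"""The two-layer blending learner.

Blending trains three heterogeneous base regressors — epsilon-SVR with
an RBF kernel, a regression tree, and elastic net with a cross-validated
penalty — on the non-holdout part of the training set, then fits a
linear meta-model (ordinary least squares with intercept) on the base
learners' predictions over the holdout.  Each layer is trained once.

ssBlending differs only in how the holdout is chosen: simple random
sampling (conventional blending) is replaced by stratified sampling,
with strata from k-means clusters of the genotypes (CA) or from
phenotype-density intervals (PP); see :mod:`ssblend.stratify`.

The holdout rate H is the fraction of the training set that forms the
meta-training (holdout) set; base learners see the remaining 1 - H.
Genotype features are standardized with base-train statistics only, so
no holdout or test information leaks into the base fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .dataio import GenotypeMatrix, PhenotypeVector
from .exceptions import LearnerError, SizeError
from .stratify import (
    StratifyConfig,
    random_sample,
    stratified_sample,
    stratify_ca,
    stratify_pp,
)

__all__ = [
    "BlendConfig",
    "BaseModelBundle",
    "MetaModel",
    "BlendEnsemble",
    "split_holdout",
    "fit_base_learners",
    "make_meta_features",
    "fit_meta",
    "fit_blending",
    "predict",
    "BASE_LEARNER_ORDER",
]

#: fixed column order of base-learner predictions in the meta design
BASE_LEARNER_ORDER = ("svr", "tree", "enet")


@dataclass(frozen=True)
class BlendConfig:
    """Configuration of one blending fit.

    h : holdout rate in (0, 1) — the fraction of the training set used
        to train the meta-learner.
    stratify : how the holdout is drawn (random / CA / PP, K layers).
    base_learner_settings : optional per-learner hyperparameter
        overrides, keyed by ``"svr"``/``"tree"``/``"enet"``.
    seed : controls the holdout draw and any stochastic learner.
    """

    h: float = 0.3
    stratify: StratifyConfig = field(default_factory=StratifyConfig)
    base_learner_settings: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.h < 1.0:
            raise ValueError(f"holdout rate h must be in (0, 1), got {self.h}")


@dataclass
class BaseModelBundle:
    """Three fitted base regressors, tagged svr/tree/enet."""

    svr_model: object
    tree_model: object
    enet_model: object
    n_features: int

    def model(self, tag: str):
        return {"svr": self.svr_model, "tree": self.tree_model,
                "enet": self.enet_model}[tag]


@dataclass
class MetaModel:
    """The linear meta-learner: intercept + one coefficient per base learner."""

    intercept: float
    coefficients: np.ndarray  # aligned to BASE_LEARNER_ORDER

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(BASE_LEARNER_ORDER),):
            raise ValueError("meta model needs one coefficient per base learner")
        if not (np.isfinite(self.intercept) and np.isfinite(self.coefficients).all()):
            raise ValueError("meta coefficients must be finite")

    def apply(self, meta_features: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(meta_features, float) @ self.coefficients


@dataclass
class BlendEnsemble:
    """A fitted blending ensemble (base bundle + meta model + provenance)."""

    bundle: BaseModelBundle
    meta: MetaModel
    config: BlendConfig
    holdout_idx: np.ndarray
    base_train_idx: np.ndarray
    feature_means: np.ndarray
    feature_scales: np.ndarray
    marker_ids: list | None = None

    def predict(self, G_new) -> np.ndarray:
        return predict(self, G_new)


def split_holdout(train_idx, config: BlendConfig, G: GenotypeMatrix,
                  y: PhenotypeVector):
    """Partition the training indices into (holdout, base-train).

    The holdout is drawn by simple random sampling or by the configured
    stratified strategy, always restricted to ``train_idx``.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    n_train = train_idx.size
    if n_train < 10:
        raise SizeError(f"need at least 10 training rows to blend, got {n_train}")
    strategy = config.stratify.strategy
    if strategy == "random":
        rel = random_sample(n_train, config.h, seed=config.seed)
    elif strategy == "ca":
        assignment = stratify_ca(G.take(train_idx), config.stratify)
        rel = stratified_sample(assignment, config.h, seed=config.seed)
    elif strategy == "pp":
        assignment = stratify_pp(y.take(train_idx), config.stratify)
        rel = stratified_sample(assignment, config.h, seed=config.seed)
    else:  # pragma: no cover - guarded by StratifyConfig
        raise ValueError(f"unknown strategy {strategy!r}")
    holdout_idx = train_idx[rel]
    base_train_idx = np.setdiff1d(train_idx, holdout_idx)
    if holdout_idx.size == 0 or base_train_idx.size == 0:
        raise SizeError(
            f"holdout rate h={config.h} leaves an empty partition "
            f"({holdout_idx.size} holdout / {base_train_idx.size} base-train)"
        )
    return holdout_idx, base_train_idx


def _default_learners(n_features: int, seed: int, settings: dict):
    svr_kw = dict(kernel="rbf", C=1.0, epsilon=0.1, gamma="auto")
    tree_kw = dict(random_state=seed)
    enet_kw = dict(l1_ratio=0.5, cv=5, eps=1e-4, alphas=100, random_state=seed,
                   max_iter=5000)
    svr_kw.update(settings.get("svr", {}))
    tree_kw.update(settings.get("tree", {}))
    enet_kw.update(settings.get("enet", {}))
    return SVR(**svr_kw), DecisionTreeRegressor(**tree_kw), ElasticNetCV(**enet_kw)


def fit_base_learners(X: np.ndarray, y: np.ndarray, settings: dict | None = None,
                      seed: int = 0) -> BaseModelBundle:
    """Fit the three base regressors on (already standardized) features.

    Defaults follow the conventions of the reference implementations:
    epsilon-SVR with RBF kernel (C=1, epsilon=0.1, gamma=1/m), a CART
    regression tree, and elastic net with mixing 0.5 and the penalty
    chosen by internal 5-fold cross-validation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 5:
        raise SizeError(f"need at least 5 rows to fit base learners, got {X.shape[0]}")
    settings = settings or {}
    svr, tree, enet = _default_learners(X.shape[1], seed, settings)
    fitted = {}
    for tag, model in zip(BASE_LEARNER_ORDER, (svr, tree, enet)):
        try:
            if tag == "enet" and np.ptp(y) == 0.0:
                # a constant response makes the CV path degenerate; pin
                # the penalty so the fit returns the constant cleanly
                model = ElasticNet(alpha=1.0, l1_ratio=0.5)
            model.fit(X, y)
        except Exception as exc:
            raise LearnerError(f"base learner {tag!r} failed to fit: {exc}") from exc
        fitted[tag] = model
    return BaseModelBundle(svr_model=fitted["svr"], tree_model=fitted["tree"],
                           enet_model=fitted["enet"], n_features=X.shape[1])


def make_meta_features(bundle: BaseModelBundle, X: np.ndarray) -> np.ndarray:
    """Stack base-learner predictions as columns (svr, tree, enet)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != bundle.n_features:
        raise ValueError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"bundle was trained on {bundle.n_features}"
        )
    cols = [bundle.model(tag).predict(X) for tag in BASE_LEARNER_ORDER]
    out = np.column_stack(cols)
    if not np.isfinite(out).all():
        raise LearnerError("a base learner produced non-finite predictions")
    return out


def fit_meta(meta_features: np.ndarray, y_holdout: np.ndarray) -> MetaModel:
    """Ordinary least squares of the holdout response on base predictions.

    Rank-deficient designs (strongly correlated base learners) resolve
    to the minimum-norm solution rather than failing.
    """
    F = np.asarray(meta_features, dtype=float)
    y = np.asarray(y_holdout, dtype=float)
    if F.ndim != 2 or F.shape[1] != len(BASE_LEARNER_ORDER):
        raise ValueError("meta features must be an n x 3 matrix")
    if F.shape[0] < 2:
        raise SizeError(f"need at least 2 holdout rows to fit the meta model, got {F.shape[0]}")
    design = np.column_stack([np.ones(F.shape[0]), F])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MetaModel(intercept=float(coef[0]), coefficients=coef[1:])


def fit_blending(G: GenotypeMatrix, y: PhenotypeVector, train_idx,
                 config: BlendConfig) -> BlendEnsemble:
    """Fit a full blending ensemble on ``train_idx`` rows of (G, y).

    Pipeline: draw the holdout (random or stratified) → standardize
    features on base-train statistics → fit the three base learners on
    base-train → compute their predictions on the holdout → fit the OLS
    meta-model.  Each layer is trained exactly once.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    holdout_idx, base_train_idx = split_holdout(train_idx, config, G, y)
    X_bt = G.dosages[base_train_idx]
    mu = X_bt.mean(axis=0)
    sd = X_bt.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    Z_bt = (X_bt - mu) / sd
    bundle = fit_base_learners(Z_bt, y.values[base_train_idx],
                               settings=config.base_learner_settings,
                               seed=config.seed)
    Z_ho = (G.dosages[holdout_idx] - mu) / sd
    meta_feats = make_meta_features(bundle, Z_ho)
    meta = fit_meta(meta_feats, y.values[holdout_idx])
    return BlendEnsemble(bundle=bundle, meta=meta, config=config,
                         holdout_idx=holdout_idx, base_train_idx=base_train_idx,
                         feature_means=mu, feature_scales=sd,
                         marker_ids=list(G.marker_ids))


def predict(ensemble: BlendEnsemble, G_new) -> np.ndarray:
    """Apply a fitted ensemble to new genotypes (matrix or ndarray rows)."""
    if isinstance(G_new, GenotypeMatrix):
        if ensemble.marker_ids is not None and list(G_new.marker_ids) != list(ensemble.marker_ids):
            missing = sorted(set(ensemble.marker_ids) - set(G_new.marker_ids))[:5]
            raise ValueError(
                f"marker set does not match training markers; "
                f"first missing/misordered: {missing or 'order differs'}"
            )
        X = G_new.dosages
    else:
        X = np.asarray(G_new, dtype=float)
    if X.shape[1] != ensemble.feature_means.size:
        raise ValueError(
            f"expected {ensemble.feature_means.size} markers, got {X.shape[1]}"
        )
    Z = (X - ensemble.feature_means) / ensemble.feature_scales
    return ensemble.meta.apply(make_meta_features(ensemble.bundle, Z))
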