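"""scikit-learn style estimators over the fusion pipeline.

``MorphometricExtractor`` and ``ProjectionTransformer`` turn lists of
:class:`~neurofuse.swc.NeuronTree` into model-ready arrays;
``NeuroFuseClassifier`` wraps feature extraction plus the fusion network in
a fit/predict estimator that composes with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .morphometrics import METRIC_NAMES, compute_feature_vector
from .net import FusionConfig, TrainConfig
from .projection import project
from .swc import NeuronTree
from .train_eval import fit, predict_proba_batched

__all__ = ["MorphometricExtractor", "ProjectionTransformer", "NeuroFuseClassifier"]


class MorphometricExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: list of NeuronTree -> (n, 43) morphometric array."""

    def fit(self, X, y=None):
        self.n_features_out_ = len(METRIC_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack([compute_feature_vector(t).values for t in X])

    def get_feature_names_out(self, input_features=None):
        return np.array(METRIC_NAMES)


class ProjectionTransformer(TransformerMixin, BaseEstimator):
    """Stateless transformer: list of NeuronTree -> (n, 3, H, W) stacks."""

    def __init__(self, resolution: int = 224, pad_fraction: float = 0.05):
        self.resolution = resolution
        self.pad_fraction = pad_fraction

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack(
            [
                project(t, resolution=self.resolution, pad_fraction=self.pad_fraction).pixels
                for t in X
            ]
        )


class NeuroFuseClassifier(ClassifierMixin, BaseEstimator):
    """Fusion-network neuron-type classifier with the sklearn estimator API.

    ``fit(X, y)`` takes a list of NeuronTree (features and projections are
    extracted internally) or a ``(morphometrics, image_stacks)`` tuple of
    arrays.  Morphometrics are z-scored with statistics learned from the
    training data when ``standardize_features`` is on.
    """

    def __init__(
        self,
        backbone: str = "tiny",
        n_classes: int | None = None,
        epochs: int = 100,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        n_groups: int = 3,
        use_fem: bool = True,
        use_fim: bool = True,
        use_mlfm: bool = True,
        fusion_strategy: str = "sum",
        fim_tokens: int = 4,
        dropout: float = 0.5,
        input_resolution: int | None = None,
        standardize_features: bool = True,
        branch: str = "both",
        random_state: int = 0,
    ):
        self.backbone = backbone
        self.n_classes = n_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_groups = n_groups
        self.use_fem = use_fem
        self.use_fim = use_fim
        self.use_mlfm = use_mlfm
        self.fusion_strategy = fusion_strategy
        self.fim_tokens = fim_tokens
        self.dropout = dropout
        self.input_resolution = input_resolution
        self.standardize_features = standardize_features
        self.branch = branch
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _config(self, n_classes: int) -> FusionConfig:
        return FusionConfig(
            backbone=self.backbone,
            n_classes=n_classes,
            n_groups=self.n_groups,
            use_fem=self.use_fem,
            use_fim=self.use_fim,
            use_mlfm=self.use_mlfm,
            fusion_strategy=self.fusion_strategy,
            fim_tokens=self.fim_tokens,
            dropout=self.dropout,
            input_resolution=self.input_resolution,
            standardize_features=self.standardize_features,
            branch=self.branch,
        )

    def _extract(self, X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, tuple) and len(X) == 2:
            return np.asarray(X[0], dtype=float), np.asarray(X[1], dtype=float)
        if len(X) and isinstance(X[0], NeuronTree):
            cfg_res = self.input_resolution or FusionConfig(
                backbone=self.backbone, n_classes=2
            ).input_resolution
            feats = MorphometricExtractor().fit_transform(X)
            imgs = ProjectionTransformer(resolution=cfg_res).fit_transform(X)
            return feats, imgs
        raise TypeError(
            "X must be a list of NeuronTree or a (morphometrics, images) tuple"
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        feats, imgs = self._extract(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n_classes = self.n_classes or len(self.classes_)
        if n_classes < len(self.classes_):
            raise ValueError("n_classes smaller than the number of labels seen")
        if self.standardize_features:
            self.feature_mean_ = feats.mean(axis=0)
            sd = feats.std(axis=0)
            sd[sd == 0] = 1.0
            self.feature_scale_ = sd
            feats = (feats - self.feature_mean_) / self.feature_scale_
        tc = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.random_state,
        )
        self.model_, self.history_ = fit(
            self._config(n_classes), feats, imgs, y_enc, tc
        )
        self.n_features_in_ = feats.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        feats, imgs = self._extract(X)
        if self.standardize_features:
            feats = (feats - self.feature_mean_) / self.feature_scale_
        return predict_proba_batched(self.model_, feats, imgs)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]
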