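"""scikit-learn style estimator wrappers over the model family.

These wrappers make the trainable models compose with sklearn model
selection and pipelines: hyperparameters are constructor arguments exposed
through ``get_params``/``set_params``, fitting populates trailing-
underscore attributes, and classification wrappers implement
``predict_proba``/``predict`` against ``classes_``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nets

__all__ = ["FFCNClassifier", "BNAImageClassifier", "UnetSegmenter"]


class FFCNClassifier(BaseEstimator, ClassifierMixin):
    """Feed-forward classifier on numeric feature vectors (widths
    16-32-64-128-64-32-16, dropout after each hidden layer)."""

    def __init__(self, epochs: int = 50, learning_rate: float = 1e-3,
                 batch_size: int = 32, dropout_rate: float = 0.2,
                 seed: int = 0):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.dropout_rate = dropout_rate
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        model = nets.build_ffcn(X.shape[1], dropout_rate=self.dropout_rate,
                                seed=self.seed)
        self.model_, self.history_ = nets.train_classifier(
            model, (X, y_idx), epochs=self.epochs, seed=self.seed,
            lr=self.learning_rate, batch_size=self.batch_size)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=np.float32))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class BNAImageClassifier(BaseEstimator, ClassifierMixin):
    """Encoder + attention-bottleneck image classifier.

    ``X`` is an (n, side, side, channels) float array in [0, 1].
    """

    def __init__(self, input_side: int = 64, input_channels: int = 3,
                 base_channels: int = 8, encoder_stages: int = 3,
                 channel_cap: int = 32, bna_out_channels: int = 4,
                 fc_widths: tuple[int, int] = (32, 16),
                 epochs: int = 20, learning_rate: float = 1e-3,
                 batch_size: int = 8, seed: int = 0):
        self.input_side = input_side
        self.input_channels = input_channels
        self.base_channels = base_channels
        self.encoder_stages = encoder_stages
        self.channel_cap = channel_cap
        self.bna_out_channels = bna_out_channels
        self.fc_widths = fc_widths
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    def _config(self) -> nets.ArchConfig:
        return nets.ArchConfig(
            input_side=self.input_side, input_channels=self.input_channels,
            base_channels=self.base_channels,
            encoder_stages=self.encoder_stages, channel_cap=self.channel_cap,
            bna_out_channels=self.bna_out_channels,
            fc_widths=tuple(self.fc_widths), seed=self.seed)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        model = nets.build_binary_classifier(self._config())
        self.model_, self.history_ = nets.train_classifier(
            model, (X, y_idx), epochs=self.epochs, seed=self.seed,
            lr=self.learning_rate, batch_size=self.batch_size)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=np.float32))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class UnetSegmenter(BaseEstimator, TransformerMixin):
    """Attention-bottleneck U-net segmenter trained with Dice loss.

    ``X`` is (n, side, side, 3) in [0, 1]; targets ``Y`` are
    (n, side, side, 3) masks (disc, cup, fovea planes).
    """

    def __init__(self, input_side: int = 64, base_channels: int = 8,
                 encoder_stages: int = 3, channel_cap: int = 32,
                 bna_out_channels: int = 4, epochs: int = 30,
                 learning_rate: float = 1e-3, batch_size: int = 8,
                 seed: int = 0):
        self.input_side = input_side
        self.base_channels = base_channels
        self.encoder_stages = encoder_stages
        self.channel_cap = channel_cap
        self.bna_out_channels = bna_out_channels
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X, Y):
        cfg = nets.ArchConfig(
            input_side=self.input_side, base_channels=self.base_channels,
            encoder_stages=self.encoder_stages, channel_cap=self.channel_cap,
            bna_out_channels=self.bna_out_channels, heads=("segmentation",),
            seed=self.seed)
        model = nets.build_lwbna_unet(cfg)
        self.model_, self.history_ = nets.train_segmenter(
            model, (np.asarray(X, np.float32), np.asarray(Y, np.float32)),
            epochs=self.epochs, seed=self.seed, lr=self.learning_rate,
            batch_size=self.batch_size)
        return self

    def transform(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=np.float32))

    predict = transform
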