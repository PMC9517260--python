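"""scikit-learn estimator interfaces over the pipeline stages.

``WaveletSmoother`` and ``WindowNormalizer`` are transformers and
``HierarchicalEnsembleClassifier`` a classifier, so the full method
composes as an sklearn ``Pipeline``::

    Pipeline([
        ("wavelet", WaveletSmoother()),
        ("norm", WindowNormalizer()),
        ("clf", HierarchicalEnsembleClassifier(max_epochs=50)),
    ]).fit(X, y)

All three accept windows as 4-D arrays (n_windows, T, S sensors, C
channels).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data import WindowedDataset
from .losses import LossConfig
from .nn import NetworkSpec, build_model
from .train import TrainConfig, predict_proba, split_holdout, train
from .wavelet import WaveletConfig, smooth_array


def _check_windows(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 4:
        raise ValueError(
            f"expected windows of shape (n, T, S, C); got ndim={X.ndim}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    return X


class WaveletSmoother(TransformerMixin, BaseEstimator):
    """Discrete-wavelet low-pass smoothing of each window channel.

    Keeps the level-``level`` approximation coefficients and discards the
    detail, shrinking the time axis (50 -> 28 with the 8-tap default).
    Stateless; ``fit`` only records the input geometry.
    """

    def __init__(self, wavelet: str = "db4", level: int = 1,
                 padding: str = "symmetric") -> None:
        self.wavelet = wavelet
        self.level = level
        self.padding = padding

    def _config(self) -> WaveletConfig:
        return WaveletConfig(self.wavelet, self.level, self.padding)

    def fit(self, X, y=None):
        X = _check_windows(X)
        self._config()  # validate parameters
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        return smooth_array(_check_windows(X), self._config())


class WindowNormalizer(TransformerMixin, BaseEstimator):
    """Per-(sensor, channel) z-scoring with statistics frozen at fit time.

    Fitted attributes ``mean_`` and ``std_`` have shape (S, C); channels
    with (near-)zero variance transform to 0.
    """

    def fit(self, X, y=None):
        X = _check_windows(X)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty set of windows")
        self.mean_ = X.mean(axis=(0, 1), dtype=np.float64)
        self.std_ = X.std(axis=(0, 1), dtype=np.float64)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mean_")
        X = _check_windows(X)
        safe = np.where(self.std_ > 1e-12, self.std_, 1.0)
        out = (X - self.mean_) / safe
        return np.where(self.std_ > 1e-12, out, 0.0)


class HierarchicalEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Hierarchical ensemble network classifier for windowed sensor data.

    Per-channel LSTM + 1-D convolution extractors, per-sensor and
    cross-sensor 2-D convolutional fusion, and a dense softmax head,
    trained with focal loss (default, ``alpha = 0.25``, ``gamma = 2``) or
    cross-entropy using Adam. A stratified fraction of the training data
    is held out to drive early stopping.

    Expects preprocessed (wavelet-smoothed, normalized) windows of shape
    (n, T, S, C); architecture geometry is inferred from the data at fit
    time, everything else from the constructor parameters.
    """

    def __init__(
        self,
        lstm_units: int = 32,
        conv1d_filters: int = 8,
        conv1d_kernel: int = 5,
        conv2d_sensor_filters: int = 8,
        conv2d_fused_filters: int = 32,
        conv2d_kernel: tuple[int, int] = (3, 3),
        head: tuple[int, ...] = (64, 32, 16, 8),
        dropout: float = 0.5,
        loss: str = "focal",
        alpha: float = 0.25,
        gamma: float = 2.0,
        learning_rate: float = 2e-4,
        batch_size: int = 128,
        max_epochs: int = 200,
        patience: int = 10,
        validation_fraction: float = 0.2,
        random_state: int = 0,
    ) -> None:
        self.lstm_units = lstm_units
        self.conv1d_filters = conv1d_filters
        self.conv1d_kernel = conv1d_kernel
        self.conv2d_sensor_filters = conv2d_sensor_filters
        self.conv2d_fused_filters = conv2d_fused_filters
        self.conv2d_kernel = conv2d_kernel
        self.head = head
        self.dropout = dropout
        self.loss = loss
        self.alpha = alpha
        self.gamma = gamma
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _loss_config(self) -> LossConfig:
        if self.loss == "cross_entropy":
            return LossConfig.cross_entropy()
        return LossConfig(kind=self.loss, alpha=self.alpha, gamma=self.gamma)

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on windows ``X`` with labels ``y``.

        If no explicit validation set is given, a stratified
        ``validation_fraction`` of (X, y) is held out for early stopping.
        """
        X = _check_windows(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y must share the leading dimension")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        _, t_in, S, C = X.shape
        spec = NetworkSpec(
            t_in=t_in,
            n_sensors=S,
            n_channels=C,
            lstm_units=self.lstm_units,
            conv1d_filters=self.conv1d_filters,
            conv1d_kernel=self.conv1d_kernel,
            conv2d_sensor_filters=self.conv2d_sensor_filters,
            conv2d_fused_filters=self.conv2d_fused_filters,
            conv2d_kernel=tuple(self.conv2d_kernel),
            head=tuple(self.head),
            dropout=self.dropout,
            n_classes=len(self.classes_),
        )
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            split_fraction=1.0 - self.validation_fraction,
            seed=self.random_state,
        )
        names = [str(c) for c in self.classes_]
        ds = WindowedDataset(X, y_idx, names, t_in, step=t_in)
        if X_val is not None:
            train_ds = ds
            yv = np.searchsorted(self.classes_, np.asarray(y_val))
            val_ds = WindowedDataset(
                _check_windows(X_val), yv, names, t_in, step=t_in)
        else:
            train_ds, val_ds = split_holdout(ds, cfg)
        self.model_ = build_model(spec, seed=self.random_state)
        self.history_ = train(
            self.model_, train_ds, val_ds, loss=self._loss_config(), cfg=cfg)
        self.n_iter_ = len(self.history_)
        self.spec_ = spec
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return predict_proba(self.model_, _check_windows(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
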