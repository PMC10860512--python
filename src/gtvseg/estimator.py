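"""scikit-learn style estimator facade over the attention U-Net trainer.

``AttentionUNetSegmenter`` treats each 2D slice as one sample: ``X`` is an
array (n_samples, H, W) of window-normalized images in [0, 1] and ``y`` the
matching binary masks.  ``fit`` trains with the soft-Dice loss, ``predict``
returns thresholded masks, ``predict_proba`` the per-pixel foreground
probabilities, and ``score`` the mean hard Dice.  ``warm_start=True`` makes
a second ``fit`` continue from the current weights, which is exactly the
transfer-learning protocol; the module-level ``train``/``fine_tune``
functions in :mod:`gtvseg.training` are the cohort-aware wrappers.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .nn.unet import AttentionUNet, NetworkConfig
from .training import TrainConfig, dice_loss, fit_network


class AttentionUNetSegmenter(BaseEstimator):
    """Binary slice segmenter with a fit/predict interface.

    Parameters mirror :class:`NetworkConfig` and :class:`TrainConfig`;
    fitted state lives in ``model_`` (the network) and ``history_``.
    """

    def __init__(
        self,
        input_size: int = 64,
        depth: int = 3,
        base_channels: int = 8,
        use_attention: bool = True,
        leaky_alpha: float = 0.1,
        learning_rate: float = 1e-3,
        epochs: int = 40,
        batch_size: int = 6,
        smooth: float = 1.0,
        early_stop_patience: int | None = None,
        threshold: float = 0.5,
        warm_start: bool = False,
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.depth = depth
        self.base_channels = base_channels
        self.use_attention = use_attention
        self.leaky_alpha = leaky_alpha
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.smooth = smooth
        self.early_stop_patience = early_stop_patience
        self.threshold = threshold
        self.warm_start = warm_start
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_X(self, X, check_range=True):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, H, W)")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(
                f"slice size {X.shape[1]}x{X.shape[2]} does not match input_size {self.input_size}"
            )
        if check_range and (X.min() < -1e-6 or X.max() > 1 + 1e-6):
            raise ValueError("X must be window-normalized to [0, 1]")
        return X

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            input_size=self.input_size,
            depth=self.depth,
            base_channels=self.base_channels,
            leaky_alpha=self.leaky_alpha,
            use_attention=self.use_attention,
            seed=self.random_state,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on slices; optional (X_val, y_val) drives best-epoch selection."""
        X = self._validate_X(X)
        y = np.asarray(y, dtype=np.float32)
        if y.shape != X.shape:
            raise ValueError("y must have the same shape as X")
        if not (self.warm_start and hasattr(self, "model_")):
            self.model_ = AttentionUNet(self.network_config())
        cfg = TrainConfig(
            epochs_max=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.random_state,
            smooth=self.smooth,
            early_stop_patience=self.early_stop_patience,
            threshold=self.threshold,
        )
        if X_val is not None:
            X_val = self._validate_X(X_val)
            y_val = np.asarray(y_val, dtype=np.float32)
        self.history_ = fit_network(self.model_, X, y, cfg, X_val, y_val)
        self.n_iter_ = len(self.history_.train_loss)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        X = self._validate_X(X)
        out = []
        for i in range(0, len(X), 12):
            out.append(self.model_.forward(X[i:i + 12], train=False))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean hard Dice of thresholded predictions against y."""
        y = np.asarray(y, dtype=np.float64)
        pred = self.predict(X).astype(np.float64)
        inter = (pred * y).sum(axis=(1, 2))
        sums = pred.sum(axis=(1, 2)) + y.sum(axis=(1, 2))
        return float(np.mean(np.where(sums > 0, 2 * inter / np.maximum(sums, 1e-12), 1.0)))

    def loss(self, X, y) -> float:
        return dice_loss(self.predict_proba(X), np.asarray(y, dtype=np.float64), self.smooth)
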