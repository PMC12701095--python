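"""scikit-learn style estimators wrapping the segmentation models.

``LightweightSegmenter`` exposes the SegNet/SegDSC family through the
``fit``/``predict`` contract so it composes with sklearn pipelines and model
selection; ``OtsuSegmenter`` wraps the threshold baseline the same way.
Samples are 2-D grayscale ROIs stacked as ``(n, H, W)`` arrays; targets are
binary masks of the same shape.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .metrics import dice
from .models import PRESETS, ArchitectureConfig, build_model, otsu_segment
from .training import AugmentConfig, TrainConfig, train_segmenter

__all__ = ["LightweightSegmenter", "OtsuSegmenter"]


def _check_stack(X: np.ndarray, name: str = "X") -> np.ndarray:
    X = np.asarray(X)
    if X.ndim == 2:
        X = X[None]
    if X.ndim != 3:
        raise ValueError(f"{name} must be (n, H, W), got shape {X.shape}")
    return X


class LightweightSegmenter(BaseEstimator):
    """Trainable encoder-decoder mass segmenter (SegNet/SegDSC family).

    Parameters
    ----------
    architecture : str or ArchitectureConfig, default="segdsc4_90"
        Preset name (``segnet3``, ``segnet4``, ``segdsc3``, ``segdsc4``,
        ``segdsc4_85``, ``segdsc4_90``, ``segdsc4_95``) or explicit config.
    learning_rate : float, default=0.01
        Initial Adam learning rate (the from-scratch regime).
    plateau_factor, plateau_patience : float, int
        Learning-rate decay on validation-loss plateau (0.6 after 5 epochs).
    early_stop_patience : int, default=25
        Stop after this many epochs without validation improvement.
    max_epochs, batch_size : int
        Epoch cap (160) and minibatch size (16).
    validation_fraction : float, default=0.1
        Cases held out for the controllers when ``fit`` gets no explicit
        validation set.
    augment : AugmentConfig or None
        Paired geometric augmentation of training batches; None disables.
    random_state : int, default=0
        Seed for weight init, shuffling, splitting and augmentation.

    Attributes
    ----------
    network_ : SegNetwork
        The trained numpy network (best-validation weights).
    history_ : list of dict
        Per-epoch train/validation loss, validation Dice and learning rate.
    n_iter_ : int
        Number of epochs actually run.
    """

    def __init__(
        self,
        architecture: str | ArchitectureConfig = "segdsc4_90",
        learning_rate: float = 0.01,
        plateau_factor: float = 0.6,
        plateau_patience: int = 5,
        early_stop_patience: int = 25,
        max_epochs: int = 160,
        batch_size: int = 16,
        validation_fraction: float = 0.1,
        augment: AugmentConfig | None = None,
        threshold: float = 0.5,
        random_state: int = 0,
    ) -> None:
        self.architecture = architecture
        self.learning_rate = learning_rate
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.augment = augment
        self.threshold = threshold
        self.random_state = random_state

    def _config(self) -> ArchitectureConfig:
        if isinstance(self.architecture, ArchitectureConfig):
            return self.architecture
        return PRESETS[str(self.architecture).lower()]

    def fit(self, X, y, X_val=None, y_val=None, groups=None):
        """Train on aligned ROI/mask pairs ``X`` (n, H, W), ``y`` (n, H, W)."""
        X = _check_stack(X)
        y = _check_stack(np.asarray(y), "y")
        if X.shape != y.shape:
            raise ValueError(f"X and y shapes differ: {X.shape} vs {y.shape}")
        cfg = TrainConfig(
            initial_lr=self.learning_rate,
            plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience,
            early_stop_patience=self.early_stop_patience,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
            validation_fraction=self.validation_fraction,
            augment=self.augment,
        )
        net = build_model(self._config(), seed=self.random_state)
        net, history = train_segmenter(
            net, X, y, cfg, X_val=X_val, y_val=y_val, groups=groups
        )
        self.network_ = net
        self.history_ = history
        self.n_iter_ = len(history)
        self.input_side_ = X.shape[-1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel mass probabilities, shape (n, H, W) in (0, 1)."""
        self._check_fitted()
        X = _check_stack(X).astype(np.float32)
        if X.max(initial=0.0) > 1.0:
            X = X / 255.0
        out = []
        for s in range(0, X.shape[0], self.batch_size):
            out.append(self.network_.forward(X[s : s + self.batch_size], training=False)[:, 0])
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """Binary masks thresholded at ``threshold`` (default 0.5)."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean hard Dice coefficient over the samples."""
        y = _check_stack(np.asarray(y), "y")
        pred = self.predict(X)
        return float(np.mean([dice(p, t) for p, t in zip(pred, y)]))

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise AttributeError("this LightweightSegmenter instance is not fitted yet")


class OtsuSegmenter(BaseEstimator):
    """Threshold-based baseline: per-ROI Otsu split, brighter class = mass.

    ``fit`` only validates inputs (the method has nothing to learn), keeping
    the estimator drop-in compatible with the trainable segmenters.
    """

    def fit(self, X=None, y=None):
        if X is not None:
            _check_stack(X)
        self.fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        X = _check_stack(X)
        return np.stack([otsu_segment(np.asarray(x)) for x in X])

    def score(self, X, y) -> float:
        y = _check_stack(np.asarray(y), "y")
        pred = self.predict(X)
        return float(np.mean([dice(p, t) for p, t in zip(pred, y)]))
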