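"""Training procedure for the scratch segmentation models.

Networks are trained with Adam on the soft Dice loss at an initial learning
rate of 0.01, with two controllers watching the validation loss:

* plateau decay — after ``plateau_patience`` epochs without improvement the
  learning rate is multiplied by ``plateau_factor`` (0.6, i.e. a 40% cut);
* early stopping — training halts after ``early_stop_patience`` (25) stagnant
  epochs, or at ``max_epochs`` (160).

"Improvement" means a validation-loss decrease greater than ``min_delta``
(1e-4 absolute).  The weights attaining the best validation loss are restored
at the end.  Augmentation (rotation, crop, scale, flips) is applied to
training pairs only; the held-out test split is never augmented.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from .nn import Adam, soft_dice_loss_batch
from .metrics import dice
from .models import SegNetwork

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "PlateauController",
    "augment_pair",
    "train_segmenter",
    "split_by_group",
]


@dataclass(frozen=True)
class AugmentConfig:
    """Magnitudes of the random paired augmentations."""

    rotation_deg: float = 20.0
    crop_frac: float = 0.10
    scale_range: tuple[float, float] = (0.9, 1.1)
    hflip_p: float = 0.5
    vflip_p: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.hflip_p <= 1 and 0 <= self.vflip_p <= 1):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be (lo, hi) with lo <= hi")
        if not (0 <= self.crop_frac < 1):
            raise ValueError("crop_frac must lie in [0, 1)")

    @property
    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0
            and self.crop_frac == 0
            and self.scale_range == (1.0, 1.0)
            and self.hflip_p == 0
            and self.vflip_p == 0
        )


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the scratch-training procedure."""

    initial_lr: float = 0.01  # 0.0001 would be the pre-trained-weights regime
    plateau_factor: float = 0.6
    plateau_patience: int = 5
    early_stop_patience: int = 25
    max_epochs: int = 160
    batch_size: int = 16
    seed: int = 0
    min_delta: float = 1e-4
    validation_fraction: float = 0.1
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if not (0 < self.plateau_factor < 1):
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


class PlateauController:
    """Learning-rate plateau decay plus early stopping on one monitored loss.

    ``step(val_loss)`` returns ``(lr, reduced, stop)`` for the epoch just
    finished.  With stagnation from epoch 1, the first reduction fires at
    epoch ``1 + plateau_patience`` and the stop at epoch
    ``1 + early_stop_patience``.
    """

    def __init__(self, cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.lr = cfg.initial_lr
        self.best = np.inf
        self._since_best = 0
        self._since_reduce = 0

    def step(self, val_loss: float) -> tuple[float, bool, bool]:
        improved = val_loss < self.best - self.cfg.min_delta
        if improved:
            self.best = val_loss
            self._since_best = 0
            self._since_reduce = 0
        else:
            self._since_best += 1
            self._since_reduce += 1
        reduced = False
        if self._since_reduce >= self.cfg.plateau_patience:
            self.lr *= self.cfg.plateau_factor
            self._since_reduce = 0
            reduced = True
        stop = self._since_best >= self.cfg.early_stop_patience
        return self.lr, reduced, stop


# ---------------------------------------------------------------------------
# paired augmentation


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric transform identically to image and mask.

    Image resampling is bilinear, mask resampling nearest-neighbour with
    re-binarisation; the output keeps the input shape.  All randomness comes
    from ``rng``, so a fixed generator state reproduces the pair exactly.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    h, w = image.shape
    # draw every variate unconditionally so the stream is config-independent
    do_h = rng.random() < cfg.hflip_p
    do_v = rng.random() < cfg.vflip_p
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    scale = rng.uniform(*cfg.scale_range)
    crop = rng.uniform(0.0, cfg.crop_frac)

    img = image.astype(np.float64)
    msk = mask.astype(np.float64)
    if do_h:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if do_v:
        img, msk = img[::-1, :], msk[::-1, :]
    if angle != 0.0:
        img = _sk_rotate(img, angle, order=1, preserve_range=True)
        msk = _sk_rotate(msk, angle, order=0, preserve_range=True)
    if scale != 1.0:
        sh, sw = max(1, round(h * scale)), max(1, round(w * scale))
        img = _sk_resize(img, (sh, sw), order=1, anti_aliasing=False, preserve_range=True)
        msk = _sk_resize(msk, (sh, sw), order=0, anti_aliasing=False, preserve_range=True)
        if scale > 1.0:  # centre-crop back
            top, left = (sh - h) // 2, (sw - w) // 2
            img = img[top : top + h, left : left + w]
            msk = msk[top : top + h, left : left + w]
        else:  # centre-pad back
            out_i = np.zeros((h, w))
            out_m = np.zeros((h, w))
            top, left = (h - sh) // 2, (w - sw) // 2
            out_i[top : top + sh, left : left + sw] = img
            out_m[top : top + sh, left : left + sw] = msk
            img, msk = out_i, out_m
    if crop > 0.0:
        ch, cw = max(1, round(h * (1 - crop))), max(1, round(w * (1 - crop)))
        top, left = (h - ch) // 2, (w - cw) // 2
        img = _sk_resize(
            img[top : top + ch, left : left + cw], (h, w), order=1,
            anti_aliasing=False, preserve_range=True,
        )
        msk = _sk_resize(
            msk[top : top + ch, left : left + cw], (h, w), order=0,
            anti_aliasing=False, preserve_range=True,
        )
    out_img = img
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out_img = np.clip(np.rint(img), info.min, info.max)
    return out_img.astype(image.dtype), (msk > 0.5).astype(np.uint8)


def split_by_group(
    groups: Sequence, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index split holding out ``fraction`` of the distinct groups.

    Splitting by mammogram id (not by ROI) keeps all ROIs of one case on the
    same side and prevents leakage between splits.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    n_val = max(1, int(round(fraction * len(uniq)))) if len(uniq) > 1 else 0
    val_groups = set(uniq[perm[:n_val]].tolist())
    val_idx = np.flatnonzero([g in val_groups for g in groups])
    train_idx = np.flatnonzero([g not in val_groups for g in groups])
    return train_idx, val_idx


# ---------------------------------------------------------------------------
# training loop


def _as_batch(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3:
        X = X[:, None]
    return X


def _eval_network(
    net: SegNetwork, X: np.ndarray, y: np.ndarray, batch_size: int
) -> tuple[float, float]:
    """Validation soft-Dice loss and mean hard Dice, without augmentation."""
    losses, dices, n = [], [], X.shape[0]
    for s in range(0, n, batch_size):
        xb, yb = X[s : s + batch_size], y[s : s + batch_size]
        p = net.forward(xb, training=False)
        loss, _ = soft_dice_loss_batch(p, yb)
        losses.append(loss * xb.shape[0])
        for i in range(xb.shape[0]):
            dices.append(dice(p[i, 0], yb[i, 0]))
    return float(np.sum(losses) / n), float(np.mean(dices))


def train_segmenter(
    net: SegNetwork,
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: TrainConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    groups: Sequence | None = None,
    callback: Callable[[dict], None] | None = None,
) -> tuple[SegNetwork, list[dict]]:
    """Train a network on aligned ROI image/mask pairs with the Dice loss.

    ``X_train``/``y_train`` are (n, H, W) or (n, 1, H, W) arrays; images may
    be uint8 (scaled to [0, 1] internally) and masks are {0, 1}.  When no
    explicit validation arrays are given, ``cfg.validation_fraction`` of the
    cases is held out, split by ``groups`` (e.g. mammogram id) when provided.

    Returns the network with its best-validation weights restored, and a
    per-epoch history of train loss, validation loss, validation Dice and
    learning rate (every rate change is visible in the ``lr`` column).
    """
    X = _as_batch(X_train)
    y = _as_batch(y_train).astype(np.float32)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    if X.shape != y.shape:
        raise ValueError(f"image/mask batch shapes differ: {X.shape} vs {y.shape}")
    if X.max() > 1.0:
        X = X / 255.0
    if X_val is None:
        if groups is None:
            groups = np.arange(X.shape[0])
        tr_idx, va_idx = split_by_group(groups, cfg.validation_fraction, cfg.seed)
        if va_idx.size == 0 or tr_idx.size == 0:
            raise ValueError("dataset too small to hold out a validation split")
        X, X_val, y, y_val = X[tr_idx], X[va_idx], y[tr_idx], y[va_idx]
    else:
        X_val = _as_batch(X_val)
        y_val = _as_batch(y_val).astype(np.float32)
        if X_val.max(initial=0.0) > 1.0:
            X_val = X_val / 255.0

    rng = np.random.default_rng(cfg.seed)
    controller = PlateauController(cfg)
    optimizer = Adam(net.parameters(), lr=cfg.initial_lr)
    history: list[dict] = []
    best_state = {k: v.copy() for k, v in net.state_arrays().items()}
    best_val = np.inf
    n = X.shape[0]

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb = X[idx].copy()
            yb = y[idx].copy()
            if cfg.augment is not None and not cfg.augment.is_identity:
                for i in range(xb.shape[0]):
                    ai, am = augment_pair(xb[i, 0], yb[i, 0].astype(np.uint8), cfg.augment, rng)
                    xb[i, 0] = ai
                    yb[i, 0] = am
            p = net.forward(xb, training=True)
            loss, dgrad = soft_dice_loss_batch(p, yb)
            optimizer.zero_grad()
            net.backward(dgrad)
            optimizer.step()
            epoch_loss += loss * xb.shape[0]
        val_loss, val_dice = _eval_network(net, X_val, y_val, cfg.batch_size)
        if val_loss < best_val:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in net.state_arrays().items()}
        lr_before = optimizer.lr
        new_lr, reduced, stop = controller.step(val_loss)
        optimizer.lr = new_lr
        record = {
            "epoch": epoch,
            "train_loss": epoch_loss / n,
            "val_loss": val_loss,
            "val_dice": val_dice,
            "lr": lr_before,
            "lr_reduced": reduced,
        }
        history.append(record)
        if callback is not None:
            callback(record)
        if stop:
            break

    net.load_state_arrays(best_state)
    return net, history
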