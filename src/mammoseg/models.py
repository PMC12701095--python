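"""The SegNet/SegDSC architecture family, exact cost accounting, and Otsu.

The family is generated from a declarative :class:`ArchitectureConfig`:

* ``depth`` encoder blocks of (3x3 conv → batch norm → ReLU) repeated
  ``convs_per_block`` times, each block ending in a 2x2/stride-2 max-pool that
  records its argmax indices;
* a mirrored decoder whose blocks start with index-based max-unpooling using
  the paired encoder's indices (no skip feature maps — the memory saving that
  defines the SegNet design);
* with ``use_dsc``, every 3x3 convolution is factorised into a depthwise 3x3
  plus a pointwise 1x1 convolution, with normalisation and ReLU after the
  pointwise step only;
* a ``width_multiplier`` shrinks every block's channel count
  (round-half-up, minimum one filter) to produce the compressed variants.

The reference filter schedule is 64/128/256/512 channels with 2/2/2/3
convolutions per block; the final decoder convolution maps to a single
channel followed by a sigmoid, giving per-pixel mass probabilities.

Parameter and multiply-accumulate budgets are computed both analytically
(closed form over the layer schedule) and by enumerating the instantiated
network's tensors; the two must agree exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .preprocess import _check_image

__all__ = [
    "ArchitectureConfig",
    "AccountingReport",
    "PRESETS",
    "SegNetwork",
    "build_model",
    "count_parameters",
    "count_macs",
    "conv_schedule",
    "otsu_threshold",
    "otsu_segment",
    "save_model",
    "load_model",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ArchitectureConfig:
    """Declarative description of one member of the SegNet/SegDSC family."""

    depth: int = 4
    use_dsc: bool = False
    width_multiplier: float = 1.0
    base_filters: tuple[int, ...] = (64, 128, 256, 512)
    convs_per_block: tuple[int, ...] = (2, 2, 2, 3)
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth not in (3, 4):
            raise ValueError("depth must be 3 or 4")
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must lie in (0, 1]")
        if len(self.base_filters) < self.depth or len(self.convs_per_block) < self.depth:
            raise ValueError("filter/conv schedules must cover every block")

    @property
    def filters(self) -> tuple[int, ...]:
        """Effective per-block channel counts after the width multiplier."""
        return tuple(
            max(1, _round_half_up(self.width_multiplier * f))
            for f in self.base_filters[: self.depth]
        )


#: Named presets.  SegDSC4_NN reduces the filters of SegDSC4 by NN percent.
PRESETS: dict[str, ArchitectureConfig] = {
    "segnet3": ArchitectureConfig(depth=3, use_dsc=False, width_multiplier=1.0),
    "segnet4": ArchitectureConfig(depth=4, use_dsc=False, width_multiplier=1.0),
    "segdsc3": ArchitectureConfig(depth=3, use_dsc=True, width_multiplier=1.0),
    "segdsc4": ArchitectureConfig(depth=4, use_dsc=True, width_multiplier=1.0),
    "segdsc4_85": ArchitectureConfig(depth=4, use_dsc=True, width_multiplier=0.15),
    "segdsc4_90": ArchitectureConfig(depth=4, use_dsc=True, width_multiplier=0.10),
    "segdsc4_95": ArchitectureConfig(depth=4, use_dsc=True, width_multiplier=0.05),
}


@dataclass(frozen=True)
class AccountingReport:
    """Cost summary matching the benchmark-table convention."""

    trainable_params: int
    size_mb: float  # 4 bytes per float32 parameter
    macs: int  # multiply-accumulates of one forward pass at `input_side`
    input_side: int

    @property
    def params_m(self) -> float:
        return self.trainable_params / 1e6

    @property
    def macs_g(self) -> float:
        return self.macs / 1e9


def conv_schedule(config: ArchitectureConfig) -> list[tuple[int, int, int]]:
    """The (cin, cout, downsampling-level) of every convolution, in order.

    The level gives the spatial extent of the convolution's output relative to
    the input side: output side = input_side / 2**level.
    """
    f = config.filters
    sched: list[tuple[int, int, int]] = []
    cin = config.in_channels
    for b in range(config.depth):  # encoder block b runs at level b
        for _ in range(config.convs_per_block[b]):
            sched.append((cin, f[b], b))
            cin = f[b]
    for b in range(config.depth - 1, -1, -1):  # decoder block b runs at level b
        n_convs = config.convs_per_block[b]
        for k in range(n_convs):
            last = k == n_convs - 1
            cout = (f[b - 1] if b > 0 else config.out_channels) if last else f[b]
            sched.append((cin, cout, b))
            cin = cout
    return sched


def count_parameters(config: ArchitectureConfig, enumerate_network: bool = True) -> AccountingReport:
    """Trainable parameter count, analytic and (optionally) by enumeration.

    Per convolution: a standard 3x3 conv holds ``9*cin*cout`` weights, a DSC
    ``9*cin + cin*cout``; no biases.  Every convolution is followed by an
    affine normalisation contributing ``2*cout``.  The analytic total must
    equal the sum over the instantiated network's tensors.
    """
    total = 0
    for cin, cout, _ in conv_schedule(config):
        if config.use_dsc:
            total += 9 * cin + cin * cout
        else:
            total += 9 * cin * cout
        total += 2 * cout  # affine norm
    if enumerate_network:
        net = build_model(config, seed=0)
        enumerated = sum(p.value.size for p in net.parameters())
        if enumerated != total:
            raise AssertionError(
                f"analytic count {total} != enumerated count {enumerated} for {config}"
            )
    return AccountingReport(
        trainable_params=total,
        size_mb=4.0 * total / 1e6,
        macs=_macs_value(config, 128),
        input_side=128,
    )


def _macs_value(config: ArchitectureConfig, input_side: int) -> int:
    if input_side % (2**config.depth) != 0:
        raise ValueError(f"input side {input_side} not divisible by 2**{config.depth}")
    total = 0
    for cin, cout, level in conv_schedule(config):
        hw = (input_side // (2**level)) ** 2
        if config.use_dsc:
            total += hw * (9 * cin + cin * cout)
        else:
            total += hw * 9 * cin * cout
    return total


def count_macs(config: ArchitectureConfig, input_side: int = 128) -> AccountingReport:
    """Multiply-accumulate count of one forward pass.

    Counts convolution MACs only (``H*W*9*cin*cout`` standard,
    ``H*W*(9*cin + cin*cout)`` DSC); normalisation, activations and pooling
    are excluded.  The spatial size halves per encoder block and doubles per
    decoder block.
    """
    macs = _macs_value(config, input_side)
    params = count_parameters(config, enumerate_network=False).trainable_params
    return AccountingReport(
        trainable_params=params, size_mb=4.0 * params / 1e6, macs=macs, input_side=input_side
    )


# ---------------------------------------------------------------------------
# network


class _ConvUnit:
    """One conv + norm (+ReLU) unit; standard or depthwise-separable."""

    def __init__(
        self, cin: int, cout: int, use_dsc: bool, relu: bool, rng: np.random.Generator
    ) -> None:
        self.layers: list[nn.Layer] = []
        if use_dsc:
            self.layers.append(nn.DepthwiseConv3x3(cin, rng))
            self.layers.append(nn.PointwiseConv(cin, cout, rng))
        else:
            self.layers.append(nn.Conv3x3(cin, cout, rng))
        self.layers.append(nn.BatchNorm2d(cout))
        if relu:
            self.layers.append(nn.ReLU())

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[nn.Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out


class SegNetwork:
    """Encoder-decoder segmentation network with max-pool-index unpooling."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        sched = conv_schedule(config)
        n_enc = sum(config.convs_per_block[: config.depth])
        self.encoder: list[list[_ConvUnit]] = []
        self.decoder: list[list[_ConvUnit]] = []
        i = 0
        for b in range(config.depth):
            block = []
            for _ in range(config.convs_per_block[b]):
                cin, cout, _level = sched[i]
                block.append(_ConvUnit(cin, cout, config.use_dsc, relu=True, rng=rng))
                i += 1
            self.encoder.append(block)
        n_total = len(sched)
        for b in range(config.depth - 1, -1, -1):
            block = []
            for _k in range(config.convs_per_block[b]):
                cin, cout, _level = sched[i]
                relu = i < n_total - 1  # final conv feeds the sigmoid head
                block.append(_ConvUnit(cin, cout, config.use_dsc, relu=relu, rng=rng))
                i += 1
            self.decoder.append(block)
        self.pools = [nn.MaxPool2x2() for _ in range(config.depth)]
        self.unpools = [nn.MaxUnpool2x2() for _ in range(config.depth)]
        self.head = nn.Sigmoid()

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        side = x.shape[-1]
        if x.shape[-2] % (2**self.config.depth) or side % (2**self.config.depth):
            raise ValueError(
                f"input side {x.shape[-2]}x{side} must be divisible by 2**{self.config.depth}"
            )
        indices = []
        for block, pool in zip(self.encoder, self.pools):
            for unit in block:
                x = unit.forward(x, training)
            x, idx = pool.forward(x, training)
            indices.append(idx)
        for k, (block, unpool) in enumerate(zip(self.decoder, self.unpools)):
            x = unpool.forward(x, indices[self.config.depth - 1 - k], training)
            for unit in block:
                x = unit.forward(x, training)
        return self.head.forward(x, training)

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.head.backward(grad)
        for k in range(len(self.decoder) - 1, -1, -1):
            for unit in reversed(self.decoder[k]):
                grad = unit.backward(grad)
            grad = self.unpools[k].backward(grad)
        for k in range(len(self.encoder) - 1, -1, -1):
            grad = self.pools[k].backward(grad)
            for unit in reversed(self.encoder[k]):
                grad = unit.backward(grad)
        return grad

    # -- parameter access ---------------------------------------------------

    def parameters(self) -> list[nn.Param]:
        out = []
        for block in self.encoder + self.decoder:
            for unit in block:
                out.extend(unit.parameters())
        return out

    def _norm_layers(self) -> list[nn.BatchNorm2d]:
        out = []
        for block in self.encoder + self.decoder:
            for unit in block:
                out.extend(l for l in unit.layers if isinstance(l, nn.BatchNorm2d))
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._norm_layers()):
            state[f"running_mean_{i}"] = bn.running_mean
            state[f"running_var_{i}"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"param_{i}"]
        for i, bn in enumerate(self._norm_layers()):
            bn.running_mean[...] = state[f"running_mean_{i}"]
            bn.running_var[...] = state[f"running_var_{i}"]


def build_model(config: ArchitectureConfig | str, seed: int = 0) -> SegNetwork:
    """Instantiate a family member from a config or preset name."""
    if isinstance(config, str):
        key = config.lower()
        if key not in PRESETS:
            raise KeyError(f"unknown preset {config!r}; known: {sorted(PRESETS)}")
        config = PRESETS[key]
    return SegNetwork(config, seed=seed)


def save_model(net: SegNetwork, path: str | Path) -> None:
    """Write weights (.npz) plus a JSON architecture descriptor side by side."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **net.state_arrays())
    report = count_parameters(net.config, enumerate_network=False)
    descriptor = {
        "config": {
            "depth": net.config.depth,
            "use_dsc": net.config.use_dsc,
            "width_multiplier": net.config.width_multiplier,
            "base_filters": list(net.config.base_filters),
            "convs_per_block": list(net.config.convs_per_block),
            "in_channels": net.config.in_channels,
            "out_channels": net.config.out_channels,
        },
        "trainable_params": report.trainable_params,
        "size_mb": report.size_mb,
        "macs_at_128": count_macs(net.config, 128).macs,
    }
    path.with_suffix(".json").write_text(json.dumps(descriptor, indent=2))


def load_model(path: str | Path) -> SegNetwork:
    path = Path(path)
    descriptor = json.loads(path.with_suffix(".json").read_text())
    cfg = descriptor["config"]
    config = ArchitectureConfig(
        depth=cfg["depth"],
        use_dsc=cfg["use_dsc"],
        width_multiplier=cfg["width_multiplier"],
        base_filters=tuple(cfg["base_filters"]),
        convs_per_block=tuple(cfg["convs_per_block"]),
        in_channels=cfg["in_channels"],
        out_channels=cfg["out_channels"],
    )
    net = SegNetwork(config, seed=0)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as state:
        net.load_state_arrays(dict(state))
    return net


# ---------------------------------------------------------------------------
# Otsu baseline


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin histogram of an 8-bit image.

    Returns the smallest t maximising the between-class variance
    w0(t)·w1(t)·(mu0(t) − mu1(t))² of the split [0..t] vs [t+1..255].
    """
    img = _check_image(img)
    if img.max(initial=0) > 255 or img.min(initial=0) < 0:
        raise ValueError("otsu expects an 8-bit image")
    hist = np.bincount(img.astype(np.uint8).ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    w0 = np.cumsum(hist)  # pixels at or below t
    w1 = total - w0
    cum_mean = np.cumsum(hist * np.arange(256))
    grand_mean = cum_mean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (grand_mean - cum_mean) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between, nan=0.0)
    return int(np.argmax(var_between))  # argmax takes the smallest maximiser


def otsu_segment(roi: np.ndarray) -> np.ndarray:
    """Threshold-based baseline: foreground = pixels brighter than Otsu's t*.

    Masses are hyperintense relative to surrounding tissue, so the brighter
    class is the predicted mass.  A constant image yields an empty mask.
    """
    roi = _check_image(roi)
    if roi.size == 0 or roi.max() == roi.min():
        return np.zeros(roi.shape, dtype=np.uint8)
    t = otsu_threshold(roi)
    return (roi > t).astype(np.uint8)
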