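"""The simultaneous segmentation + landmark localisation network (2.5D FCN).

The input volume is presented as a multi-channel 2D image whose channels are
the short-axis slices.  A fine-to-coarse branch of 3x3 convolutions (each
coarser scale reached by 2x2 mean pooling) learns features at several
resolutions; all scale outputs are upsampled back to the in-plane grid and
concatenated; a 1x1 fusion convolution feeds two softmax heads that emit,
for every voxel of the full 3D grid, a distribution over the 5 tissue
classes and over the 7 landmark classes.  Being fully convolutional, the
parameter count is independent of the in-plane size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigError
from .layers import AvgPool2, Conv2d, ReLU, Upsample

__all__ = ["NetConfig", "SSLLNModel", "build_network"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimisation settings.

    ``scales`` lists ``(n_convs, width)`` per resolution level, finest first;
    the first level's count includes the stem convolution.  The total
    convolution count is ``sum(n_convs) + 3`` (fusion + two heads).
    """

    in_slices: int = 80
    n_seg_classes: int = 5
    n_lm_classes: int = 7
    scales: tuple[tuple[int, int], ...] = ((3, 32), (3, 64), (3, 96), (3, 96))
    fuse_width: int = 64
    conv_layers: int | None = 15
    alpha: float = 1.0          # landmark-loss weight
    beta: float = 1e-4          # weight decay
    eps: float = 1e-5           # Dice smoothing constant
    optimizer: str = "sgd"      # "sgd" (momentum) or "adam"
    lr: float = 0.05
    lr_decay: float = 1.0       # final lr = lr * lr_decay, linear schedule
    momentum: float = 0.9
    epochs: int = 50
    batch_size: int = 1
    lm_dilation: int = 1        # landmark rasterisation dilation during training
    dice_per_class: bool = False  # train with the per-class Dice variant
    augment: bool = True
    lm_probe_epoch: int | None = None   # early landmark sanity probe (epoch index)
    lm_probe_threshold_mm: float = 8.0  # held-in mean error that triggers a re-init
    max_restarts: int = 3
    rng_seed: int = 0

    def __post_init__(self):
        n_convs = sum(n for n, _ in self.scales) + 3
        if self.conv_layers is None:
            object.__setattr__(self, "conv_layers", n_convs)
        elif self.conv_layers != n_convs:
            raise ConfigError(
                f"scales imply {n_convs} convolutional layers, config says {self.conv_layers}")
        if self.conv_layers < 3:
            raise ConfigError("need at least 3 convolutional layers")
        if self.alpha < 0 or self.beta < 0 or self.eps <= 0:
            raise ConfigError("alpha, beta must be >= 0 and eps > 0")

    @classmethod
    def tiny(cls, in_slices: int, **overrides) -> "NetConfig":
        """A small configuration for CPU-scale experiments and benchmarks."""
        defaults = dict(
            in_slices=in_slices,
            scales=((1, 12), (2, 16), (2, 24), (2, 32)),
            fuse_width=32,
            conv_layers=None,
            lr=0.05,
            epochs=40,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _softmax(z: np.ndarray, axis: int = 0) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class SSLLNModel:
    """Multi-scale 2.5D FCN with segmentation and landmark softmax heads."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        self.branches = []      # per scale: list of (Conv2d, ReLU)
        c_prev = cfg.in_slices
        for n_convs, width in cfg.scales:
            layers = []
            for _ in range(n_convs):
                layers.append(Conv2d(c_prev, width, 3, rng))
                layers.append(ReLU())
                c_prev = width
            self.branches.append(layers)
        self.pools = [AvgPool2() for _ in cfg.scales[1:]]
        self.ups = [Upsample(2 ** i) for i in range(len(cfg.scales))]
        c_cat = sum(w for _, w in cfg.scales)
        self.fuse = Conv2d(c_cat, cfg.fuse_width, 1, rng)
        self.fuse_act = ReLU()
        # the heads see the fused multi-scale context plus the raw input
        # slices (skip connection): per-slice intensity evidence reaches the
        # per-slice output channels directly
        c_head = cfg.fuse_width + cfg.in_slices
        self.head_seg = Conv2d(c_head, cfg.n_seg_classes * cfg.in_slices, 1, rng)
        self.head_lm = Conv2d(c_head, cfg.n_lm_classes * cfg.in_slices, 1, rng)

    # -- parameters ---------------------------------------------------------

    def conv_layers(self):
        for layers in self.branches:
            for lyr in layers:
                if isinstance(lyr, Conv2d):
                    yield lyr
        yield self.fuse
        yield self.head_seg
        yield self.head_lm

    def params(self):
        for conv in self.conv_layers():
            yield from conv.params()

    def weights_sqnorm(self) -> float:
        return float(sum((c.W ** 2).sum() for c in self.conv_layers()))

    def zero_grad(self):
        for conv in self.conv_layers():
            conv.dW[:] = 0.0
            conv.db[:] = 0.0

    # -- forward / backward -------------------------------------------------

    def forward(self, volume: np.ndarray):
        """``volume`` is (X, Y, Z); returns softmax grids
        ``seg (N_r, X, Y, Z)`` and ``lm (N_l, X, Y, Z)``."""
        cfg = self.cfg
        if volume.shape[2] != cfg.in_slices:
            raise ConfigError(
                f"volume has {volume.shape[2]} slices, network expects {cfg.in_slices}")
        x_in = np.ascontiguousarray(np.moveaxis(np.asarray(volume, dtype=np.float32), 2, 0))
        x = x_in
        feats = []
        for i, layers in enumerate(self.branches):
            if i > 0:
                x = self.pools[i - 1].forward(x)
            for lyr in layers:
                x = lyr.forward(x)
            feats.append(x)
        upped = [self.ups[i].forward(f) for i, f in enumerate(feats)]
        self._split = [f.shape[0] for f in upped]
        cat = np.concatenate(upped, axis=0)
        fused = self.fuse_act.forward(self.fuse.forward(cat))
        head_in = np.concatenate([fused, x_in], axis=0)
        zs = self.head_seg.forward(head_in)
        zl = self.head_lm.forward(head_in)
        H, W = zs.shape[1:]
        zs = zs.reshape(cfg.n_seg_classes, cfg.in_slices, H, W)
        zl = zl.reshape(cfg.n_lm_classes, cfg.in_slices, H, W)
        seg = _softmax(zs.astype(np.float64), axis=0)
        lm = _softmax(zl.astype(np.float64), axis=0)
        self._probs = (seg, lm)
        # back to (class, X, Y, Z) ordering
        return np.moveaxis(seg, 1, 3), np.moveaxis(lm, 1, 3)

    def backward(self, d_seg: np.ndarray, d_lm: np.ndarray):
        """Backpropagate gradients w.r.t. the softmax *probabilities*
        (class, X, Y, Z), accumulating parameter gradients."""
        cfg = self.cfg
        seg, lm = self._probs

        def through_softmax(p, dp):
            inner = (dp * p).sum(axis=0, keepdims=True)
            return p * (dp - inner)

        dzs = through_softmax(seg, np.moveaxis(d_seg, 3, 1)).astype(np.float32)
        dzl = through_softmax(lm, np.moveaxis(d_lm, 3, 1)).astype(np.float32)
        H, W = dzs.shape[2:]
        dhead = self.head_seg.backward(dzs.reshape(-1, H, W))
        dhead += self.head_lm.backward(dzl.reshape(-1, H, W))
        dfused = dhead[: self.cfg.fuse_width]  # gradient into the input skip is dropped
        dcat = self.fuse.backward(self.fuse_act.backward(dfused))
        splits = np.cumsum(self._split)[:-1]
        dups = np.split(dcat, splits, axis=0)
        dx_next = None
        for i in reversed(range(len(self.branches))):
            dx = self.ups[i].backward(dups[i])
            if dx_next is not None:
                dx = dx + dx_next
            for lyr in reversed(self.branches[i]):
                dx = lyr.backward(dx)
            dx_next = self.pools[i - 1].backward(dx) if i > 0 else None
        return dx


def build_network(cfg: NetConfig) -> SSLLNModel:
    """Construct the model; raises :class:`ConfigError` on inconsistent cfg."""
    return SSLLNModel(cfg)


def save_model(model: SSLLNModel, path) -> None:
    """Write weights plus the full NetConfig to a ``.npz`` checkpoint."""
    import dataclasses
    import json

    arrays = {}
    for i, conv in enumerate(model.conv_layers()):
        arrays[f"W{i}"] = conv.W
        arrays[f"b{i}"] = conv.b
    cfg = dataclasses.asdict(model.cfg)
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> SSLLNModel:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    import json

    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        for key in ("scales",):
            cfg_dict[key] = tuple(tuple(s) for s in cfg_dict[key])
        for key in cfg_dict:
            if isinstance(cfg_dict[key], list):
                cfg_dict[key] = tuple(cfg_dict[key])
        model = SSLLNModel(NetConfig(**cfg_dict))
        for i, conv in enumerate(model.conv_layers()):
            conv.W = data[f"W{i}"].copy()
            conv.b = data[f"b{i}"].copy()
    return model
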