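"""Patch classifiers and U-Net variants for chorio-retinal segmentation.

Patch classifiers (4-way softmax over ILM/RPE/CSI/BG anchors):

* ``cifar_cnn``   -- three conv+pool stages and two fully-connected stages,
  the classic small image-classification CNN of the CNN-graph-search line.
* ``complex_cnn`` -- a deeper/wider five-conv-stage variant.
* ``renet_rnn``   -- ReNet-style stacked bidirectional recurrent sweeps over
  non-overlapping 2x2 receptive-field tiles (vertical then horizontal),
  followed by a fully-connected softmax.  Fewest parameters, slowest.

Semantic models: U-Net encoder-decoder with four 2x2 poolings, eight base
filters doubling per level, zero-padded convolutions, batch-norm before
every ReLU and 50% dropout at the bottleneck output.  Variants: residual
shortcuts per convolution block, a bidirectional-RNN bottleneck,
squeeze-excitation blocks (cSE / sSE / scSE) after each block, and the
combination of all three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import BatchNorm, BiRNNSweep, Conv2d, Dropout, Linear, Module

__all__ = [
    "PatchModelConfig", "SemanticModelConfig",
    "build_patch_model", "build_semantic_model",
    "PATCH_ARCHITECTURES", "SEMANTIC_VARIANTS",
]

PATCH_ARCHITECTURES = ("cifar_cnn", "complex_cnn", "renet_rnn")
SEMANTIC_VARIANTS = ("standard", "residual", "rnn_bottleneck",
                     "cse", "sse", "scse", "combined")


@dataclass(frozen=True)
class PatchModelConfig:
    architecture: str = "cifar_cnn"
    patch_height: int = 32
    patch_width: int = 32
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in PATCH_ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.patch_height % 2 or self.patch_width % 2:
            raise ValueError("patch dimensions must be even")


@dataclass(frozen=True)
class SemanticModelConfig:
    variant: str = "standard"
    n_pool: int = 4
    base_filters: int = 8
    dropout_bottleneck: float = 0.5
    n_area_classes: int = 4
    scse_combine: str = "max"  # 'max' or 'add'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in SEMANTIC_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.scse_combine not in ("max", "add"):
            raise ValueError("scse_combine must be 'max' or 'add'")

    @property
    def encoder_filters(self) -> tuple[int, ...]:
        return tuple(self.base_filters * 2 ** level
                     for level in range(self.n_pool + 1))


def _softmax_probs(logits: Tensor, axis: int) -> Tensor:
    return ad.log_softmax(logits, axis=axis).exp()


# --------------------------------------------------------------------------
# patch classifiers
# --------------------------------------------------------------------------

class CifarCNN(Module):
    def __init__(self, config: PatchModelConfig, rng: np.random.Generator):
        self.config = config
        h, w = config.patch_height, config.patch_width
        if h % 8 or w % 8:
            raise ValueError("cifar_cnn needs patch dimensions divisible by 8")
        self.conv1 = Conv2d(1, 32, 5, rng)
        self.conv2 = Conv2d(32, 32, 5, rng)
        self.conv3 = Conv2d(32, 64, 5, rng)
        self.fc1 = Linear((h // 8) * (w // 8) * 64, 64, rng)
        self.fc2 = Linear(64, config.n_classes, rng)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        n = x.shape[0]
        h = ad.maxpool2d(self.conv1(x).relu())
        h = ad.maxpool2d(self.conv2(h).relu())
        h = ad.maxpool2d(self.conv3(h).relu())
        h = self.fc1(h.reshape(n, -1)).relu()
        return self.fc2(h)


class ComplexCNN(Module):
    def __init__(self, config: PatchModelConfig, rng: np.random.Generator):
        self.config = config
        h, w = config.patch_height, config.patch_width
        if h % 8 or w % 8:
            raise ValueError("complex_cnn needs patch dimensions divisible by 8")
        self.conv1 = Conv2d(1, 32, 3, rng)
        self.conv2 = Conv2d(32, 32, 3, rng)
        self.conv3 = Conv2d(32, 64, 3, rng)
        self.conv4 = Conv2d(64, 64, 3, rng)
        self.conv5 = Conv2d(64, 128, 3, rng)
        self.fc1 = Linear((h // 8) * (w // 8) * 128, 128, rng)
        self.fc2 = Linear(128, config.n_classes, rng)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        n = x.shape[0]
        h = self.conv2(self.conv1(x).relu()).relu()
        h = ad.maxpool2d(h)
        h = self.conv4(self.conv3(h).relu()).relu()
        h = ad.maxpool2d(h)
        h = ad.maxpool2d(self.conv5(h).relu())
        h = self.fc1(h.reshape(n, -1)).relu()
        return self.fc2(h)


class ReNetClassifier(Module):
    """ReNet-style classifier: 2x2 tiles, vertical then horizontal sweeps."""

    RECEPTIVE = 2
    FILTERS = 32
    DROPOUT = 0.2

    def __init__(self, config: PatchModelConfig, rng: np.random.Generator):
        self.config = config
        h, w = config.patch_height, config.patch_width
        if h % self.RECEPTIVE or w % self.RECEPTIVE:
            raise ValueError("renet_rnn needs patch dimensions divisible by 2")
        tile_ch = self.RECEPTIVE ** 2
        self.vertical = BiRNNSweep(tile_ch, self.FILTERS, "vertical", rng)
        self.horizontal = BiRNNSweep(2 * self.FILTERS, self.FILTERS,
                                     "horizontal", rng)
        self.drop = Dropout(self.DROPOUT)
        th, tw = h // self.RECEPTIVE, w // self.RECEPTIVE
        self.fc = Linear(th * tw * 2 * self.FILTERS, config.n_classes, rng)

    def _space_to_depth(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        k = self.RECEPTIVE
        x = x.reshape(n, c, h // k, k, w // k, k)
        return x.transpose(0, 1, 3, 5, 2, 4).reshape(n, c * k * k, h // k, w // k)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        if training and rng is None:
            raise ValueError("training mode needs an rng for dropout")
        n = x.shape[0]
        h = self._space_to_depth(x)
        h = self.vertical(h)
        if training:
            h = self.drop(h, rng, training)
        h = self.horizontal(h)
        if training:
            h = self.drop(h, rng, training)
        return self.fc(h.reshape(n, -1))


def build_patch_model(config: PatchModelConfig) -> Module:
    """Build a patch classifier; identical seeds give identical weights."""
    rng = np.random.default_rng(config.seed)
    cls = {"cifar_cnn": CifarCNN, "complex_cnn": ComplexCNN,
           "renet_rnn": ReNetClassifier}[config.architecture]
    return cls(config, rng)


# --------------------------------------------------------------------------
# semantic segmentation U-Net variants
# --------------------------------------------------------------------------

class SqueezeExcite(Module):
    """cSE / sSE / scSE recalibration of a feature map."""

    def __init__(self, channels: int, mode: str, rng: np.random.Generator,
                 combine: str = "max", reduction: int = 2):
        self.mode = mode
        self.combine = combine
        if mode in ("cse", "scse"):
            mid = max(channels // reduction, 1)
            self.fc1 = Linear(channels, mid, rng)
            self.fc2 = Linear(mid, channels, rng)
        if mode in ("sse", "scse"):
            self.spatial = Conv2d(channels, 1, 1, rng)

    def _cse(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        squeezed = x.mean(axis=(2, 3))  # global average pool -> (N, C)
        scale = self.fc2(self.fc1(squeezed).relu()).sigmoid()
        return x * scale.reshape(n, c, 1, 1)

    def _sse(self, x: Tensor) -> Tensor:
        return x * self.spatial(x).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        if self.mode == "cse":
            return self._cse(x)
        if self.mode == "sse":
            return self._sse(x)
        a, b = self._cse(x), self._sse(x)
        return ad.maximum(a, b) if self.combine == "max" else a + b


class ConvBlock(Module):
    """Two 3x3 conv + BN + ReLU stages, optional residual shortcut and SE."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 residual: bool = False, se: SqueezeExcite | None = None):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.bn1 = BatchNorm(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm(c_out)
        self.residual = residual
        self.se = se
        if residual and c_in != c_out:
            self.project = Conv2d(c_in, c_out, 1, rng)
        else:
            self.project = None

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = self.bn1(self.conv1(x), training).relu()
        h = self.bn2(self.conv2(h), training)
        if self.residual:
            shortcut = self.project(x) if self.project is not None else x
            h = h + shortcut
        h = h.relu()
        if self.se is not None:
            h = self.se(h)
        return h


class RNNBottleneck(Module):
    """Bottleneck convolutions replaced by vertical + horizontal bi-RNN sweeps."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 se: SqueezeExcite | None = None):
        if c_out % 2:
            raise ValueError("RNN bottleneck needs an even output width")
        self.vertical = BiRNNSweep(c_in, c_out // 2, "vertical", rng)
        self.horizontal = BiRNNSweep(c_out, c_out // 2, "horizontal", rng)
        self.se = se

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = self.horizontal(self.vertical(x))
        if self.se is not None:
            h = self.se(h)
        return h


class UNet(Module):
    """U-Net encoder-decoder over the four chorio-retinal area classes."""

    def __init__(self, config: SemanticModelConfig, rng: np.random.Generator):
        self.config = config
        variant = config.variant
        residual = variant in ("residual", "combined")
        rnn_bottleneck = variant in ("rnn_bottleneck", "combined")
        se_mode = {"cse": "cse", "sse": "sse", "scse": "scse",
                   "combined": "scse"}.get(variant)

        def make_se(channels: int) -> SqueezeExcite | None:
            if se_mode is None:
                return None
            return SqueezeExcite(channels, se_mode, rng, config.scse_combine)

        filters = config.encoder_filters
        self.enc_blocks = []
        c_prev = 1
        for c in filters[:-1]:
            self.enc_blocks.append(
                ConvBlock(c_prev, c, rng, residual, make_se(c)))
            c_prev = c
        c_bottom = filters[-1]
        if rnn_bottleneck:
            self.bottleneck: Module = RNNBottleneck(
                c_prev, c_bottom, rng, make_se(c_bottom))
        else:
            self.bottleneck = ConvBlock(
                c_prev, c_bottom, rng, residual, make_se(c_bottom))
        self.drop = Dropout(config.dropout_bottleneck)

        self.up_convs = []
        self.dec_blocks = []
        c_prev = c_bottom
        for c in reversed(filters[:-1]):
            self.up_convs.append(Conv2d(c_prev, c, 3, rng))
            self.dec_blocks.append(
                ConvBlock(2 * c, c, rng, residual, make_se(c)))
            c_prev = c
        self.head = Conv2d(filters[0], config.n_area_classes, 1, rng)

    def _check_size(self, h: int, w: int) -> None:
        div = 2 ** self.config.n_pool
        if h % div or w % div:
            pad_h = (div - h % div) % div
            pad_w = (div - w % div) % div
            raise ValueError(
                f"input {h}x{w} not divisible by {div}; pad by "
                f"({pad_h}, {pad_w}) rows/columns")

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        """Per-pixel class logits of shape (N, n_classes, H, W)."""
        if training and rng is None:
            raise ValueError("training mode needs an rng for dropout")
        self._check_size(x.shape[2], x.shape[3])
        skips = []
        h = x
        for block in self.enc_blocks:
            h = block(h, training)
            skips.append(h)
            h = ad.maxpool2d(h)
        h = self.bottleneck(h, training)
        if training:
            h = self.drop(h, rng, training)
        for up, block, skip in zip(self.up_convs, self.dec_blocks,
                                   reversed(skips)):
            h = up(ad.upsample2d(h))
            h = ad.concat([h, skip], axis=1)
            h = block(h, training)
        return self.head(h)

    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """Area-class probabilities (H, W, n_classes) for one image in [0, 255]."""
        x = Tensor((image[None, None, :, :] / 255.0).astype(np.float32))
        logits = self(x, training=False)
        probs = _softmax_probs(logits, axis=1)
        return np.asarray(probs.data[0]).transpose(1, 2, 0)


def build_semantic_model(config: SemanticModelConfig) -> UNet:
    """Build a semantic segmentation network; seed-deterministic weights."""
    rng = np.random.default_rng(config.seed)
    return UNet(config, rng)
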