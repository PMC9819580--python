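"""Restoration network architectures: SRCNN, U-Net and REDNet.

All three map a single-channel band-limited B-mode image to a same-size
restored image and end in a ReLU (non-negative output).  Layer widths and
kernels live in :class:`ModelSpec` as data so the parameter accounting of a
built model can be diagnosed layer by layer:

* ``srcnn`` - three convolutions 9x9/128, 3x3/64, 5x5/1 (85,889 parameters,
  all trainable).  The canonical 9-5-5 / 64-32-1 variant of the original
  super-resolution network (57,281 parameters) is available as
  ``srcnn_canonical`` for reference.
* ``unet`` - a depth-5 encoder/decoder, base width 16 doubling to 256, two
  3x3 conv + batch-norm + ReLU layers per block, 2x2 max pooling, and
  nearest-neighbour upsampling followed by a 3x3 conv (no batch norm on the
  up-convs); skip concatenations; 3x3 single-channel head.  2,164,433
  parameters of which 2,944 (the batch-norm moving statistics) are
  non-trainable.
* ``rednet`` - a residual encoder/decoder: a frozen bank of 32 Sobel-derived
  edge kernels is concatenated with the input, followed by seven dilated 3x3
  convolutions (widths 14-24-42-42-42-24-14, dilation schedule
  1-2-3-4-3-2-1) with dropout 0.05, the input concatenated again before a
  3x3 head, and the prediction added residually to the input.  60,760
  parameters; the 320 frozen edge-bank weights are non-trainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nn
from .bmode import BModeImage

__all__ = ["ModelSpec", "Model", "build_model", "sobel_bank", "predict"]

MODEL_NAMES = ("srcnn", "srcnn_canonical", "unet", "rednet")


@dataclass
class ModelSpec:
    """Architecture description; widths/kernels are data, not code."""

    name: str = "rednet"
    filters_per_layer: list[int] = field(default_factory=list)
    kernel_sizes: list[int] = field(default_factory=list)
    dilation_rates: list[int] = field(default_factory=list)
    dropout_rate: float = 0.05
    final_activation: str = "relu"
    edge_bank_size: int = 32       # rednet only: frozen Sobel-orientation kernels
    seed: int = 0

    @classmethod
    def for_name(cls, name: str, seed: int = 0) -> "ModelSpec":
        if name == "srcnn":
            return cls(name, [128, 64, 1], [9, 3, 5], [], 0.0, seed=seed)
        if name == "srcnn_canonical":
            return cls(name, [64, 32, 1], [9, 5, 5], [], 0.0, seed=seed)
        if name == "unet":
            return cls(name, [16, 32, 64, 128, 256], [3], [], 0.0, seed=seed)
        if name == "rednet":
            return cls(name, [14, 24, 42, 42, 42, 24, 14], [3],
                       [1, 2, 3, 4, 3, 2, 1], 0.05, seed=seed)
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def sobel_bank(n_orientations: int = 32) -> np.ndarray:
    """Steered Sobel kernels cos(t)*Gx + sin(t)*Gy over n orientations.

    Returns weights of shape (3, 3, 1, n_orientations); used frozen.
    """
    gx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], np.float32)
    gy = gx.T
    thetas = 2 * np.pi * np.arange(n_orientations) / n_orientations
    bank = np.stack([np.cos(t) * gx + np.sin(t) * gy for t in thetas], axis=-1)
    return bank[:, :, None, :].astype(np.float32)


def _build_srcnn(spec: ModelSpec) -> nn.Network:
    net = nn.Network(spec.seed)
    rng = net.build_rng
    c = 1
    n_layers = len(spec.filters_per_layer)
    for i, (f, k) in enumerate(zip(spec.filters_per_layer, spec.kernel_sizes)):
        net.add(nn.Conv2D(c, f, k, rng=rng, name=f"conv{i}"))
        if i < n_layers - 1:
            net.add(nn.ReLU())
        c = f
    net.add(nn.ReLU())  # non-negative output head
    return net


def _build_unet(spec: ModelSpec) -> nn.Network:
    net = nn.Network(spec.seed)
    rng = net.build_rng
    k = spec.kernel_sizes[0]
    widths = spec.filters_per_layer
    c = 1
    skips = []

    def block(c_in, f, tag):
        nonlocal net
        net.add(nn.Conv2D(c_in, f, k, rng=rng, name=f"{tag}a"))
        net.add(nn.BatchNorm(f, name=f"{tag}a_bn"))
        net.add(nn.ReLU())
        net.add(nn.Conv2D(f, f, k, rng=rng, name=f"{tag}b"))
        net.add(nn.BatchNorm(f, name=f"{tag}b_bn"))
        return net.add(nn.ReLU())

    for i, f in enumerate(widths[:-1]):
        skips.append(block(c, f, f"enc{i}"))
        net.add(nn.MaxPool2())
        c = f
    bott = block(c, widths[-1], "bott")
    c = widths[-1]
    prev = bott
    for i, f in enumerate(reversed(widths[:-1])):
        net.add(nn.Upsample2(), prev)
        upc = net.add(nn.Conv2D(c, f, k, rng=rng, name=f"up{i}"))
        upr = net.add(nn.ReLU(), upc)
        cat = net.add(nn.Concat(), upr, skips[-(i + 1)])
        prev = block(2 * f, f, f"dec{i}")
        c = f
    net.add(nn.Conv2D(c, 1, k, rng=rng, name="head"), prev)
    net.add(nn.ReLU())
    return net


def _build_rednet(spec: ModelSpec) -> nn.Network:
    net = nn.Network(spec.seed)
    rng = net.build_rng
    inp = 0
    bank = sobel_bank(spec.edge_bank_size)
    edges = net.add(nn.FixedConv2D(bank, bias=np.zeros(spec.edge_bank_size,
                                                       np.float32),
                                   name="edge_bank"), inp)
    x = net.add(nn.Concat(), inp, edges)
    c = 1 + spec.edge_bank_size
    for i, (f, d) in enumerate(zip(spec.filters_per_layer, spec.dilation_rates)):
        x = net.add(nn.Conv2D(c, f, 3, dilation=d, rng=rng, name=f"dil{i}"), x)
        x = net.add(nn.ReLU(), x)
        if spec.dropout_rate > 0:
            x = net.add(nn.Dropout(spec.dropout_rate), x)
        c = f
    cat = net.add(nn.Concat(), x, inp)
    head = net.add(nn.Conv2D(c + 1, 1, 3, rng=rng, name="head"), cat)
    res = net.add(nn.Add(), inp, head)
    net.add(nn.ReLU(), res)
    return net


@dataclass
class Model:
    """A built network plus its spec and exact parameter counts."""

    spec: ModelSpec
    net: nn.Network
    patch_size: int
    total_params: int
    trainable_params: int
    non_trainable_params: int

    @property
    def downsampling_factor(self) -> int:
        if self.spec.name == "unet":
            return 2 ** (len(self.spec.filters_per_layer) - 1)
        return 1

    def __call__(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(batch, training=training)

    def save_weights(self, path):
        np.savez(path, **self.net.state_dict())

    def load_weights(self, path):
        with np.load(path) as data:
            self.net.load_state_dict(dict(data))


def build_model(spec: ModelSpec | str, patch_size: int = 128,
                seed: int | None = None) -> Model:
    """Construct a network and report (total, trainable, non-trainable).

    ``patch_size`` is validated against the architecture (the U-Net needs
    spatial sizes divisible by its total downsampling factor); the parameter
    counts of these fully convolutional nets do not depend on it.
    """
    if isinstance(spec, str):
        spec = ModelSpec.for_name(spec, seed=seed or 0)
    elif seed is not None:
        spec = ModelSpec(**{**asdict(spec), "seed": seed})
    if spec.name in ("srcnn", "srcnn_canonical"):
        net = _build_srcnn(spec)
    elif spec.name == "unet":
        factor = 2 ** (len(spec.filters_per_layer) - 1)
        if patch_size % factor:
            raise ValueError(
                f"patch_size {patch_size} not divisible by the U-Net "
                f"downsampling factor {factor}")
        net = _build_unet(spec)
    elif spec.name == "rednet":
        net = _build_rednet(spec)
    else:
        raise ValueError(f"unknown model {spec.name!r}")
    total, trainable, non_trainable = net.count_params()
    return Model(spec, net, patch_size, total, trainable, non_trainable)


def _forward_image(model: Model, img: np.ndarray) -> np.ndarray:
    """Run one whole image, reflect-padding to the U-Net grid if needed."""
    f = model.downsampling_factor
    h, w = img.shape
    ph = (-h) % f
    pw = (-w) % f
    x = np.pad(img, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else img
    out = model.net.forward(x[None, :, :, None], training=False)[0, :, :, 0]
    return out[:h, :w]


def predict(model: Model, image: BModeImage | np.ndarray,
            tile: int | None = None, overlap: int = 64) -> BModeImage:
    """Restore a B-mode image, whole or by overlapping tiles.

    Tiled mode processes ``tile`` x ``tile`` windows advanced by
    ``tile - overlap`` and keeps only the central region of each window
    (margin ``overlap // 2``), so every retained pixel is far from interior
    tile edges; with a margin beyond the receptive-field radius this equals
    whole-image inference exactly for the fully convolutional nets.  Output
    values are clipped to [0, 1] for the returned image.
    """
    arr = image.pixels if isinstance(image, BModeImage) else np.asarray(image)
    arr = arr.astype(np.float32)
    h, w = arr.shape
    rf_min = model.downsampling_factor
    if h < rf_min or w < rf_min:
        raise ValueError("image smaller than the network's minimum input size")
    if tile is None or (h <= tile and w <= tile):
        out = _forward_image(model, arr)
    else:
        if overlap % 2 or overlap >= tile:
            raise ValueError("overlap must be even and smaller than tile")
        margin = overlap // 2
        stride = tile - overlap
        out = np.zeros_like(arr)

        def origins(extent):
            if extent <= tile:
                return [0]
            os = list(range(0, extent - tile, stride)) + [extent - tile]
            return os

        for r0 in origins(h):
            for c0 in origins(w):
                r1, c1 = min(r0 + tile, h), min(c0 + tile, w)
                patch = _forward_image(model, arr[r0:r1, c0:c1])
                kr0 = 0 if r0 == 0 else margin
                kr1 = (r1 - r0) if r1 == h else (r1 - r0) - margin
                kc0 = 0 if c0 == 0 else margin
                kc1 = (c1 - c0) if c1 == w else (c1 - c0) - margin
                out[r0 + kr0:r0 + kr1, c0 + kc0:c0 + kc1] = patch[kr0:kr1, kc0:kc1]
    dr = image.dynamic_range_db if isinstance(image, BModeImage) else 60.0
    return BModeImage(np.clip(out, 0.0, 1.0), dr, f"model({model.spec.name})")
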