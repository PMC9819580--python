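"""Training losses: PL1 (scaled MSE) and PL2 (pixel + perceptual mixture).

PL1 multiplies the mean squared error by a scaling factor tau; on [0, 1]
display-scaled images the raw MSE is tiny and its gradients underflow
float32 early in training, which is what the scaling counteracts.  PL2 mixes
a pixel-domain term with a perceptual term - the mean squared difference of
frozen convolutional feature activations - in a 30:70 ratio (pixel :
perceptual).

The perceptual features come from a fixed, deterministic random-convolution
extractor built in-package (random convolutional features are a standard
texture-sensitive comparison basis), or from user-supplied weights loaded
from disk.  A missing weight file raises immediately; there is no silent
fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["LossConfig", "pl1_loss", "pl1_grad", "pl2_loss", "pl2_grad",
           "FeatureExtractor", "make_loss"]


@dataclass
class LossConfig:
    """Loss selection.

    kind : 'pl1' or 'pl2'.
    tau : PL1 scaling factor (> 0).  The display-scale motivation above sets
        the default of 1000.
    mix_weights : (pixel, perceptual) weights for PL2, non-negative, sum 1.
    pixel_term : 'mse' or 'rmse' for PL2's pixel-domain term.
    feature_layer : extractor stage used for the perceptual term
        ('block1' | 'block2' | 'block3').
    """

    kind: str = "pl1"
    tau: float = 1000.0
    mix_weights: tuple[float, float] = (0.3, 0.7)
    pixel_term: str = "mse"
    feature_layer: str = "block2"

    def __post_init__(self):
        if self.kind not in ("pl1", "pl2"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        w = self.mix_weights
        if min(w) < 0 or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("mix weights must be non-negative and sum to 1")
        if self.pixel_term not in ("mse", "rmse"):
            raise ValueError("pixel_term must be 'mse' or 'rmse'")


def _check_shapes(y: np.ndarray, t: np.ndarray):
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {t.shape}")


def pl1_loss(y_model: np.ndarray, y_fb: np.ndarray, tau: float = 1000.0) -> float:
    """tau-scaled mean squared error over all elements of the batch."""
    _check_shapes(y_model, y_fb)
    diff = np.asarray(y_model, np.float64) - np.asarray(y_fb, np.float64)
    return float(tau * np.mean(diff * diff))


def pl1_grad(y_model: np.ndarray, y_fb: np.ndarray, tau: float = 1000.0) -> np.ndarray:
    _check_shapes(y_model, y_fb)
    diff = np.asarray(y_model, np.float32) - np.asarray(y_fb, np.float32)
    return (2.0 * tau / diff.size) * diff


class FeatureExtractor:
    """Frozen convolutional feature pyramid for perceptual comparison.

    Three stages of (conv 3x3, ReLU, conv 3x3, ReLU, 2x2 max-pool) with
    widths 8/16/32; weights are He-initialized from a fixed seed and never
    trained, so the extractor is a deterministic function.  Inputs are
    single-channel image batches (N, H, W) or (N, H, W, 1).
    """

    WIDTHS = (8, 16, 32)
    LAYERS_PER_BLOCK = 5  # conv relu conv relu pool

    def __init__(self, seed: int = 7, weights: dict | None = None):
        net = nn.Network(seed)
        rng = np.random.default_rng(seed)
        c = 1
        self.block_nodes: dict[str, int] = {}
        for bi, f in enumerate(self.WIDTHS):
            for name in ("a", "b"):
                conv = nn.Conv2D(c, f, 3, trainable=False, rng=rng,
                                 name=f"b{bi}{name}")
                # He-normal weights suit the ReLU pyramid better than Glorot
                conv.w.value = (rng.standard_normal(conv.w.value.shape)
                                * np.sqrt(2.0 / (9 * c))).astype(np.float32)
                net.add(conv)
                net.add(nn.ReLU())
                c = f
            self.block_nodes[f"block{bi + 1}"] = len(net.nodes) - 1
            net.add(nn.MaxPool2())
        self.net = net
        if weights is not None:
            net.load_state_dict(weights)

    @classmethod
    def from_file(cls, path) -> "FeatureExtractor":
        """Load extractor weights from an .npz file; explicit error if absent."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(
                f"feature-extractor weights not found at {path}; install a "
                "weight file offline (npz with keys p0..pN matching the "
                "extractor layout) or use the built-in deterministic extractor")
        with np.load(path) as data:
            return cls(weights=dict(data))

    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[..., None]
        h, w = x.shape[1:3]
        f = 2 ** len(self.WIDTHS)
        ph, pw = (-h) % f, (-w) % f
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
        return x

    def features(self, x: np.ndarray, layer: str = "block2") -> np.ndarray:
        if layer not in self.block_nodes:
            raise ValueError(f"unknown feature layer {layer!r}")
        self.net.forward(self._prep(x), training=False)
        return self.net._outs[self.block_nodes[layer]]

    def features_and_input_grad(self, x: np.ndarray, dfeat: np.ndarray,
                                layer: str) -> np.ndarray:
        """Backpropagate a feature-space gradient to the input image."""
        x = self._prep(x)
        node = self.block_nodes[layer]
        self.net.forward(x, training=False)
        # truncate the graph at the requested node for the backward pass
        grads: list[np.ndarray | None] = [None] * len(self.net.nodes)
        grads[node] = np.asarray(dfeat, np.float32)
        for idx in range(node, 0, -1):
            layer_obj, parents = self.net.nodes[idx]
            if grads[idx] is None:
                continue
            dxs = layer_obj.backward(grads[idx])
            if not isinstance(dxs, tuple):
                dxs = (dxs,)
            for p, dx in zip(parents, dxs):
                grads[p] = dx if grads[p] is None else grads[p] + dx
        return grads[0]


_DEFAULT_EXTRACTOR: FeatureExtractor | None = None


def default_extractor() -> FeatureExtractor:
    global _DEFAULT_EXTRACTOR
    if _DEFAULT_EXTRACTOR is None:
        _DEFAULT_EXTRACTOR = FeatureExtractor()
    return _DEFAULT_EXTRACTOR


def _pixel_term(y, t, kind):
    mse = float(np.mean((np.asarray(y, np.float64) - np.asarray(t, np.float64)) ** 2))
    return np.sqrt(mse) if kind == "rmse" else mse


def pl2_loss(y_model: np.ndarray, y_fb: np.ndarray, config: LossConfig,
             extractor: FeatureExtractor | None = None) -> float:
    """w_pixel * pixel-term + w_perceptual * feature-space MSE."""
    _check_shapes(y_model, y_fb)
    w_pix, w_feat = config.mix_weights
    pix = _pixel_term(y_model, y_fb, config.pixel_term)
    feat = 0.0
    if w_feat > 0:
        ex = extractor or default_extractor()
        fy = ex.features(y_model, config.feature_layer)
        ft = ex.features(y_fb, config.feature_layer)
        feat = float(np.mean((fy.astype(np.float64) - ft.astype(np.float64)) ** 2))
    return w_pix * pix + w_feat * feat


def pl2_grad(y_model: np.ndarray, y_fb: np.ndarray, config: LossConfig,
             extractor: FeatureExtractor | None = None) -> np.ndarray:
    _check_shapes(y_model, y_fb)
    y = np.asarray(y_model, np.float32)
    t = np.asarray(y_fb, np.float32)
    w_pix, w_feat = config.mix_weights
    diff = y - t
    if config.pixel_term == "mse":
        g = w_pix * 2.0 / diff.size * diff
    else:
        rmse = float(np.sqrt(np.mean(diff.astype(np.float64) ** 2)))
        g = w_pix * diff / max(diff.size * rmse, 1e-30)
    if w_feat > 0:
        ex = extractor or default_extractor()
        fy = ex.features(y, config.feature_layer)
        ft = ex.features(t, config.feature_layer)
        dfeat = 2.0 / fy.size * (fy - ft)
        gin = ex.features_and_input_grad(y, dfeat, config.feature_layer)
        # strip the extractor's grid padding and channel axis back to y's shape
        if y.ndim == 2:
            gin = gin[0, : y.shape[0], : y.shape[1], 0]
        elif y.ndim == 3:
            gin = gin[:, : y.shape[1], : y.shape[2], 0]
        else:
            gin = gin[:, : y.shape[1], : y.shape[2], :]
        g = g + w_feat * gin
    return g.astype(np.float32)


def make_loss(config: LossConfig, extractor: FeatureExtractor | None = None):
    """Return (loss_fn, grad_fn) closures for the training loop."""
    if config.kind == "pl1":
        return (lambda y, t: pl1_loss(y, t, config.tau),
                lambda y, t: pl1_grad(y, t, config.tau))
    ex = extractor or default_extractor()
    return (lambda y, t: pl2_loss(y, t, config, ex),
            lambda y, t: pl2_grad(y, t, config, ex))
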