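"""Patch extraction and the training loop.

The training protocol: 64 random overlapping patches of 128 x 128 per image,
batch size 16, Adam (lr 1e-4, beta1 0.9, beta2 0.999, Keras-default
epsilon, no decay), up to 300 epochs with early stopping on the validation
loss and restoration of the best-validation weights.  Patches are drawn once
(not re-drawn per epoch) so the patch totals are fixed; epoch-level
shuffling uses a per-epoch derived seed, which keeps runs reproducible and
resumable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PairedDataset
from .losses import LossConfig, make_loss, FeatureExtractor
from .nets import Model
from . import nn

__all__ = ["PatchSet", "TrainConfig", "History", "extract_patches",
           "train_model", "save_checkpoint", "load_checkpoint"]


@dataclass
class PatchSet:
    """Aligned input/target patch stacks cut at identical coordinates."""

    inputs: np.ndarray           # (N, size, size) float32
    targets: np.ndarray
    source_indices: np.ndarray   # image id per patch
    seed: int = 0

    def __len__(self):
        return self.inputs.shape[0]


@dataclass
class TrainConfig:
    """Optimization protocol; defaults follow the published recipe."""

    batch_size: int = 16
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 300
    early_stop_patience: int = 20   # epochs; <= 0 disables early stopping
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.train_loss) + 1),
                             "train_loss": self.train_loss,
                             "val_loss": self.val_loss})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def extract_patches(pairs: PairedDataset, per_image: int = 64,
                    size: int = 128, seed: int = 0) -> PatchSet:
    """Cut ``per_image`` random overlapping square patches from each pair.

    Top-left corners are uniform over all valid placements; input and target
    patches are cut at identical coordinates.  Deterministic under ``seed``.
    """
    n, h, w = pairs.inputs.shape
    if h < size or w < size:
        raise ValueError(
            f"images ({h}x{w}) smaller than the patch size {size}")
    rng = np.random.default_rng(seed)
    total = per_image * n
    xs = np.empty((total, size, size), np.float32)
    ys = np.empty((total, size, size), np.float32)
    src = np.repeat(np.arange(n), per_image)
    k = 0
    for i in range(n):
        rows = rng.integers(0, h - size + 1, size=per_image)
        cols = rng.integers(0, w - size + 1, size=per_image)
        for r, c in zip(rows, cols):
            xs[k] = pairs.inputs[i, r:r + size, c:c + size]
            ys[k] = pairs.targets[i, r:r + size, c:c + size]
            k += 1
    return PatchSet(xs, ys, src, seed)


def _epoch_pass(model: Model, patches: PatchSet, config: TrainConfig,
                loss_fn, grad_fn, optimizer: nn.Adam | None,
                order: np.ndarray) -> float:
    """One pass over ``patches`` in the given order; trains if optimizer given."""
    bs = config.batch_size
    losses = []
    training = optimizer is not None
    for start in range(0, len(order), bs):
        idx = order[start:start + bs]
        xb = patches.inputs[idx][..., None]
        yb = patches.targets[idx][..., None]
        out = model.net.forward(xb, training=training)
        loss = loss_fn(out[..., 0], yb[..., 0])
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss ({loss}); check the loss scaling "
                f"(tau={getattr(config.loss, 'tau', None)}) and learning rate "
                f"(lr={config.learning_rate})")
        losses.append(loss)
        if training:
            model.net.zero_grad()
            g = grad_fn(out[..., 0], yb[..., 0])
            model.net.backward(np.asarray(g, np.float32)[..., None])
            optimizer.step()
    return float(np.mean(losses))


def train_model(model: Model, train_patches: PatchSet, val_patches: PatchSet,
                config: TrainConfig, extractor: FeatureExtractor | None = None,
                initial_epoch: int = 0, optimizer: nn.Adam | None = None,
                ) -> tuple[History, nn.Adam]:
    """Optimize the configured loss; early-stop on validation loss.

    Stops after ``max_epochs`` total epochs or once the validation loss has
    not improved for ``early_stop_patience`` consecutive epochs; the weights
    from the best-validation epoch are restored before returning.  Pass
    ``initial_epoch`` and the returned optimizer to resume a run.
    """
    loss_fn, grad_fn = make_loss(config.loss, extractor)
    if optimizer is None:
        optimizer = nn.Adam(model.net.params(), lr=config.learning_rate,
                            beta1=config.beta1, beta2=config.beta2)
    history = History()
    best_val = np.inf
    best_state = None
    since_best = 0
    for epoch in range(initial_epoch, config.max_epochs):
        model.net.rng = np.random.default_rng([config.seed, epoch, 17])
        order = np.random.default_rng([config.seed, epoch]).permutation(
            len(train_patches))
        tr = _epoch_pass(model, train_patches, config, loss_fn, grad_fn,
                         optimizer, order)
        va = _epoch_pass(model, val_patches, config, loss_fn, grad_fn, None,
                         np.arange(len(val_patches)))
        history.train_loss.append(tr)
        history.val_loss.append(va)
        if va < best_val - 1e-12:
            best_val = va
            best_state = {k: v.copy() for k, v in model.net.state_dict().items()}
            since_best = 0
        else:
            since_best += 1
            if config.early_stop_patience > 0 and since_best >= config.early_stop_patience:
                break
    if best_state is not None:
        model.net.load_state_dict(best_state)
    return history, optimizer


def save_checkpoint(path, model: Model, optimizer: nn.Adam,
                    config: TrainConfig, epoch: int):
    """Weights + Adam state + epoch counter, as a single npz."""
    payload = {f"w_{k}": v for k, v in model.net.state_dict().items()}
    payload.update({f"opt_{k}": v for k, v in optimizer.state_dict().items()})
    payload["epoch"] = np.asarray(epoch)
    np.savez(path, **payload)


def load_checkpoint(path, model: Model, config: TrainConfig,
                    ) -> tuple[nn.Adam, int]:
    with np.load(path) as data:
        weights = {k[2:]: data[k] for k in data.files if k.startswith("w_")}
        opt_state = {k[4:]: data[k] for k in data.files if k.startswith("opt_")}
        epoch = int(data["epoch"])
    model.net.load_state_dict(weights)
    optimizer = nn.Adam(model.net.params(), lr=config.learning_rate,
                        beta1=config.beta1, beta2=config.beta2)
    optimizer.load_state_dict(opt_state)
    return optimizer, epoch
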