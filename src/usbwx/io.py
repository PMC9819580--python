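"""Dataset containers, HDF5 layouts, image export and config snapshots.

HDF5 layouts
------------
Paired dataset: ``/pairs/input`` and ``/pairs/target`` (N x depth x lateral,
float32) with attributes ``fraction``, ``dynamic_range_db``, ``seed``.

RF/simulation file: ``/field``, ``/labels``, ``/rf`` (each N x depth x
lateral) with attributes ``pixel_spacing_mm``, ``center_frequency``,
``passband_width``, ``axial_sampling_frequency``, ``lateral_beamwidth``,
``seed``.

Orientation: row 0 is the shallowest depth; columns are lateral position.
Storage is float32; metrics elsewhere compute in float64.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import numpy as np
import yaml
from PIL import Image
import tifffile

__all__ = ["PairedDataset", "write_paired_h5", "read_paired_h5",
           "paired_h5_info", "write_rf_h5", "read_rf_h5", "export_images",
           "split_dataset", "write_config_snapshot"]


@dataclass
class PairedDataset:
    """Aligned (band-limited input, full-bandwidth target) image stacks."""

    inputs: np.ndarray    # (N, depth, lateral) float32
    targets: np.ndarray
    fraction: float = 0.2
    dynamic_range_db: float = 60.0
    seed: int = 0

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, np.float32)
        self.targets = np.asarray(self.targets, np.float32)
        if self.inputs.shape != self.targets.shape:
            raise ValueError("inputs and targets must share a shape")
        if self.inputs.ndim != 3:
            raise ValueError("expected stacks of shape (N, depth, lateral)")

    def __len__(self):
        return self.inputs.shape[0]

    def subset(self, idx) -> "PairedDataset":
        return PairedDataset(self.inputs[idx], self.targets[idx],
                             self.fraction, self.dynamic_range_db, self.seed)


def write_paired_h5(path, ds: PairedDataset):
    with h5py.File(path, "w") as fh:
        g = fh.create_group("pairs")
        g.create_dataset("input", data=ds.inputs, dtype="float32")
        g.create_dataset("target", data=ds.targets, dtype="float32")
        fh.attrs["fraction"] = ds.fraction
        fh.attrs["dynamic_range_db"] = ds.dynamic_range_db
        fh.attrs["seed"] = ds.seed


def _require(fh, key):
    node = fh.get(key)
    if node is None:
        raise KeyError(f"paired-dataset schema error: missing {key!r}")
    return node


def read_paired_h5(path) -> PairedDataset:
    with h5py.File(path, "r") as fh:
        inp = _require(fh, "pairs/input")[...]
        tgt = _require(fh, "pairs/target")[...]
        for attr in ("fraction", "dynamic_range_db", "seed"):
            if attr not in fh.attrs:
                raise KeyError(f"paired-dataset schema error: missing attribute {attr!r}")
        return PairedDataset(inp, tgt, float(fh.attrs["fraction"]),
                             float(fh.attrs["dynamic_range_db"]),
                             int(fh.attrs["seed"]))


def paired_h5_info(path) -> dict:
    """Header-only probe: image count and shape without reading pixel data."""
    with h5py.File(path, "r") as fh:
        shape = _require(fh, "pairs/input").shape
        return {"n_images": shape[0], "image_shape": shape[1:],
                "fraction": float(fh.attrs["fraction"])}


def write_rf_h5(path, fields: np.ndarray, labels: np.ndarray, rf: np.ndarray,
                pulse, pixel_spacing=(0.05, 0.1), seed: int = 0):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("field", data=np.asarray(fields, np.float32))
        fh.create_dataset("labels", data=np.asarray(labels, np.int32))
        fh.create_dataset("rf", data=np.asarray(rf, np.float32))
        fh.attrs["pixel_spacing_mm"] = pixel_spacing
        fh.attrs["center_frequency"] = pulse.center_frequency
        fh.attrs["passband_width"] = pulse.passband_width
        fh.attrs["axial_sampling_frequency"] = pulse.axial_sampling_frequency
        fh.attrs["lateral_beamwidth"] = pulse.lateral_beamwidth
        fh.attrs["pulse_bandwidth"] = pulse.pulse_bandwidth
        fh.attrs["seed"] = seed


def read_rf_h5(path) -> dict:
    from .phantom_sim import PulseSpec

    with h5py.File(path, "r") as fh:
        for key in ("field", "labels", "rf"):
            _require(fh, key)
        pulse = PulseSpec(float(fh.attrs["center_frequency"]),
                          float(fh.attrs["passband_width"]),
                          float(fh.attrs["axial_sampling_frequency"]),
                          float(fh.attrs["lateral_beamwidth"]),
                          float(fh.attrs["pulse_bandwidth"]))
        return {"field": fh["field"][...], "labels": fh["labels"][...],
                "rf": fh["rf"][...], "pulse": pulse,
                "seed": int(fh.attrs["seed"])}


def export_images(images, out_dir, fmt: str = "png8", prefix: str = "img"):
    """Write a stack of [0, 1] images as 8-bit PNG or float32 TIFF.

    png8 quantizes with round-half-up: byte = floor(p * 255 + 0.5).
    Out-of-range pixels raise; nothing is clipped silently.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(np.asarray(images, np.float32)):
        if img.min() < 0 or img.max() > 1:
            raise ValueError(f"image {i} has pixels outside [0, 1]")
        if fmt == "png8":
            data = np.floor(img.astype(np.float64) * 255.0 + 0.5).astype(np.uint8)
            p = out_dir / f"{prefix}_{i:04d}.png"
            Image.fromarray(data, mode="L").save(p)
        elif fmt == "tiff_float":
            p = out_dir / f"{prefix}_{i:04d}.tiff"
            tifffile.imwrite(p, img.astype(np.float32))
        else:
            raise ValueError(f"unknown format {fmt!r}")
        paths.append(p)
    return paths


def split_dataset(n: int, fractions=(0.6, 0.2, 0.2),
                  counts: tuple[int, int, int] | None = None,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled train/validation/test index split.

    By default a 60/20/20 split (rounded, remainder to the training set);
    explicit ``counts`` override the rounding when the published counts do
    not follow from it exactly.
    """
    if counts is None:
        n_val = int(round(fractions[1] * n))
        n_test = int(round(fractions[2] * n))
        n_train = n - n_val - n_test
    else:
        n_train, n_val, n_test = counts
        if n_train + n_val + n_test != n:
            raise ValueError("counts must sum to the dataset size")
    perm = np.random.default_rng(seed).permutation(n)
    return (perm[:n_train], perm[n_train:n_train + n_val],
            perm[n_train + n_val:])


def write_config_snapshot(path, config: dict):
    """YAML snapshot of a run's configuration, written next to its outputs."""
    def clean(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: clean(v) for k, v in asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, Path):
            return str(obj)
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(config), fh)
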