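"""Evaluation metrics: RMSE, PSNR, frequency-domain Pearson correlation,
error maps, and per-dataset aggregation.

RMSE is the root mean squared pixel difference; PSNR is
10*log10(Imax^2 / MSE) with Imax taken from the full-bandwidth reference
(so PSNR is not symmetric in its arguments); PC is the Pearson correlation
between the Fourier amplitude spectra of the two images, measuring how much
of the reference's frequency content the restoration recovers.  Aggregates
are arithmetic mean +/- sample standard deviation over test images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bmode import BModeImage

__all__ = ["rmse", "psnr", "pearson_freq_corr", "error_map",
           "MetricReport", "evaluate_dataset"]


def _pair(y_model, y_fb) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(y_model.pixels if isinstance(y_model, BModeImage) else y_model,
                   np.float64)
    b = np.asarray(y_fb.pixels if isinstance(y_fb, BModeImage) else y_fb,
                   np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rmse(y_model, y_fb) -> float:
    """Root of the mean squared pixel difference (symmetric)."""
    a, b = _pair(y_model, y_fb)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(y_model, y_fb) -> float:
    """10*log10(Imax^2 / MSE); Imax is the reference image's maximum.

    Identical images yield +inf (documented sentinel, excluded from
    aggregation with a warning there).
    """
    a, b = _pair(y_model, y_fb)
    mse = float(np.mean((a - b) ** 2))
    imax = float(b.max())
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(imax * imax / mse))


def pearson_freq_corr(y_model, y_fb, spectrum: str = "2d") -> float:
    """Pearson correlation of Fourier amplitude spectra, in [-1, 1].

    ``spectrum='2d'`` correlates the flattened magnitudes of the unshifted
    2D DFTs (default); ``'axial'`` uses the column-wise 1D axial spectra.
    """
    a, b = _pair(y_model, y_fb)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant image: amplitude-spectrum correlation undefined")
    if spectrum == "2d":
        fa = np.abs(np.fft.fft2(a)).ravel()
        fb = np.abs(np.fft.fft2(b)).ravel()
    elif spectrum == "axial":
        fa = np.abs(np.fft.fft(a, axis=0)).ravel()
        fb = np.abs(np.fft.fft(b, axis=0)).ravel()
    else:
        raise ValueError(f"unknown spectrum kind {spectrum!r}")
    sa, sb = fa.std(), fb.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant amplitude spectrum: correlation undefined")
    cov = np.mean((fa - fa.mean()) * (fb - fb.mean()))
    return float(cov / (sa * sb))


def error_map(y_model, y_fb) -> tuple[np.ndarray, tuple[float, float]]:
    """Signed difference image (model - reference) and its value range."""
    a, b = _pair(y_model, y_fb)
    diff = a - b
    return diff, (float(diff.min()), float(diff.max()))


@dataclass
class MetricReport:
    """Per-image metric rows and a mean +/- std aggregate per method."""

    per_image: pd.DataFrame    # image_id, method, rmse, psnr_db, pc
    aggregate: pd.DataFrame    # method, metric means and stds
    n_pixels: int
    i_max: float

    def to_csv(self, per_image_path, aggregate_path=None):
        self.per_image.to_csv(per_image_path, index=False)
        if aggregate_path is not None:
            self.aggregate.to_csv(aggregate_path, index=False)


def aggregate_rows(per_image: pd.DataFrame) -> pd.DataFrame:
    """Recompute the mean +/- std aggregate from per-image rows."""
    finite = per_image.replace([np.inf, -np.inf], np.nan)
    if not np.isfinite(per_image["psnr_db"]).all():
        import warnings
        warnings.warn("infinite PSNR rows excluded from the aggregate")
    g = finite.groupby("method", sort=False)
    out = g.agg(rmse_mean=("rmse", "mean"), rmse_std=("rmse", "std"),
                psnr_mean=("psnr_db", "mean"), psnr_std=("psnr_db", "std"),
                pc_mean=("pc", "mean"), pc_std=("pc", "std"))
    return out.reset_index()


def evaluate_dataset(pairs, methods: dict) -> MetricReport:
    """Run each enhancer over the dataset and tabulate all three metrics.

    ``methods`` maps a name to a callable taking the band-limited input image
    (2D array in [0, 1]) and returning the enhanced image.  The untouched
    band-limited input is always reported under 'band_limited'.
    """
    if len(pairs) == 0:
        raise ValueError("empty dataset")
    rows = []
    for i in range(len(pairs)):
        x = pairs.inputs[i]
        t = pairs.targets[i]
        outputs = {"band_limited": x}
        for name, fn in methods.items():
            y = fn(x)
            outputs[name] = y.pixels if isinstance(y, BModeImage) else np.asarray(y)
        for name, y in outputs.items():
            rows.append({"image_id": i, "method": name, "rmse": rmse(y, t),
                         "psnr_db": psnr(y, t), "pc": pearson_freq_corr(y, t)})
    per_image = pd.DataFrame(rows)
    return MetricReport(per_image, aggregate_rows(per_image),
                        n_pixels=int(pairs.inputs[0].size),
                        i_max=float(pairs.targets.max()))
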