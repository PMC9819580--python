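"""First-order speckle statistics: envelope histograms, speckle size via
autocorrelation FWHM, and resolution-ellipse eccentricity.

Speckle size along each image axis is read off the full width at half
maximum of the (mean-subtracted, linear) autocorrelation of an envelope
patch; the eccentricity sqrt(b^2 - a^2)/b of the ellipse spanned by the
shortest and longest FWHM axes quantifies how anisotropic the resolution
is - 0 for perfectly isotropic speckle.  Histograms are computed on the
envelope (pre-log-compression) image.
"""

from __future__ import annotations

import numpy as np

__all__ = ["speckle_histogram", "histogram_overlap", "speckle_size",
           "eccentricity", "speckle_report"]


def speckle_histogram(patch: np.ndarray, n_bins: int = 64,
                      value_range: tuple[float, float] | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalized histogram of an envelope patch.

    Returns (bin_edges, density); the densities integrate to 1 over the
    range.  Supply ``value_range`` to put two histograms on shared edges.
    """
    patch = np.asarray(patch, np.float64)
    if patch.size == 0:
        raise ValueError("empty patch")
    if n_bins < 2:
        raise ValueError("need at least two bins")
    density, edges = np.histogram(patch.ravel(), bins=n_bins,
                                  range=value_range, density=True)
    return edges, density


def histogram_overlap(patch1: np.ndarray, patch2: np.ndarray,
                      n_bins: int = 64) -> float:
    """Overlap coefficient of two envelope distributions, in [0, 1].

    Both histograms are built on shared bin edges spanning the union of the
    two value ranges; the overlap is the integral of the bin-wise minimum of
    the two densities (1 for identical samples, 0 for disjoint supports).
    """
    p1 = np.asarray(patch1, np.float64).ravel()
    p2 = np.asarray(patch2, np.float64).ravel()
    if p1.size == 0 or p2.size == 0:
        raise ValueError("empty patch")
    lo = min(p1.min(), p2.min())
    hi = max(p1.max(), p2.max())
    if hi == lo:
        return 1.0
    edges, d1 = speckle_histogram(p1, n_bins, (lo, hi))
    _, d2 = speckle_histogram(p2, n_bins, (lo, hi))
    width = edges[1] - edges[0]
    return float(np.minimum(d1, d2).sum() * width)


def _fwhm_from_profile(profile: np.ndarray) -> float:
    """FWHM of a symmetric correlation profile peaked (=1) at index 0.

    Linear interpolation between the two lags bracketing 0.5; the width is
    twice the positive-lag half width.
    """
    below = np.nonzero(profile < 0.5)[0]
    if below.size == 0:
        raise ValueError("autocorrelation never falls below half maximum; "
                         "patch too small for its correlation length")
    k = int(below[0])
    y0, y1 = profile[k - 1], profile[k]
    half = (k - 1) + (y0 - 0.5) / (y0 - y1)
    return float(2.0 * half)


def speckle_size(patch: np.ndarray) -> tuple[float, float]:
    """Speckle FWHM (axis 0, axis 1) in pixels from the 2D autocorrelation.

    The patch is mean-subtracted, linearly autocorrelated via zero-padded
    FFT, normalized to unit peak at zero lag, and the FWHM is measured along
    each axis through the peak.
    """
    patch = np.asarray(patch, np.float64)
    if patch.ndim != 2 or min(patch.shape) < 4:
        raise ValueError("need a 2D patch of at least 4x4 pixels")
    x = patch - patch.mean()
    if not x.any():
        raise ValueError("constant patch has no speckle")
    h, w = x.shape
    f = np.fft.rfft2(x, s=(2 * h - 1, 2 * w - 1))
    ac = np.fft.irfft2(f * np.conj(f), s=(2 * h - 1, 2 * w - 1))
    ac /= ac[0, 0]
    # unbiased axis profiles: undo the zero-padding overlap taper so a patch
    # smaller than its correlation support is detected rather than truncated
    prof0 = ac[:h, 0] * (h / (h - np.arange(h)))
    prof1 = ac[0, :w] * (w / (w - np.arange(w)))
    return _fwhm_from_profile(prof0), _fwhm_from_profile(prof1)


def eccentricity(fwhm_a: float, fwhm_b: float) -> float:
    """sqrt(b^2 - a^2)/b for the shortest (a) and longest (b) axes.

    Arguments are ordered canonically, so the result is invariant under
    swapping; equal axes (isotropic speckle) give 0.
    """
    if fwhm_a <= 0 or fwhm_b <= 0:
        raise ValueError("FWHM values must be positive")
    a, b = sorted((float(fwhm_a), float(fwhm_b)))
    return float(np.sqrt(b * b - a * a) / b)


def speckle_report(patches: np.ndarray, n_bins: int = 64) -> dict:
    """Mean +/- std speckle statistics over a stack of envelope patches."""
    patches = np.asarray(patches, np.float64)
    if patches.ndim == 2:
        patches = patches[None]
    sizes = np.array([speckle_size(p) for p in patches])
    eccs = np.array([eccentricity(*s) for s in sizes])
    return {
        "axial_fwhm_mean": float(sizes[:, 0].mean()),
        "axial_fwhm_std": float(sizes[:, 0].std(ddof=1)) if len(sizes) > 1 else 0.0,
        "lateral_fwhm_mean": float(sizes[:, 1].mean()),
        "lateral_fwhm_std": float(sizes[:, 1].std(ddof=1)) if len(sizes) > 1 else 0.0,
        "eccentricity_mean": float(eccs.mean()),
        "eccentricity_std": float(eccs.std(ddof=1)) if len(eccs) > 1 else 0.0,
        "n_patches": int(len(patches)),
    }
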