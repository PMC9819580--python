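"""Synthetic speckle phantoms and RF image simulation.

The in-vitro targets the restoration networks are meant for are
tissue-mimicking gelatin phantoms doped with silicon-carbide scatterers at
several concentrations, with embedded inclusions of differing echogenicity.
This module emulates them with the standard fully-developed-speckle model: a
sparse random reflectivity map convolved with a separable point-spread
function (an axial Gabor pulse times a lateral Gaussian beam profile).  The
result has the statistical structure real B-mode data exhibits (Rayleigh
envelope statistics in the dense-scatterer limit, anisotropic speckle) while
staying fully seeded and cheap to generate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "PulseSpec", "ScattererField", "RFImage", "InclusionSpec",
    "make_scatterer_field", "simulate_rf", "axial_psf", "lateral_psf",
]


@dataclass(frozen=True)
class PulseSpec:
    """Imaging pulse description.

    center_frequency : Hz, carrier of the axial pulse.
    passband_width : Hz, the transducer's full acquisition passband (the
        value the fractional bandwidths are taken relative to).
    axial_sampling_frequency : Hz, RF sampling rate along depth.
    lateral_beamwidth : Gaussian sigma of the lateral PSF, in pixels.
    pulse_bandwidth : Hz, full -6 dB width of the transmitted pulse's
        amplitude spectrum.  Defaults to 0.6 x the passband so that the
        pulse spectrum (including its Gaussian tails) lies inside the
        acquisition passband - which is what makes the unfiltered
        reconstruction genuinely "full bandwidth": a brick-wall filter at
        fraction 1.0 then passes essentially all pulse energy.
    """

    center_frequency: float = 7.8e6
    passband_width: float = 3.04e6
    axial_sampling_frequency: float = 31.25e6
    lateral_beamwidth: float = 2.0
    pulse_bandwidth: float | None = None

    def __post_init__(self):
        if self.pulse_bandwidth is None:
            object.__setattr__(self, "pulse_bandwidth", 0.6 * self.passband_width)
        if not 0 < self.passband_width < self.axial_sampling_frequency:
            raise ValueError("passband must be positive and below the sampling rate")
        if self.center_frequency <= self.passband_width / 2:
            raise ValueError("center frequency must exceed half the passband")
        if self.lateral_beamwidth <= 0:
            raise ValueError("lateral beamwidth must be positive")
        if not 0 < self.pulse_bandwidth <= self.passband_width:
            raise ValueError("pulse bandwidth must be positive and fit the passband")


@dataclass
class ScattererField:
    """2D reflectivity map with labeled inclusion regions.

    ``amplitudes`` is the signed scatterer reflectivity (dimensionless),
    ``region_labels`` an integer map (0 = background, k > 0 = inclusion k).
    """

    amplitudes: np.ndarray
    pixel_spacing: tuple[float, float] = (0.05, 0.1)  # (axial, lateral) mm
    region_labels: np.ndarray = field(default=None)
    seed: int = 0

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, np.float32)
        if self.region_labels is None:
            self.region_labels = np.zeros(self.amplitudes.shape, np.int32)
        self.region_labels = np.asarray(self.region_labels, np.int32)
        if self.amplitudes.shape != self.region_labels.shape:
            raise ValueError("amplitudes and region_labels must share a shape")


@dataclass
class RFImage:
    """Beamformed radio-frequency image (depth x lateral).

    Axis 0 is depth (the axis that carries the carrier oscillation and gets
    band-filtered), axis 1 is lateral position.
    """

    samples: np.ndarray
    axial_sampling_frequency: float
    pulse: PulseSpec

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.dtype not in (np.float32, np.float64):
            self.samples = self.samples.astype(np.float32)
        if self.samples.ndim != 2:
            raise ValueError("RF image must be 2D (depth x lateral)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF image contains non-finite values")


@dataclass(frozen=True)
class InclusionSpec:
    """Axis-aligned rectangle or circle painted into the label map.

    kind='rect': center=(row, col), size=(height, width) in pixels.
    kind='circle': center=(row, col), radius in pixels.
    """

    kind: str
    center: tuple[float, float]
    size: tuple[float, float] | None = None
    radius: float | None = None

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        r0, c0 = self.center
        if self.kind == "rect":
            h, w = self.size
            m = ((np.abs(rr - r0) <= h / 2) & (np.abs(cc - c0) <= w / 2))
            lo_r, hi_r = r0 - h / 2, r0 + h / 2
            lo_c, hi_c = c0 - w / 2, c0 + w / 2
            inside = lo_r >= 0 and hi_r <= shape[0] - 1 and lo_c >= 0 and hi_c <= shape[1] - 1
        elif self.kind == "circle":
            m = (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius ** 2
            inside = (r0 - self.radius >= 0 and r0 + self.radius <= shape[0] - 1
                      and c0 - self.radius >= 0 and c0 + self.radius <= shape[1] - 1)
        else:
            raise ValueError(f"unknown inclusion kind {self.kind!r}")
        if not inside:
            raise ValueError(f"inclusion {self} does not fit inside grid {shape}")
        return m


def make_scatterer_field(shape: tuple[int, int], density: float,
                         contrast_levels: list[float] | None = None,
                         inclusion_specs: list[InclusionSpec] | None = None,
                         seed: int = 0,
                         pixel_spacing: tuple[float, float] = (0.05, 0.1),
                         ) -> ScattererField:
    """Draw a sparse random scatterer field with labeled inclusions.

    Each pixel holds a scatterer with probability ``density``; amplitudes are
    uniform in [-1, 1] (zero-mean, symmetric) scaled by the per-region
    echogenicity multiplier ``contrast_levels[label]``.  ``density=0`` yields
    an all-zero field with an empty label map.  Deterministic under ``seed``.
    """
    depth, lateral = shape
    if depth <= 0 or lateral <= 0:
        raise ValueError("shape must be positive")
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    inclusion_specs = inclusion_specs or []
    contrast_levels = list(contrast_levels) if contrast_levels is not None else [1.0]
    if len(contrast_levels) < len(inclusion_specs) + 1:
        raise ValueError("need one contrast level per region (background + inclusions)")

    labels = np.zeros(shape, np.int32)
    for k, spec in enumerate(inclusion_specs, start=1):
        labels[spec.mask(shape)] = k

    rng = np.random.default_rng(seed)
    if density == 0:
        return ScattererField(np.zeros(shape, np.float32), pixel_spacing,
                              np.zeros(shape, np.int32), seed)
    present = rng.random(shape) < density
    amp = rng.uniform(-1.0, 1.0, size=shape).astype(np.float32)
    amp *= present
    contrast = np.asarray(contrast_levels, np.float32)[labels]
    amp *= contrast
    return ScattererField(amp, pixel_spacing, labels, seed)


def axial_psf(pulse: PulseSpec) -> np.ndarray:
    """Gabor pulse: cosine at the center frequency under a Gaussian envelope.

    The envelope is chosen so the -6 dB full width of the amplitude spectrum
    equals ``pulse.pulse_bandwidth``.
    """
    # |G(f)| = exp(-(f-fc)^2 / (2 sf^2)); -6 dB full width W: W = 2 sf sqrt(2 ln 10^{0.3})
    sf = pulse.pulse_bandwidth / (2.0 * np.sqrt(2.0 * np.log(10 ** 0.3)))
    st = 1.0 / (2.0 * np.pi * sf)  # time-domain sigma
    fs = pulse.axial_sampling_frequency
    half = max(int(np.ceil(4.0 * st * fs)), 2)
    t = np.arange(-half, half + 1) / fs
    return (np.exp(-0.5 * (t / st) ** 2)
            * np.cos(2 * np.pi * pulse.center_frequency * t)).astype(np.float32)


def lateral_psf(pulse: PulseSpec) -> np.ndarray:
    """Gaussian lateral beam profile, unit peak, truncated at 4 sigma."""
    s = pulse.lateral_beamwidth
    half = max(int(np.ceil(4.0 * s)), 1)
    x = np.arange(-half, half + 1)
    return np.exp(-0.5 * (x / s) ** 2).astype(np.float32)


def simulate_rf(field: ScattererField, pulse: PulseSpec) -> RFImage:
    """Convolve a scatterer field with the separable PSF ('same' mode).

    Linear in the field; a single unit scatterer reproduces the PSF centred
    at its position.
    """
    ax = axial_psf(pulse)
    lat = lateral_psf(pulse)
    h, w = field.amplitudes.shape
    if len(ax) > h or len(lat) > w:
        raise ValueError(
            f"PSF ({len(ax)}x{len(lat)}) larger than image ({h}x{w}); "
            "increase the image size or shorten the pulse")
    rf = fftconvolve(field.amplitudes, ax[:, None], mode="same")
    rf = fftconvolve(rf, lat[None, :], mode="same")
    return RFImage(rf.astype(np.float32), pulse.axial_sampling_frequency, pulse)
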