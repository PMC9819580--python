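"""Image-formation chain: band limiting, envelope detection, log compression.

Band-limited / full-bandwidth image pairs are produced by band-pass filtering
the RF data along the axial axis to a stated fraction of the transducer's
full passband, then envelope-detecting (analytic-signal magnitude),
log-compressing to a display dynamic range and normalizing to [0, 1].  Both
members of a pair are normalized by the full-bandwidth envelope maximum so
they share one intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .phantom_sim import PulseSpec, RFImage

__all__ = ["RFImage", "BandLimitSpec", "BModeImage", "band_limit", "envelope",
           "to_bmode", "make_pair"]


@dataclass(frozen=True)
class BandLimitSpec:
    """Fractional band-pass specification.

    ``fraction`` of the full passband width is retained, centred on the pulse
    center frequency.  ``filter_kind`` selects the realization: a zero-phase
    FFT brick-wall mask (exact fractional bandwidth, idempotent) or a
    forward-backward Butterworth of the given order.
    """

    fraction: float
    filter_kind: str = "brickwall_fft"
    order: int = 4

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        if self.filter_kind not in ("brickwall_fft", "butterworth"):
            raise ValueError(f"unknown filter kind {self.filter_kind!r}")


@dataclass
class BModeImage:
    """Envelope-detected, log-compressed image with pixels in [0, 1].

    ``provenance`` tags the processing route, e.g. ``band_limited(0.2)``,
    ``full_bandwidth``, ``model(rednet)``, ``he`` or ``clahe``.
    """

    pixels: np.ndarray
    dynamic_range_db: float = 60.0
    provenance: str = "full_bandwidth"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, np.float32)
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("B-mode pixels must lie in [0, 1]")
        if self.dynamic_range_db <= 0:
            raise ValueError("dynamic range must be positive")


def band_limit(rf: RFImage, spec: BandLimitSpec) -> RFImage:
    """Zero-phase axial band-pass to ``fraction`` x full passband width.

    The retained band is centred at the pulse center frequency.  Output shape
    equals input shape; structures are not shifted axially.
    """
    pulse = rf.pulse
    fs = rf.axial_sampling_frequency
    width = spec.fraction * pulse.passband_width
    fc = pulse.center_frequency
    if fc + width / 2 > fs / 2:
        raise ValueError("reduced passband exceeds the Nyquist frequency")
    n = rf.samples.shape[0]
    if spec.filter_kind == "brickwall_fft":
        freqs = np.fft.fftfreq(n, d=1.0 / fs)
        if width / 2 < fs / n:
            raise ValueError("passband collapses below one frequency bin")
        mask = (np.abs(np.abs(freqs) - fc) <= width / 2).astype(np.float64)
        spec_ax = np.fft.fft(rf.samples.astype(np.float64), axis=0)
        out = np.fft.ifft(spec_ax * mask[:, None], axis=0).real
    else:
        lo, hi = fc - width / 2, fc + width / 2
        sos = butter(spec.order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        out = sosfiltfilt(sos, rf.samples.astype(np.float64), axis=0)
    # kept in float64: the brick-wall realization is idempotent to ~1e-15
    return RFImage(out, fs, pulse)


def envelope(rf: RFImage) -> np.ndarray:
    """Magnitude of the axial analytic signal (carrier removed)."""
    return np.abs(hilbert(rf.samples.astype(np.float64), axis=0))


def to_bmode(rf: RFImage, dynamic_range_db: float = 60.0,
             norm_max: float | None = None,
             provenance: str = "full_bandwidth") -> BModeImage:
    """Envelope detection, log compression and [0, 1] normalization.

    20*log10(envelope / norm_max), clipped to [-dynamic_range_db, 0] and
    mapped affinely to [0, 1].  ``norm_max`` defaults to the image's own
    envelope maximum; pass the full-bandwidth maximum to put both members of
    a pair on one scale.
    """
    if dynamic_range_db <= 0:
        raise ValueError("dynamic range must be positive")
    env = envelope(rf)
    mx = float(env.max()) if norm_max is None else float(norm_max)
    if mx <= 0:
        raise ValueError("cannot normalize an all-zero RF image")
    db = 20.0 * np.log10(np.maximum(env / mx, 1e-30))
    db = np.clip(db, -dynamic_range_db, 0.0)
    pix = (db + dynamic_range_db) / dynamic_range_db
    return BModeImage(pix.astype(np.float32), dynamic_range_db, provenance)


def make_pair(rf: RFImage, fraction: float, dynamic_range_db: float = 60.0,
              filter_kind: str = "brickwall_fft") -> tuple[BModeImage, BModeImage]:
    """(band-limited input, full-bandwidth target) B-mode pair.

    Both images are normalized by the full-bandwidth envelope maximum so that
    pixel-wise error metrics compare on a shared intensity scale.
    """
    spec = BandLimitSpec(fraction, filter_kind)
    full_env_max = float(envelope(rf).max())
    target = to_bmode(rf, dynamic_range_db, norm_max=full_env_max,
                      provenance="full_bandwidth")
    limited = band_limit(rf, spec)
    inp = to_bmode(limited, dynamic_range_db, norm_max=full_env_max,
                   provenance=f"band_limited({fraction})")
    return inp, target
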