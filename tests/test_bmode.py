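"""Band limiting, envelope detection, log compression and pair formation."""

import numpy as np
import pytest

from usbwx.bmode import (BandLimitSpec, band_limit, envelope, make_pair, to_bmode)
from usbwx.metrics import rmse
from usbwx.phantom_sim import PulseSpec, RFImage, make_scatterer_field, simulate_rf


def _bin_aligned(f, fs, n):
    """Snap a frequency onto the length-n DFT grid (no spectral leakage)."""
    return round(f / fs * n) * fs / n


def _inband_rf(pulse, n=256, m=32):
    """Sum of bin-aligned axial sinusoids strictly inside the full passband."""
    fs = pulse.axial_sampling_frequency
    t = np.arange(n) / fs
    fc, w = pulse.center_frequency, pulse.passband_width
    sig = sum(np.cos(2 * np.pi * _bin_aligned(fc + df, fs, n) * t)
              for df in (-0.3 * w, 0.0, 0.3 * w))
    return RFImage(np.tile(sig[:, None], (1, m)).astype(np.float64),
                   fs, pulse)


class TestBandLimit:
    def test_fraction_one_is_identity_on_inband_signal(self, pulse):
        rf = _inband_rf(pulse)
        out = band_limit(rf, BandLimitSpec(1.0, "brickwall_fft"))
        scale = np.abs(rf.samples).max()
        np.testing.assert_allclose(out.samples, rf.samples,
                                   atol=1e-6 * scale)

    def test_stopband_suppression_on_white_noise(self, pulse):
        rng = np.random.default_rng(0)
        rf = RFImage(rng.standard_normal((512, 16)).astype(np.float32),
                     pulse.axial_sampling_frequency, pulse)
        out = band_limit(rf, BandLimitSpec(0.2, "brickwall_fft"))
        spec = np.abs(np.fft.rfft(out.samples.astype(np.float64), axis=0)) ** 2
        freqs = np.fft.rfftfreq(512, 1.0 / pulse.axial_sampling_frequency)
        half = 0.2 * pulse.passband_width / 2
        in_band = np.abs(freqs - pulse.center_frequency) <= half
        out_band_max = spec[~in_band].max()
        in_band_mean = spec[in_band].mean()
        assert out_band_max <= 1e-10 * in_band_mean

    def test_retained_width_is_fraction_of_printed_passband(self, pulse):
        # 20% of the 3.04 MHz passband -> 0.608 MHz retained width
        assert pulse.passband_width == 3.04e6
        rng = np.random.default_rng(1)
        n = 2048
        rf = RFImage(rng.standard_normal((n, 4)).astype(np.float32),
                     pulse.axial_sampling_frequency, pulse)
        out = band_limit(rf, BandLimitSpec(0.2, "brickwall_fft"))
        spec = np.abs(np.fft.rfft(out.samples.astype(np.float64), axis=0)).mean(1)
        freqs = np.fft.rfftfreq(n, 1.0 / pulse.axial_sampling_frequency)
        passed = freqs[spec > 1e-8 * spec.max()]
        width = passed.max() - passed.min()
        bin_w = pulse.axial_sampling_frequency / n
        assert width == pytest.approx(0.2 * 3.04e6, abs=2 * bin_w)
        assert width == pytest.approx(0.608e6, abs=2 * bin_w)

    def test_brickwall_idempotent(self, speckle_rf):
        spec = BandLimitSpec(0.4, "brickwall_fft")
        once = band_limit(speckle_rf, spec).samples
        twice = band_limit(band_limit(speckle_rf, spec), spec).samples
        assert np.max(np.abs(once - twice)) <= 1e-10 * np.abs(once).max()

    def test_zero_phase_no_axial_shift(self, pulse):
        # a single pulse echo keeps its envelope peak position
        field = make_scatterer_field((256, 32), 0.0, seed=0)
        field.amplitudes[128, 16] = 1.0
        rf = simulate_rf(field, pulse)
        out = band_limit(rf, BandLimitSpec(0.4, "brickwall_fft"))
        peak_in = np.argmax(np.abs(envelope(rf))[:, 16])
        peak_out = np.argmax(np.abs(envelope(out))[:, 16])
        assert abs(int(peak_in) - int(peak_out)) <= 1

    def test_butterworth_variant_attenuates_stopband(self, pulse):
        rng = np.random.default_rng(2)
        rf = RFImage(rng.standard_normal((512, 8)).astype(np.float32),
                     pulse.axial_sampling_frequency, pulse)
        out = band_limit(rf, BandLimitSpec(0.2, "butterworth", order=6))
        spec = np.abs(np.fft.rfft(out.samples.astype(np.float64), axis=0)) ** 2
        freqs = np.fft.rfftfreq(512, 1.0 / pulse.axial_sampling_frequency)
        far = np.abs(freqs - pulse.center_frequency) > pulse.passband_width
        near = np.abs(freqs - pulse.center_frequency) <= 0.1 * pulse.passband_width
        assert spec[far].mean() < 1e-4 * spec[near].mean()

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            BandLimitSpec(fraction)

    def test_subbin_passband_rejected(self, pulse):
        rf = RFImage(np.ones((16, 4), np.float32),
                     pulse.axial_sampling_frequency, pulse)
        with pytest.raises(ValueError, match="frequency bin"):
            band_limit(rf, BandLimitSpec(1e-4, "brickwall_fft"))


class TestToBmode:
    def test_sinusoid_envelope_is_amplitude(self, pulse):
        n = 512
        fs = pulse.axial_sampling_frequency
        t = np.arange(n) / fs
        amp = 0.7
        f0 = _bin_aligned(pulse.center_frequency, fs, n)
        sig = amp * np.cos(2 * np.pi * f0 * t)
        rf = RFImage(np.tile(sig[:, None], (1, 8)).astype(np.float32),
                     pulse.axial_sampling_frequency, pulse)
        env = envelope(rf)
        interior = env[n // 4: 3 * n // 4]
        np.testing.assert_allclose(interior, amp, rtol=1e-3)
        bm = to_bmode(rf, 60.0)
        assert bm.pixels[n // 4: 3 * n // 4].min() > 0.999

    def test_normalization_contract(self, speckle_rf):
        bm = to_bmode(speckle_rf, 60.0)
        assert bm.pixels.max() == pytest.approx(1.0, abs=1e-6)
        assert bm.pixels.min() >= 0.0

    def test_gabor_pulse_envelope_matches_gaussian(self, pulse):
        # closed-form envelope of a Gabor pulse is its Gaussian modulation
        fs = pulse.axial_sampling_frequency
        n = 1024
        t = (np.arange(n) - n / 2) / fs
        st = 2e-7
        gauss = np.exp(-0.5 * (t / st) ** 2)
        sig = gauss * np.cos(2 * np.pi * pulse.center_frequency * t)
        rf = RFImage(np.tile(sig[:, None], (1, 4)).astype(np.float32), fs, pulse)
        env = envelope(rf)[:, 0]
        core = gauss >= 0.5  # the peak half
        np.testing.assert_allclose(env[core], gauss[core], rtol=1e-2)

    def test_all_zero_rf_rejected(self, pulse):
        rf = RFImage(np.zeros((64, 8), np.float32),
                     pulse.axial_sampling_frequency, pulse)
        with pytest.raises(ValueError, match="all-zero"):
            to_bmode(rf, 60.0)

    def test_log_compression_monotone(self, speckle_rf):
        env = envelope(speckle_rf).ravel()
        bm = to_bmode(speckle_rf, 60.0).pixels.ravel()
        floor = env.max() * 10 ** (-60 / 20)
        above = env > floor
        order = np.argsort(env[above])
        assert np.all(np.diff(bm[above][order]) >= 0)

    def test_dynamic_range_validation(self, speckle_rf):
        with pytest.raises(ValueError):
            to_bmode(speckle_rf, -10.0)


class TestMakePair:
    def test_fraction_one_pair_nearly_equal(self, speckle_rf):
        # degenerate pair: the brick wall at fraction 1 removes only the
        # Gaussian tail energy outside the acquisition passband (<1%)
        inp, tgt = make_pair(speckle_rf, 1.0)
        full = rmse(inp.pixels, tgt.pixels)
        limited = rmse(*(b.pixels for b in make_pair(speckle_rf, 0.2)))
        assert full < 0.05
        assert full < 0.5 * limited

    def test_fraction_02_removes_information(self, speckle_rf):
        inp, tgt = make_pair(speckle_rf, 0.2)
        assert rmse(inp.pixels, tgt.pixels) > 0.0

    def test_pair_share_shape_and_scale(self, speckle_rf):
        inp, tgt = make_pair(speckle_rf, 0.2)
        assert inp.pixels.shape == tgt.pixels.shape
        assert inp.dynamic_range_db == tgt.dynamic_range_db
        assert inp.provenance == "band_limited(0.2)"
        assert tgt.provenance == "full_bandwidth"

    def test_rmse_strictly_decreasing_in_fraction(self, pulse):
        # monotone spectral truncation, averaged over seeded simulations
        means = {f: [] for f in (0.2, 0.4, 0.6)}
        for seed in range(10):
            field = make_scatterer_field((128, 128), 0.6, seed=100 + seed)
            rf = simulate_rf(field, pulse)
            for f in means:
                inp, tgt = make_pair(rf, f)
                means[f].append(rmse(inp.pixels, tgt.pixels))
        m = {f: np.mean(v) for f, v in means.items()}
        assert m[0.2] > m[0.4] > m[0.6]
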