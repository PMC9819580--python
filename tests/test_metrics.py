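"""Metric implementations against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from usbwx.bmode import make_pair
from usbwx.io import PairedDataset
from usbwx.metrics import (aggregate_rows, error_map, evaluate_dataset,
                           pearson_freq_corr, psnr, rmse)
from usbwx.phantom_sim import make_scatterer_field, simulate_rf


# -- independent oracles (elementwise loops / two-pass statistics) ----------

def naive_rmse(a, b):
    total = 0.0
    n = 0
    for x, y in zip(a.ravel().tolist(), b.ravel().tolist()):
        total += (x - y) ** 2
        n += 1
    return (total / n) ** 0.5


def naive_psnr(a, b):
    imax = max(b.ravel().tolist())
    mse = naive_rmse(a, b) ** 2
    return 10.0 * np.log10(imax * imax / mse)


def naive_pearson(u, v):
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    cov = sum((x - mu) * (y - mv) for x, y in zip(u, v)) / n
    su = (sum((x - mu) ** 2 for x in u) / n) ** 0.5
    sv = (sum((y - mv) ** 2 for y in v) / n) ** 0.5
    return cov / (su * sv)


def naive_pc(a, b):
    fa = np.abs(np.fft.fft2(a)).ravel().tolist()
    fb = np.abs(np.fft.fft2(b)).ravel().tolist()
    return naive_pearson(fa, fb)


class TestAgainstOracles:
    def test_all_metrics_agree_with_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.random((16, 16))
            b = rng.random((16, 16))
            assert abs(rmse(a, b) - naive_rmse(a, b)) <= 1e-10
            assert abs(psnr(a, b) - naive_psnr(a, b)) <= 1e-10
            assert abs(pearson_freq_corr(a, b) - naive_pc(a, b)) <= 1e-10

    def test_error_map_range_matches_brute_force(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((12, 12)), rng.random((12, 12))
        diff, (lo, hi) = error_map(a, b)
        assert hi == max((a - b).ravel().tolist())
        assert lo == min((a - b).ravel().tolist())
        assert max(abs(lo), abs(hi)) == np.abs(diff).max()


class TestClosedForms:
    def test_rmse_trivial_cases(self):
        z, o = np.zeros((8, 8)), np.ones((8, 8))
        assert rmse(z, z) == 0.0
        assert rmse(z, o) == 1.0

    def test_psnr_closed_forms(self):
        t = np.zeros((10, 10))
        t[0, 0] = 1.0  # Imax = 1
        y1 = t + 0.1
        y1[0, 0] = 1.1  # constant offset 0.1 -> RMSE 0.1
        assert psnr(y1 - 0.1 + 0.1, t) == pytest.approx(20.0, abs=1e-9)
        y2 = t + 0.5
        assert psnr(y2, t) == pytest.approx(10 * np.log10(1 / 0.25), abs=1e-4)
        assert psnr(y2, t) == pytest.approx(6.0206, abs=1e-3)

    def test_psnr_algebraic_identity(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((16, 16)), rng.random((16, 16))
        expected = 20 * np.log10(b.max()) - 20 * np.log10(rmse(a, b))
        assert psnr(a, b) == pytest.approx(expected, abs=1e-10)

    def test_identical_images_infinite_psnr(self):
        a = np.random.default_rng(3).random((8, 8))
        assert psnr(a, a) == np.inf

    def test_pc_self_correlation_is_one(self):
        a = np.random.default_rng(4).random((16, 16))
        assert pearson_freq_corr(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_pc_invariant_to_positive_scaling(self):
        a = np.random.default_rng(5).random((16, 16))
        assert pearson_freq_corr(3.0 * a, a) == pytest.approx(1.0, abs=1e-10)

    def test_pc_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_freq_corr(np.ones((8, 8)), np.ones((8, 8)))

    def test_error_map_trivial_cases(self):
        a = np.random.default_rng(6).random((8, 8))
        diff, rng_ = error_map(a, a)
        assert not diff.any() and rng_ == (0.0, 0.0)
        diff, rng_ = error_map(a + 0.1, a)
        np.testing.assert_allclose(diff, 0.1)


class TestSymmetry:
    def test_rmse_symmetric_psnr_not(self):
        rng = np.random.default_rng(7)
        a = rng.random((16, 16))
        b = 0.5 * rng.random((16, 16))  # different maxima
        assert rmse(a, b) == rmse(b, a)
        assert psnr(a, b) != psnr(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.zeros((4, 4)), np.zeros((5, 5)))


class TestEvaluateDataset:
    def _tiny_pairs(self):
        rng = np.random.default_rng(8)
        t = rng.random((2, 16, 16)).astype(np.float32)
        x = np.clip(t + 0.1, 0, 1)
        return PairedDataset(x, t)

    def test_identity_on_target_scores_perfectly(self):
        pairs = self._tiny_pairs()
        report = evaluate_dataset(pairs, {"oracle": lambda x: pairs.targets[0]})
        row = report.per_image.query("method == 'oracle' and image_id == 0").iloc[0]
        assert row.rmse == 0.0 and row.pc == pytest.approx(1.0, abs=1e-9)

    def test_constant_difference_aggregate(self):
        # hand-set constant differences 0.1 and 0.3 -> aggregate mean 0.2
        rng = np.random.default_rng(9)
        t = (0.5 * rng.random((2, 8, 8))).astype(np.float32)
        x = t.copy()
        x[0] += 0.1
        x[1] += 0.3
        report = evaluate_dataset(PairedDataset(x, t), {})
        agg = report.aggregate.set_index("method").loc["band_limited"]
        assert agg.rmse_mean == pytest.approx(0.2, abs=1e-7)

    def test_aggregate_recomputable_from_per_image_csv(self, tmp_path):
        pairs = self._tiny_pairs()
        report = evaluate_dataset(pairs, {"he_like": lambda x: x ** 0.5})
        path = tmp_path / "per_image.csv"
        report.to_csv(path)
        reread = aggregate_rows(pd.read_csv(path))
        pd.testing.assert_frame_equal(
            reread.sort_values("method").reset_index(drop=True),
            report.aggregate.sort_values("method").reset_index(drop=True))

    def test_empty_dataset_rejected(self):
        pairs = PairedDataset(np.zeros((0, 4, 4)), np.zeros((0, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            evaluate_dataset(pairs, {})


def test_pc_rises_as_rmse_falls_across_fractions(pulse):
    """Frequency-content recovery and pixel error move oppositely with
    retained bandwidth."""
    rmses, pcs = [], []
    for f in (0.2, 0.4, 0.6):
        vals_r, vals_p = [], []
        for seed in range(5):
            rf = simulate_rf(make_scatterer_field((128, 128), 0.6, seed=seed),
                             pulse)
            inp, tgt = make_pair(rf, f)
            vals_r.append(rmse(inp.pixels, tgt.pixels))
            vals_p.append(pearson_freq_corr(inp.pixels, tgt.pixels))
        rmses.append(np.mean(vals_r))
        pcs.append(np.mean(vals_p))
    assert rmses[0] > rmses[1] > rmses[2]
    assert pcs[0] < pcs[1] < pcs[2]
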