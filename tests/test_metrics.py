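import numpy as np
import pytest

import cestrecon as cr
from cestrecon.imaging import CESTImageStack
from cestrecon.metrics import (
    abs_error_modulus, evaluate_stacks, pooled_regression, psnr_per_offset,
    regression_r2, ssim_pair, ssim_per_offset, table2,
)


def _stack(data, grid=None, mask=None):
    K = data.shape[2]
    grid = grid or cr.OffsetGrid(np.linspace(-1, 1, K))
    return CESTImageStack(np.asarray(data, dtype=float), grid, mask=mask)


@pytest.fixture()
def random_pair():
    rng = np.random.default_rng(0)
    truth = rng.uniform(0.2, 0.9, (16, 16, 4))
    recon = truth + rng.normal(0, 0.02, truth.shape)
    return _stack(recon), _stack(truth)


class TestAbsErrorModulus:
    def test_identical_stacks_give_zero(self, random_pair):
        _, truth = random_pair
        err, per_offset = abs_error_modulus(truth, truth)
        assert np.all(err[truth.mask] == 0)
        assert np.all(per_offset == 0)

    def test_constant_shift_is_three_percent(self):
        truth = _stack(np.full((8, 8, 3), 0.50))
        recon = _stack(np.full((8, 8, 3), 0.53))
        err, per_offset = abs_error_modulus(recon, truth)
        assert np.allclose(err[truth.mask], 3.0)
        assert np.allclose(per_offset, 3.0)

    def test_per_offset_means_match_loop(self, random_pair):
        recon, truth = random_pair
        _, per_offset = abs_error_modulus(recon, truth)
        for k in range(truth.data.shape[2]):
            direct = np.mean(np.abs(recon.data[:, :, k] - truth.data[:, :, k])
                             [truth.mask]) * 100
            assert per_offset[k] == pytest.approx(direct, abs=1e-12)

    def test_grid_mismatch_rejected(self, random_pair):
        recon, truth = random_pair
        other = _stack(truth.data, grid=cr.OffsetGrid(np.linspace(-2, 2, 4)))
        with pytest.raises(ValueError, match="grids"):
            abs_error_modulus(recon, other)


class TestRegression:
    def test_identity_relation(self, random_pair):
        _, truth = random_pair
        slope, intercept, r2 = regression_r2(truth, truth)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_exact_linear_relation(self, random_pair):
        _, truth = random_pair
        recon = _stack(2.0 * truth.data + 0.1)
        slope, intercept, r2 = regression_r2(recon, truth)
        assert slope == pytest.approx(2.0, abs=1e-10)
        assert intercept == pytest.approx(0.1, abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_r2_matches_squared_correlation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=4000)
        y = 0.7 * x + rng.normal(size=4000)
        _, _, r2 = pooled_regression(x, y)
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)

    def test_constant_truth_is_undefined(self):
        truth = _stack(np.full((4, 4, 2), 0.5))
        recon = _stack(np.random.default_rng(0).uniform(0, 1, (4, 4, 2)))
        with pytest.raises(ValueError, match="undefined"):
            regression_r2(recon, truth)


class TestSSIM:
    def test_self_similarity_is_one(self, random_pair):
        _, truth = random_pair
        assert np.allclose(ssim_per_offset(truth, truth), 1.0, atol=1e-12)

    def test_matches_reference_implementation(self):
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, (64, 64))
        y = np.clip(x + rng.normal(0, 0.05, x.shape), 0, 1)
        _, smap = ssim_pair(x, y)
        ref, ref_map = structural_similarity(
            x, y, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
            data_range=1.0, full=True,
        )
        pad = 5
        assert np.allclose(smap[pad:-pad, pad:-pad], ref_map[pad:-pad, pad:-pad],
                           atol=1e-6)
        mine, _ = ssim_pair(x, y)
        assert mine == pytest.approx(ref, abs=1e-6)

    def test_symmetric_in_arguments(self, random_pair):
        recon, truth = random_pair
        assert np.allclose(ssim_per_offset(recon, truth), ssim_per_offset(truth, recon),
                           atol=1e-12)

    def test_ignores_unmasked_pixels(self):
        rng = np.random.default_rng(2)
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True
        base = rng.uniform(0.2, 0.8, (32, 32, 2))
        poisoned = base.copy()
        poisoned[~mask] = 1e6
        a = _stack(base, mask=mask)
        b = _stack(poisoned, mask=mask)
        other = _stack(np.clip(base + rng.normal(0, 0.05, base.shape), 0, 1), mask=mask)
        assert np.allclose(ssim_per_offset(a, other), ssim_per_offset(b, other),
                           atol=1e-12)
        assert np.allclose(psnr_per_offset(a, other), psnr_per_offset(b, other),
                           atol=1e-12)


class TestPSNR:
    def test_analytic_twenty_db(self):
        truth = _stack(np.full((8, 8, 2), 0.5))
        recon = _stack(np.full((8, 8, 2), 0.6))
        assert np.allclose(psnr_per_offset(recon, truth), 20.0, atol=1e-10)

    def test_identical_frames_are_infinite(self, random_pair):
        _, truth = random_pair
        assert np.all(np.isinf(psnr_per_offset(truth, truth)))

    def test_noise_degrades_psnr_and_ssim(self, random_pair):
        recon, truth = random_pair
        rng = np.random.default_rng(9)
        worse = _stack(recon.data + rng.normal(0, 0.05, recon.data.shape))
        assert psnr_per_offset(worse, truth).mean() < psnr_per_offset(recon, truth).mean()
        assert ssim_per_offset(worse, truth).mean() < ssim_per_offset(recon, truth).mean()


class TestSummarize:
    def test_full_report_on_identical_stacks(self, random_pair):
        _, truth = random_pair
        with pytest.warns(UserWarning, match="infinite PSNR"):
            report = evaluate_stacks(truth, truth)
        assert report.mean_ssim == pytest.approx(1.0, abs=1e-12)
        assert report.mean_mae_pct == 0.0
        assert report.r2 == pytest.approx(1.0, abs=1e-12)

    def test_grand_means_match_direct_recomputation(self, random_pair):
        recon, truth = random_pair
        report = evaluate_stacks(recon, truth)
        assert report.mean_mae_pct == pytest.approx(
            np.mean(report.per_offset_mae_pct), abs=1e-12)
        assert report.mean_ssim == pytest.approx(
            np.mean(report.per_offset_ssim), abs=1e-12)
        assert report.mean_psnr_db == pytest.approx(
            np.mean(report.per_offset_psnr_db), abs=1e-12)
        assert report.n_offsets == 4
        assert report.n_pixels == 256

    def test_single_offset_grand_mean(self):
        rng = np.random.default_rng(1)
        truth = _stack(rng.uniform(0.2, 0.8, (8, 8, 1)))
        recon = _stack(np.clip(truth.data + rng.normal(0, 0.02, truth.data.shape), 0, 1))
        report = evaluate_stacks(recon, truth)
        assert report.mean_ssim == report.per_offset_ssim[0]
        assert report.mean_psnr_db == report.per_offset_psnr_db[0]

    def test_table2_layout(self, random_pair):
        recon, truth = random_pair
        r = evaluate_stacks(recon, truth)
        df = table2({"tcn_lstm": r, "rnn": r})
        assert list(df.index) == ["tcn_lstm", "rnn"]
        assert {"SSIM", "PSNR"} <= set(df.columns)

    def test_report_json_roundtrip(self, random_pair):
        import json

        recon, truth = random_pair
        d = json.loads(evaluate_stacks(recon, truth).to_json())
        assert len(d["per_offset_ssim"]) == 4
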