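import numpy as np
import pytest

import cestrecon as cr
from cestrecon.imaging import (
    CESTImageStack, load_stack, lorentzian_reconstruct_stack, normalize_stack,
    reconstruct_stack, save_stack,
)
from cestrecon.phantom import PhantomSpec, REGION_LABELS, make_label_map, make_phantom
from cestrecon.training import predict


@pytest.fixture(scope="module")
def small_phantom(pulse, scanner):
    spec = PhantomSpec(height=24, width=24, noise_sigma=0.0, seed=0)
    return make_phantom(spec, cr.sparse_default(), cr.dense_default(), pulse, scanner)


class TestNormalize:
    def test_raw_equal_s0_gives_ones(self):
        g = cr.OffsetGrid([-1.0, 0.0, 1.0])
        s0 = np.full((4, 4), 3.0)
        raw = np.repeat(s0[:, :, None], 3, axis=2)
        stack = normalize_stack(raw, s0, g)
        assert np.allclose(stack.data, 1.0)

    def test_zero_s0_inside_mask_is_an_error(self):
        g = cr.OffsetGrid([0.0])
        s0 = np.ones((3, 3))
        s0[1, 1] = 0.0
        with pytest.raises(ValueError, match="1 masked pixel"):
            normalize_stack(np.ones((3, 3, 1)), s0, g)

    def test_roundtrip_recovers_raw(self):
        rng = np.random.default_rng(0)
        g = cr.OffsetGrid([-1.0, 1.0])
        s0 = rng.uniform(1, 2, (5, 5))
        raw = rng.uniform(0, 1, (5, 5, 2)) * s0[:, :, None]
        stack = normalize_stack(raw, s0, g)
        assert np.allclose(stack.data * s0[:, :, None], raw, atol=1e-12)


class TestReconstructStack:
    def test_shape_64x64_11_to_101(self, trained_small):
        rng = np.random.default_rng(0)
        data = np.clip(rng.uniform(0.2, 0.9, (8, 8, 11)), 0, 1)
        stack = CESTImageStack(data, cr.sparse_default())
        out = reconstruct_stack(trained_small, stack)
        assert out.shape == (8, 8, 101)
        assert out.grid == cr.dense_default()

    def test_identical_input_spectra_give_identical_outputs(self, trained_small):
        spec = np.linspace(0.3, 0.9, 11)
        data = np.tile(spec, (4, 4, 1))
        out = reconstruct_stack(trained_small, CESTImageStack(data, cr.sparse_default()))
        flat = out.data.reshape(-1, 101)
        assert np.allclose(flat, flat[0][None, :], atol=0)

    def test_batched_matches_per_pixel_loop(self, trained_small):
        rng = np.random.default_rng(1)
        data = rng.uniform(0.2, 0.9, (5, 4, 11))
        stack = CESTImageStack(data, cr.sparse_default())
        out = reconstruct_stack(trained_small, stack)
        for i in range(5):
            for j in range(4):
                single = predict(trained_small, data[i, j])
                assert np.allclose(out.data[i, j], single[0], atol=1e-6)

    def test_unmasked_pixels_never_read_and_are_nan(self, trained_small):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        data = np.full((6, 6, 11), np.nan)  # poison outside the mask
        data[mask] = np.linspace(0.3, 0.9, 11)
        out = reconstruct_stack(trained_small, CESTImageStack(data, cr.sparse_default(), mask=mask))
        assert np.all(np.isfinite(out.data[mask]))
        assert np.all(np.isnan(out.data[~mask]))

    def test_grid_mismatch_rejected(self, trained_small):
        stack = CESTImageStack(np.full((3, 3, 5), 0.5), cr.OffsetGrid([-2, -1, 0, 1, 2]))
        with pytest.raises(ValueError, match="does not match"):
            reconstruct_stack(trained_small, stack)


class TestPhantom:
    def test_labels_partition_the_mask(self):
        labels = make_label_map(64, 64)
        mask = labels > 0
        counts = [(labels == v).sum() for v in REGION_LABELS.values()]
        assert sum(counts) == mask.sum()
        assert all(c > 0 for c in counts)

    def test_noiseless_regions_broadcast_exactly(self, small_phantom, pulse, scanner):
        sp, dn, labels = small_phantom
        presets = cr.load_presets()
        sel = labels == REGION_LABELS["tumor_like"]
        expected = cr.simulate_zspectrum(presets["tumor_like"], pulse, scanner,
                                         cr.dense_default()).z
        region = dn.data[sel]
        assert np.allclose(region, expected[None, :], atol=0)

    def test_phantom_is_seed_reproducible(self, pulse, scanner):
        spec = PhantomSpec(height=16, width=16, noise_sigma=0.02, seed=11)
        a = make_phantom(spec, cr.sparse_default(), cr.dense_default(), pulse, scanner)
        b = make_phantom(spec, cr.sparse_default(), cr.dense_default(), pulse, scanner)
        assert np.array_equal(a[0].data[a[0].mask], b[0].data[b[0].mask])
        assert np.array_equal(a[2], b[2])

    def test_noise_standard_deviation(self, pulse, scanner):
        spec = PhantomSpec(height=48, width=48, noise_sigma=0.01, seed=3)
        _, dn, labels = make_phantom(spec, cr.sparse_default(), cr.dense_default(),
                                     pulse, scanner)
        sel = labels == REGION_LABELS["gm_like"]
        assert sel.sum() > 500
        sd = dn.data[sel].std(axis=0).mean()
        assert sd == pytest.approx(0.01, rel=0.2)

    def test_out_of_bounds_region_rejected(self):
        presets = cr.load_presets()
        bad = dict(presets)
        from cestrecon.pools import PoolRole, PoolSpec, TissueModel

        pools = list(presets["gm_like"].pools)
        pools[0] = PoolSpec(PoolRole.WATER, fs=1.0, t1=5.0, t2=0.05)  # T1 above UB
        bad["gm_like"] = TissueModel(tuple(pools))
        spec = PhantomSpec(height=8, width=8, regions=bad)
        with pytest.raises(ValueError, match="outside sampling bounds"):
            make_phantom(spec, cr.sparse_default(), cr.dense_default())


class TestLorentzianStack:
    def test_baseline_reconstruction_shape(self, small_phantom):
        sp, dn, _ = small_phantom
        out = lorentzian_reconstruct_stack(sp, cr.dense_default())
        assert out.shape == sp.shape[:2] + (101,)
        assert np.all(np.isfinite(out.data[sp.mask]))


class TestRoundtrip:
    def test_nifti_save_load(self, tmp_path, small_phantom):
        sp, _, _ = small_phantom
        path = tmp_path / "stack.nii"
        save_stack(sp, path)
        again = load_stack(path)
        assert again.grid == sp.grid
        assert np.array_equal(again.mask, sp.mask)
        assert np.allclose(again.data[again.mask], sp.data[sp.mask], atol=1e-12)


def test_end_to_end_phantom_reconstruction_error(trained_small, small_phantom):
    """A briefly trained model reconstructs a noiseless phantom's dense
    stack with mean absolute error under 3% inside the mask."""
    sp, dn, _ = small_phantom
    out = reconstruct_stack(trained_small, sp)
    mae_pct = float(np.mean(np.abs(out.data[sp.mask] - dn.data[dn.mask]))) * 100
    assert mae_pct < 3.0
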