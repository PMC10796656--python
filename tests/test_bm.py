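import numpy as np
import pytest
from scipy import stats

import cestrecon as cr
from cestrecon.bm import assemble_generator, sample_params, sample_tissue
from cestrecon.pools import PoolRole, PoolSpec, TissueModel

from conftest import degenerate_bounds


def _no_exchange_tissue(mid_tissue):
    pools = [mid_tissue.water]
    for p in mid_tissue.solutes:
        pools.append(PoolSpec(p.role, fs=p.fs, ksw=0.0, t1=p.t1, t2=p.t2))
    return TissueModel(tuple(pools))


class TestGenerator:
    def test_zero_exchange_gives_block_diagonal_A(self, mid_tissue, pulse, scanner):
        tissue = _no_exchange_tissue(mid_tissue)
        A, _ = assemble_generator(tissue, pulse, scanner, 3.5)
        assert A.shape == (21, 21)
        off_block = A.copy()
        for i in range(7):
            off_block[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = 0.0
        assert np.all(off_block == 0.0)

    def test_recovery_vector_structure(self, mid_tissue, pulse, scanner):
        _, b = assemble_generator(mid_tissue, pulse, scanner, 0.0)
        expected = np.zeros(21)
        for i, p in enumerate(mid_tissue.pools):
            expected[3 * i + 2] = p.fs / p.t1
        assert np.allclose(b, expected, rtol=0, atol=0)
        assert np.all(b[np.arange(21) % 3 != 2] == 0.0)

    def test_generator_is_stable_across_sampling_box(self, bounds, pulse, scanner):
        """All eigenvalues of A have non-positive real part for 1,000
        random tissues at 3.5 ppm (relaxation dominates exchange)."""
        rng = np.random.default_rng(42)
        As = np.stack(
            [
                assemble_generator(sample_tissue(bounds, rng), pulse, scanner, 3.5)[0]
                for _ in range(1000)
            ]
        )
        eig = np.linalg.eigvals(As)
        assert eig.real.max() <= 1e-9

    def test_non_finite_parameters_rejected(self, mid_tissue, pulse, scanner):
        with pytest.raises(ValueError):
            assemble_generator(mid_tissue, pulse, scanner, np.nan)


class TestZValue:
    def test_water_only_spectrum_is_symmetric(self, pulse, scanner):
        w = TissueModel.water_only(2.0, 0.06)
        for d in (0.5, 1.2, 3.0, 6.0):
            zp = cr.simulate_zvalue(w, pulse, scanner, +d)
            zm = cr.simulate_zvalue(w, pulse, scanner, -d)
            assert abs(zp - zm) < 1e-9

    def test_water_only_minimum_at_resonance(self, pulse, scanner):
        w = TissueModel.water_only(2.0, 0.06)
        zs = cr.simulate_zspectrum(w, pulse, scanner, cr.dense_default())
        assert np.argmin(zs.z) == 50  # 0 ppm
        assert zs.grid.offsets_ppm[50] == 0.0

    def test_expm_matches_ode_at_midpoint(self, mid_tissue, pulse, scanner):
        z1 = cr.simulate_zvalue(mid_tissue, pulse, scanner, 3.5, method="expm")
        z2 = cr.simulate_zvalue(mid_tissue, pulse, scanner, 3.5, method="ode")
        assert abs(z1 - z2) < 1e-6

    def test_expm_matches_ode_on_random_tissues(self, bounds, pulse, scanner):
        rng = np.random.default_rng(7)
        sparse = cr.sparse_default()
        for _ in range(25):
            tissue = sample_tissue(bounds, rng)
            off = rng.choice(sparse.offsets_ppm)
            z1 = cr.simulate_zvalue(tissue, pulse, scanner, off, method="expm")
            z2 = cr.simulate_zvalue(tissue, pulse, scanner, off, method="ode")
            assert abs(z1 - z2) < 1e-6

    def test_unknown_method_rejected(self, mid_tissue, pulse, scanner):
        with pytest.raises(ValueError):
            cr.simulate_zvalue(mid_tissue, pulse, scanner, 0.0, method="euler")


class TestZSpectrum:
    def test_default_grid_lengths(self, mid_tissue, pulse, scanner):
        assert len(cr.simulate_zspectrum(mid_tissue, pulse, scanner, cr.sparse_default())) == 11
        assert len(cr.simulate_zspectrum(mid_tissue, pulse, scanner, cr.dense_default())) == 101

    def test_empty_grid_is_an_error(self):
        with pytest.raises(ValueError):
            cr.OffsetGrid([])

    def test_single_offset_equals_zvalue(self, mid_tissue, pulse, scanner):
        zs = cr.simulate_zspectrum(mid_tissue, pulse, scanner, cr.OffsetGrid([0.0]))
        zv = cr.simulate_zvalue(mid_tissue, pulse, scanner, 0.0)
        assert zs.z[0] == pytest.approx(zv, abs=1e-12)

    def test_spectra_respect_physical_bounds(self, bounds, pulse, scanner):
        rng = np.random.default_rng(11)
        for _ in range(10):
            zs = cr.simulate_zspectrum(sample_tissue(bounds, rng), pulse, scanner,
                                       cr.sparse_default())
            assert np.all(zs.z >= -1e-6) and np.all(zs.z <= 1.0 + 1e-6)

    def test_amide_fraction_monotonically_deepens_3p5ppm_dip(self, bounds, pulse, scanner):
        lo, hi = bounds.as_arrays()
        mid = 0.5 * (lo + hi)
        fs_lo = bounds.solutes[PoolRole.AMIDE]["fs"].lo
        fs_hi = bounds.solutes[PoolRole.AMIDE]["fs"].hi
        zvals = []
        for fs in np.linspace(fs_lo, fs_hi, 10):
            v = mid.copy()
            v[2] = fs  # amide fs position in the canonical vector
            tissue = bounds.tissue_from_vector(v)
            zvals.append(cr.simulate_zvalue(tissue, pulse, scanner, 3.5))
        assert np.all(np.diff(zvals) <= 1e-12)


class TestSampling:
    def test_sampled_tissue_has_fixed_deltas_and_bounded_mt(self, bounds):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = sample_tissue(bounds, rng)
            amide = next(p for p in t.solutes if p.role is PoolRole.AMIDE)
            mt = next(p for p in t.solutes if p.role is PoolRole.MT)
            assert amide.delta_ppm == 3.5
            assert 10e-3 <= mt.fs <= 200e-3

    def test_degenerate_bounds_sample_identically(self):
        db = degenerate_bounds()
        rng = np.random.default_rng(0)
        v1, v2 = sample_params(db, rng), sample_params(db, rng)
        assert np.array_equal(v1, v2)

    def test_water_t1_sampling_is_uniform(self, bounds):
        """KS test of 10,000 water-T1 draws against Uniform(1, 3)."""
        rng = np.random.default_rng(2024)
        t1 = np.array([sample_params(bounds, rng)[0] for _ in range(10_000)])
        res = stats.kstest(t1, stats.uniform(loc=1.0, scale=2.0).cdf)
        assert res.pvalue > 0.01


class TestDatasetGeneration:
    def test_same_seed_bit_identical(self):
        d1 = cr.generate_dataset(20, seed=5)
        d2 = cr.generate_dataset(20, seed=5)
        assert d1.equals(d2)

    def test_different_seed_differs(self):
        d1 = cr.generate_dataset(5, seed=5)
        d2 = cr.generate_dataset(5, seed=6)
        assert not np.array_equal(d1.params, d2.params)

    def test_degenerate_bounds_give_identical_rows(self):
        ds = cr.generate_dataset(3, bounds=degenerate_bounds(), seed=0)
        assert np.array_equal(ds.dense_z[0], ds.dense_z[1])
        assert np.array_equal(ds.dense_z[1], ds.dense_z[2])

    def test_rows_lie_within_bounds(self, bounds):
        ds = cr.generate_dataset(10, seed=9)
        assert bounds.contains(ds.params)

    def test_sparse_fast_path_matches_direct_simulation(self, pulse, scanner, bounds):
        ds = cr.generate_dataset(2, seed=31)
        tissue = bounds.tissue_from_vector(ds.params[0])
        direct = cr.simulate_zspectrum(tissue, pulse, scanner, cr.sparse_default())
        assert np.allclose(ds.sparse_z[0], direct.z, rtol=0, atol=1e-12)

    def test_save_load_roundtrip(self, tmp_path):
        ds = cr.generate_dataset(4, seed=2)
        path = tmp_path / "ds.npz"
        ds.save(path)
        again = cr.SimulatedDataset.load(path)
        assert ds.equals(again)
        assert again.seed == 2
        assert again.metadata["pulse"]["b1_uT"] == 1.2

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            cr.generate_dataset(0)
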