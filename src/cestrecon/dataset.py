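"""Paired sparse/dense training datasets of simulated Z-spectra.

``generate_dataset`` samples tissues uniformly within the parameter
bounds, simulates each on the sparse and dense grids, and returns the
aligned matrices together with the sampled parameter vectors and the
seed, so that regeneration is bit-for-bit reproducible.  When every
sparse offset lies on the dense grid (true for the default protocol) each
tissue is simulated once on the dense grid and the sparse columns are
extracted from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bm import _z_many, sample_params
from .grids import OffsetGrid
from .pools import ParameterBounds, default_bounds
from .protocol import SaturationPulse, ScannerConfig
from . import grids as _grids

__all__ = ["SimulatedDataset", "generate_dataset"]


@dataclass(frozen=True)
class SimulatedDataset:
    """n paired (sparse, dense) Z-spectra with their parameter vectors."""

    sparse_z: np.ndarray  # (n, len(sparse_grid))
    dense_z: np.ndarray  # (n, len(dense_grid))
    params: np.ndarray  # (n, 20)
    seed: int
    sparse_grid: OffsetGrid
    dense_grid: OffsetGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.sparse_z.shape[0]
        if not (self.dense_z.shape[0] == n and self.params.shape[0] == n):
            raise ValueError("row counts of sparse_z, dense_z and params must agree")
        if self.sparse_z.shape[1] != len(self.sparse_grid):
            raise ValueError("sparse_z width does not match sparse grid")
        if self.dense_z.shape[1] != len(self.dense_grid):
            raise ValueError("dense_z width does not match dense grid")

    @property
    def n(self) -> int:
        return int(self.sparse_z.shape[0])

    def save(self, path) -> None:
        """Write a single-file array container (.npz) with JSON metadata."""
        meta = dict(self.metadata)
        meta["seed"] = int(self.seed)
        np.savez(
            path,
            sparse_z=self.sparse_z,
            dense_z=self.dense_z,
            params=self.params,
            sparse_offsets_ppm=self.sparse_grid.offsets_ppm,
            dense_offsets_ppm=self.dense_grid.offsets_ppm,
            metadata_json=np.array(json.dumps(meta)),
        )

    @staticmethod
    def load(path) -> "SimulatedDataset":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["metadata_json"]))
            return SimulatedDataset(
                sparse_z=f["sparse_z"],
                dense_z=f["dense_z"],
                params=f["params"],
                seed=int(meta.pop("seed")),
                sparse_grid=OffsetGrid(f["sparse_offsets_ppm"]),
                dense_grid=OffsetGrid(f["dense_offsets_ppm"]),
                metadata=meta,
            )

    def equals(self, other: "SimulatedDataset") -> bool:
        return (
            np.array_equal(self.sparse_z, other.sparse_z)
            and np.array_equal(self.dense_z, other.dense_z)
            and np.array_equal(self.params, other.params)
            and self.sparse_grid == other.sparse_grid
            and self.dense_grid == other.dense_grid
        )


def generate_dataset(
    n: int,
    sparse: OffsetGrid | None = None,
    dense: OffsetGrid | None = None,
    pulse: SaturationPulse | None = None,
    scanner: ScannerConfig | None = None,
    bounds: ParameterBounds | None = None,
    seed: int = 0,
    noise_sigma: float = 0.0,
    progress: bool = False,
) -> SimulatedDataset:
    """Simulate ``n`` paired sparse/dense Z-spectra.

    Tissues are drawn uniformly within ``bounds`` from a generator seeded
    with ``seed``; the result is a pure function of the configuration and
    the seed.  ``noise_sigma`` adds i.i.d. Gaussian noise on Z to both
    matrices (independent draws; default off, matching noiseless
    training data).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sparse = sparse or _grids.sparse_default()
    dense = dense or _grids.dense_default()
    pulse = pulse or SaturationPulse()
    scanner = scanner or ScannerConfig()
    bounds = bounds or default_bounds()

    rng = np.random.default_rng(seed)
    params = np.stack([sample_params(bounds, rng) for _ in range(n)])

    subset = sparse.is_subset_of(dense)
    if subset:
        sparse_idx = sparse.indices_in(dense)

    sparse_z = np.empty((n, len(sparse)))
    dense_z = np.empty((n, len(dense)))
    it = range(n)
    if progress:
        from tqdm import tqdm

        it = tqdm(it, desc="simulating", unit="spectrum")
    for i in it:
        tissue = bounds.tissue_from_vector(params[i])
        dz = _z_many(tissue, dense.offsets_ppm, pulse, scanner)
        dense_z[i] = dz
        if subset:
            sparse_z[i] = dz[sparse_idx]
        else:
            sparse_z[i] = _z_many(tissue, sparse.offsets_ppm, pulse, scanner)

    if noise_sigma > 0:
        sparse_z = sparse_z + rng.normal(0.0, noise_sigma, sparse_z.shape)
        dense_z = dense_z + rng.normal(0.0, noise_sigma, dense_z.shape)

    meta = {
        "bounds": bounds.to_dict(),
        "pulse": {"b1_uT": pulse.b1_uT, "duration_s": pulse.duration_s, "shape": pulse.shape},
        "scanner": {"b0_T": scanner.b0_T, "gamma_rad_per_s_per_T": scanner.gamma_rad_per_s_per_T},
        "noise_sigma": noise_sigma,
    }
    return SimulatedDataset(sparse_z, dense_z, params, int(seed), sparse, dense, meta)
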