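"""Frequency-offset grids for Z-spectrum acquisition and simulation.

A Z-spectrum is sampled at a set of saturation frequency offsets, expressed
in ppm relative to the water resonance.  Two grids matter throughout this
package: the 11-point non-uniform *sparse* grid that a short scan acquires,
and the 101-point uniform *dense* grid (-6 to 6 ppm) that reconstruction
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OffsetGrid", "SPARSE_OFFSETS_PPM", "sparse_default", "dense_default"]

#: The 11 acquisition offsets (ppm) of the sparse protocol.  Every value
#: lies on the default dense grid (multiples of 0.12 ppm from -6).
SPARSE_OFFSETS_PPM = (
    -6.00, -3.60, -2.64, -1.68, -1.20, 0.96, 1.92, 2.76, 3.36, 3.96, 6.00,
)


@dataclass(frozen=True)
class OffsetGrid:
    """An ordered set of saturation frequency offsets in ppm.

    Offsets are canonically sorted ascending on construction and must be
    finite and pairwise distinct.
    """

    offsets_ppm: np.ndarray = field()

    def __init__(self, offsets_ppm) -> None:
        arr = np.asarray(offsets_ppm, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("offset grid must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("offset grid contains non-finite values")
        arr = np.sort(arr)
        if np.any(np.diff(arr) <= 0):
            raise ValueError("offset grid values must be distinct")
        arr.flags.writeable = False
        object.__setattr__(self, "offsets_ppm", arr)

    def __len__(self) -> int:
        return int(self.offsets_ppm.size)

    def __iter__(self):
        return iter(self.offsets_ppm)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OffsetGrid):
            return NotImplemented
        return self.offsets_ppm.shape == other.offsets_ppm.shape and bool(
            np.array_equal(self.offsets_ppm, other.offsets_ppm)
        )

    def __hash__(self) -> int:
        return hash(self.offsets_ppm.tobytes())

    def is_subset_of(self, other: "OffsetGrid", tol: float = 1e-9) -> bool:
        """True if every offset here matches an offset of ``other`` within ``tol``."""
        d = np.abs(self.offsets_ppm[:, None] - other.offsets_ppm[None, :])
        return bool(np.all(d.min(axis=1) <= tol))

    def indices_in(self, other: "OffsetGrid", tol: float = 1e-9) -> np.ndarray:
        """Index of each of this grid's offsets inside ``other`` (raises if absent)."""
        d = np.abs(self.offsets_ppm[:, None] - other.offsets_ppm[None, :])
        idx = d.argmin(axis=1)
        if np.any(d[np.arange(len(self)), idx] > tol):
            raise ValueError("grid is not a subset of the target grid")
        return idx


def sparse_default() -> OffsetGrid:
    """The 11-offset sparse acquisition grid."""
    return OffsetGrid(SPARSE_OFFSETS_PPM)


def dense_default() -> OffsetGrid:
    """The 101-offset dense grid, evenly spaced on [-6, 6] ppm inclusive."""
    return OffsetGrid(np.linspace(-6.0, 6.0, 101))
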