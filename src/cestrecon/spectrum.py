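"""The Z-spectrum container: normalized water signal per frequency offset."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import OffsetGrid

__all__ = ["ZSpectrum", "PHYSICAL_SLACK"]

#: Numeric slack on the physical bound |Z| <= 1.
PHYSICAL_SLACK = 1e-9


@dataclass(frozen=True)
class ZSpectrum:
    """Normalized water longitudinal magnetization Mz(t_sat)/M0 per offset.

    ``check_bounds=False`` skips the physical-bound check; model-derived
    spectra (e.g. Lorentzian evaluations with a free baseline) may
    legitimately exceed 1 slightly.
    """

    grid: OffsetGrid
    z: np.ndarray

    def __init__(self, grid: OffsetGrid, z, check_bounds: bool = True) -> None:
        z = np.asarray(z, dtype=float)
        if z.ndim != 1 or z.size != len(grid):
            raise ValueError(f"z length {z.size} does not match grid length {len(grid)}")
        if not np.all(np.isfinite(z)):
            raise ValueError("Z values must be finite")
        if check_bounds and np.any(np.abs(z) > 1.0 + PHYSICAL_SLACK):
            raise ValueError("Z values exceed the physical bound |Z| <= 1")
        z = z.copy()
        z.flags.writeable = False
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return len(self.grid)
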