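"""The 7-pool tissue parameterization driving Bloch-McConnell simulation.

Each proton pool carries a size fraction ``fs`` relative to water, a
solute->water exchange rate ``ksw`` (s^-1), relaxation times T1/T2 (s),
and a fixed chemical-shift offset from water (ppm).  The canonical model
has seven pools: free water plus amide (3.5 ppm), guanidyl/amine (2 ppm),
hydroxyl (1.3 ppm), an NOE pool at -1.6 ppm, a semi-solid MT pool at
-2.4 ppm and a second NOE pool at -3.5 ppm.

``ParameterBounds`` holds the uniform sampling box for the 20 free
parameters used to generate training data: (fs, ksw, T2) for each of the
six solute pools, plus water T1 and T2.  Water fs is fixed at 1 and every
solute T1 is fixed at 1 s.  Bounds are stored in SI units (absolute
fractions and seconds); the conventional literature units (1e-3 for fs,
ms for T2) are converted at construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "PoolRole",
    "PoolSpec",
    "TissueModel",
    "ParameterBounds",
    "DELTA_PPM",
    "SOLUTE_ROLES",
    "FREE_PARAM_NAMES",
    "default_bounds",
    "midpoint_tissue",
]


class PoolRole(str, Enum):
    WATER = "water"
    AMIDE = "amide"
    GUANIDYL_AMINE = "guanidyl_amine"
    HYDROXYL = "hydroxyl"
    NOE_M1P6 = "noe_m1p6"
    MT = "mt"
    NOE_M3P5 = "noe_m3p5"


#: Fixed resonance offset of each pool relative to water, ppm.
DELTA_PPM: Mapping[PoolRole, float] = {
    PoolRole.WATER: 0.0,
    PoolRole.AMIDE: 3.5,
    PoolRole.GUANIDYL_AMINE: 2.0,
    PoolRole.HYDROXYL: 1.3,
    PoolRole.NOE_M1P6: -1.6,
    PoolRole.MT: -2.4,
    PoolRole.NOE_M3P5: -3.5,
}

#: Canonical solute ordering (water always precedes these in a TissueModel).
SOLUTE_ROLES = (
    PoolRole.AMIDE,
    PoolRole.GUANIDYL_AMINE,
    PoolRole.HYDROXYL,
    PoolRole.NOE_M1P6,
    PoolRole.MT,
    PoolRole.NOE_M3P5,
)

#: Names of the 20 free parameters, in the canonical vector order used by
#: dataset generation: water (t1, t2) then (fs, ksw, t2) per solute.
FREE_PARAM_NAMES = tuple(
    ["water.t1", "water.t2"]
    + [f"{role.value}.{p}" for role in SOLUTE_ROLES for p in ("fs", "ksw", "t2")]
)


@dataclass(frozen=True)
class PoolSpec:
    """One proton pool.  ``ksw`` is None for water (no self-exchange)."""

    role: PoolRole
    fs: float
    t1: float
    t2: float
    ksw: float | None = None
    delta_ppm: float | None = None

    def __post_init__(self) -> None:
        if self.delta_ppm is None:
            object.__setattr__(self, "delta_ppm", DELTA_PPM[self.role])
        vals = (self.fs, self.t1, self.t2)
        if not all(np.isfinite(vals)) or not all(v > 0 for v in vals):
            raise ValueError(f"{self.role.value}: fs, t1, t2 must be finite and positive")
        if self.role is PoolRole.WATER:
            if self.ksw is not None:
                raise ValueError("water pool has no exchange rate")
        else:
            if self.ksw is None or not np.isfinite(self.ksw) or self.ksw < 0:
                raise ValueError(f"{self.role.value}: ksw must be finite and >= 0")


@dataclass(frozen=True)
class TissueModel:
    """An ordered collection of pools, water first.

    The back-exchange (water->solute) rates follow from mass balance:
    ``kws_i = ksw_i * fs_i / fs_water``.
    """

    pools: tuple[PoolSpec, ...]

    def __post_init__(self) -> None:
        if not self.pools or self.pools[0].role is not PoolRole.WATER:
            raise ValueError("first pool must be water")
        roles = [p.role for p in self.pools]
        if len(set(roles)) != len(roles):
            raise ValueError("duplicate pool roles")
        if sum(r is PoolRole.WATER for r in roles) != 1:
            raise ValueError("exactly one water pool required")

    @property
    def water(self) -> PoolSpec:
        return self.pools[0]

    @property
    def solutes(self) -> tuple[PoolSpec, ...]:
        return self.pools[1:]

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def kws(self, pool: PoolSpec) -> float:
        """Water->solute exchange rate of ``pool`` (s^-1), by mass balance."""
        if pool.role is PoolRole.WATER:
            raise ValueError("kws is defined for solute pools only")
        return pool.ksw * pool.fs / self.water.fs

    @staticmethod
    def water_only(t1: float, t2: float, fs: float = 1.0) -> "TissueModel":
        """Single-pool reduction: free water alone (no exchange partners)."""
        return TissueModel((PoolSpec(PoolRole.WATER, fs=fs, t1=t1, t2=t2),))

    @staticmethod
    def from_parameters(params: Mapping[PoolRole, Mapping[str, float]]) -> "TissueModel":
        """Build a full 7-pool model from per-role parameter dicts.

        Water needs ``t1``/``t2`` (``fs`` optional, default 1); solutes need
        ``fs``/``ksw``/``t2`` (``t1`` optional, default 1 s).
        """
        w = params[PoolRole.WATER]
        pools = [PoolSpec(PoolRole.WATER, fs=w.get("fs", 1.0), t1=w["t1"], t2=w["t2"])]
        for role in SOLUTE_ROLES:
            p = params[role]
            pools.append(
                PoolSpec(role, fs=p["fs"], ksw=p["ksw"], t1=p.get("t1", 1.0), t2=p["t2"])
            )
        return TissueModel(tuple(pools))


@dataclass(frozen=True)
class Bounds1D:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo <= self.hi):
            raise ValueError(f"invalid bounds [{self.lo}, {self.hi}]")

    @property
    def mid(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class ParameterBounds:
    """Uniform sampling box for the 20 free tissue parameters (SI units).

    ``water`` maps ``t1``/``t2`` to bounds; ``solutes`` maps each solute
    role to ``fs``/``ksw``/``t2`` bounds.  Solute T1 is fixed at
    ``solute_t1_s`` and water fs at ``water_fs``.
    """

    water: Mapping[str, Bounds1D]
    solutes: Mapping[PoolRole, Mapping[str, Bounds1D]]
    solute_t1_s: float = 1.0
    water_fs: float = 1.0

    def __post_init__(self) -> None:
        if set(self.water) != {"t1", "t2"}:
            raise ValueError("water bounds must provide exactly t1 and t2")
        if set(self.solutes) != set(SOLUTE_ROLES):
            raise ValueError("bounds must cover all six solute roles")
        for role, b in self.solutes.items():
            if set(b) != {"fs", "ksw", "t2"}:
                raise ValueError(f"{role.value}: bounds must provide fs, ksw, t2")

    @property
    def n_free(self) -> int:
        return len(FREE_PARAM_NAMES)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) bound vectors in canonical parameter order."""
        lo, hi = [], []
        for b in (self.water["t1"], self.water["t2"]):
            lo.append(b.lo), hi.append(b.hi)
        for role in SOLUTE_ROLES:
            for p in ("fs", "ksw", "t2"):
                b = self.solutes[role][p]
                lo.append(b.lo), hi.append(b.hi)
        return np.array(lo), np.array(hi)

    def contains(self, params: np.ndarray, rtol: float = 1e-12) -> bool:
        lo, hi = self.as_arrays()
        p = np.atleast_2d(np.asarray(params, dtype=float))
        slack = rtol * np.maximum(np.abs(lo), np.abs(hi))
        return bool(np.all(p >= lo - slack) and np.all(p <= hi + slack))

    def tissue_from_vector(self, params: np.ndarray) -> TissueModel:
        """Materialize a TissueModel from a canonical 20-vector."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} parameters, got {params.shape}")
        pools = [
            PoolSpec(PoolRole.WATER, fs=self.water_fs, t1=params[0], t2=params[1])
        ]
        for j, role in enumerate(SOLUTE_ROLES):
            fs, ksw, t2 = params[2 + 3 * j : 5 + 3 * j]
            pools.append(PoolSpec(role, fs=fs, ksw=ksw, t1=self.solute_t1_s, t2=t2))
        return TissueModel(tuple(pools))

    def to_dict(self) -> dict:
        return {
            "water": {k: [b.lo, b.hi] for k, b in self.water.items()},
            "solutes": {
                role.value: {k: [b.lo, b.hi] for k, b in bb.items()}
                for role, bb in self.solutes.items()
            },
            "solute_t1_s": self.solute_t1_s,
            "water_fs": self.water_fs,
        }

    @staticmethod
    def from_dict(d: Mapping) -> "ParameterBounds":
        return ParameterBounds(
            water={k: Bounds1D(*v) for k, v in d["water"].items()},
            solutes={
                PoolRole(r): {k: Bounds1D(*v) for k, v in bb.items()}
                for r, bb in d["solutes"].items()
            },
            solute_t1_s=d.get("solute_t1_s", 1.0),
            water_fs=d.get("water_fs", 1.0),
        )


def _ms(lo: float, hi: float) -> Bounds1D:
    return Bounds1D(lo * 1e-3, hi * 1e-3)


def default_bounds() -> ParameterBounds:
    """The standard in vivo sampling box (fs and T2 converted to SI).

    fs bounds are quoted in units of 1e-3 and T2 bounds in ms in the
    literature; stored here as absolute fractions and seconds.
    """
    return ParameterBounds(
        water={"t1": Bounds1D(1.0, 3.0), "t2": _ms(20, 100)},
        solutes={
            PoolRole.AMIDE: {"fs": _ms(0.1, 3), "ksw": Bounds1D(1, 100), "t2": _ms(0.5, 100)},
            PoolRole.GUANIDYL_AMINE: {"fs": _ms(0.1, 2), "ksw": Bounds1D(100, 1000), "t2": _ms(0.1, 5)},
            PoolRole.HYDROXYL: {"fs": _ms(0.1, 10), "ksw": Bounds1D(100, 2000), "t2": _ms(0.1, 5)},
            PoolRole.NOE_M1P6: {"fs": _ms(1, 5), "ksw": Bounds1D(1, 50), "t2": _ms(0.1, 1)},
            PoolRole.MT: {"fs": _ms(10, 200), "ksw": Bounds1D(1, 50), "t2": _ms(0.01, 0.1)},
            PoolRole.NOE_M3P5: {"fs": _ms(10, 50), "ksw": Bounds1D(1, 40), "t2": _ms(1, 10)},
        },
    )


def midpoint_tissue(bounds: ParameterBounds | None = None) -> TissueModel:
    """Tissue with every free parameter at the midpoint of its bounds."""
    b = bounds or default_bounds()
    lo, hi = b.as_arrays()
    return b.tissue_from_vector(0.5 * (lo + hi))
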