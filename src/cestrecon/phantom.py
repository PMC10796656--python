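"""Digital brain phantoms: reproducible stand-ins for in vivo CEST stacks.

A phantom is an elliptical "brain" mask partitioned into three labeled
regions — gray-matter-like cortex, a white-matter-like inner ellipse and
a tumor-like disc — each carrying its own 7-pool tissue model.  Region
parameters ship as a YAML preset file and must lie inside the uniform
sampling bounds, so phantom spectra stay inside the training domain.
Each region's sparse and dense Z-spectra are simulated once and
broadcast to the region's pixels; optional i.i.d. Gaussian noise on Z
is added per pixel and offset.  Generation is a pure function of the
spec, grids and protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .bm import simulate_zspectrum
from .grids import OffsetGrid
from .imaging import CESTImageStack
from .pools import ParameterBounds, PoolRole, TissueModel, default_bounds
from .protocol import SaturationPulse, ScannerConfig

__all__ = ["PhantomSpec", "make_phantom", "load_presets", "REGION_LABELS"]

#: Label values in the phantom label map (0 = outside the mask).
REGION_LABELS = {"gm_like": 1, "wm_like": 2, "tumor_like": 3}


def load_presets() -> dict[str, TissueModel]:
    """Load the shipped per-region tissue presets."""
    text = resources.files("cestrecon.data").joinpath("phantom_presets.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, pools in raw.items():
        out[name] = TissueModel.from_parameters(
            {PoolRole(role): params for role, params in pools.items()}
        )
    return out


def _check_in_bounds(name: str, tissue: TissueModel, bounds: ParameterBounds) -> None:
    def ok(b, v):
        return b.lo - 1e-12 <= v <= b.hi + 1e-12

    w = tissue.water
    if not (ok(bounds.water["t1"], w.t1) and ok(bounds.water["t2"], w.t2)):
        raise ValueError(f"region {name!r}: water parameters outside sampling bounds")
    for p in tissue.solutes:
        bb = bounds.solutes[p.role]
        if not (ok(bb["fs"], p.fs) and ok(bb["ksw"], p.ksw) and ok(bb["t2"], p.t2)):
            raise ValueError(
                f"region {name!r}: {p.role.value} parameters outside sampling bounds"
            )


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 64
    width: int = 64
    regions: dict[str, TissueModel] | None = None  # defaults to shipped presets
    noise_sigma: float = 0.0
    seed: int = 0
    bounds: ParameterBounds = field(default_factory=default_bounds)

    def region_models(self) -> dict[str, TissueModel]:
        models = self.regions if self.regions is not None else load_presets()
        if set(models) != set(REGION_LABELS):
            raise ValueError(f"regions must be exactly {sorted(REGION_LABELS)}")
        for name, tissue in models.items():
            _check_in_bounds(name, tissue, self.bounds)
        return models


def make_label_map(height: int, width: int) -> np.ndarray:
    """Elliptical brain mask with gm/wm/tumor labels (0 outside)."""
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    u = (yy - cy) / (0.42 * height)
    v = (xx - cx) / (0.36 * width)
    brain = u**2 + v**2 <= 1.0
    uw = (yy - cy) / (0.26 * height)
    vw = (xx - cx) / (0.20 * width)
    wm = uw**2 + vw**2 <= 1.0
    ty, tx = cy - 0.18 * height, cx + 0.16 * width
    tumor = (yy - ty) ** 2 + (xx - tx) ** 2 <= (0.11 * min(height, width)) ** 2
    labels = np.zeros((height, width), dtype=np.int8)
    labels[brain] = REGION_LABELS["gm_like"]
    labels[brain & wm] = REGION_LABELS["wm_like"]
    labels[brain & tumor] = REGION_LABELS["tumor_like"]
    return labels


def make_phantom(
    spec: PhantomSpec,
    sparse: OffsetGrid,
    dense: OffsetGrid,
    pulse: SaturationPulse | None = None,
    scanner: ScannerConfig | None = None,
) -> tuple[CESTImageStack, CESTImageStack, np.ndarray]:
    """Build paired sparse/dense phantom stacks plus the region label map."""
    pulse = pulse or SaturationPulse()
    scanner = scanner or ScannerConfig()
    models = spec.region_models()
    labels = make_label_map(spec.height, spec.width)
    mask = labels > 0

    sparse_data = np.full((spec.height, spec.width, len(sparse)), np.nan)
    dense_data = np.full((spec.height, spec.width, len(dense)), np.nan)
    for name, label in REGION_LABELS.items():
        sel = labels == label
        if not sel.any():
            continue
        zs = simulate_zspectrum(models[name], pulse, scanner, sparse).z
        zd = simulate_zspectrum(models[name], pulse, scanner, dense).z
        sparse_data[sel] = zs
        dense_data[sel] = zd

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        sparse_data[mask] += rng.normal(0.0, spec.noise_sigma, sparse_data[mask].shape)
        dense_data[mask] += rng.normal(0.0, spec.noise_sigma, dense_data[mask].shape)

    meta = {"noise_sigma": spec.noise_sigma, "seed": spec.seed}
    return (
        CESTImageStack(sparse_data, sparse, mask=mask, metadata=dict(meta)),
        CESTImageStack(dense_data, dense, mask=mask, metadata=dict(meta)),
        labels,
    )
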