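"""CEST image stacks: containers, normalization, pixel-wise reconstruction,
and NIfTI round-tripping.

A stack is an H x W x K cube of Z-values, one frame per saturation
offset, with an inclusion mask and an optional unsaturated reference
image S0.  On disk a stack is a 3-D NIfTI volume (offsets along the
third axis) with a JSON sidecar carrying the offset grid and metadata;
the mask travels as a companion integer NIfTI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import OffsetGrid
from .training import TrainedModel, predict

__all__ = [
    "CESTImageStack",
    "normalize_stack",
    "reconstruct_stack",
    "lorentzian_reconstruct_stack",
    "save_stack",
    "load_stack",
]


@dataclass
class CESTImageStack:
    """H x W x K cube of normalized Z-values with offset grid and ROI mask."""

    data: np.ndarray
    grid: OffsetGrid
    mask: np.ndarray | None = None
    s0: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be H x W x K")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"stack has {self.data.shape[2]} frames but grid has {len(self.grid)} offsets"
            )
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape must be H x W")
        if self.s0 is not None:
            self.s0 = np.asarray(self.s0, dtype=float)
            if self.s0.shape != self.data.shape[:2]:
                raise ValueError("s0 shape must be H x W")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("masked Z-values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def masked_values(self) -> np.ndarray:
        """(n_masked, K) matrix of the spectra inside the mask."""
        return self.data[self.mask]


def normalize_stack(raw: np.ndarray, s0: np.ndarray, grid: OffsetGrid,
                    mask: np.ndarray | None = None,
                    clip: tuple[float, float] | None = None) -> CESTImageStack:
    """Z = raw / S0 per pixel; optionally clip Z and record it in metadata.

    Raises when S0 is non-positive anywhere inside the mask (the count of
    offending pixels is reported).
    """
    raw = np.asarray(raw, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if raw.ndim != 3 or s0.shape != raw.shape[:2]:
        raise ValueError("raw must be H x W x K and s0 must be H x W")
    m = np.ones(raw.shape[:2], dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    bad = int(np.count_nonzero(s0[m] <= 0))
    if bad:
        raise ValueError(f"s0 is non-positive at {bad} masked pixel(s)")
    with np.errstate(divide="ignore", invalid="ignore"):
        data = raw / s0[:, :, None]
    data[~m] = np.nan
    meta = {}
    if clip is not None:
        data = np.clip(data, clip[0], clip[1])
        meta["clip"] = list(clip)
    data = np.where(m[:, :, None], data, np.nan)
    return CESTImageStack(data=data, grid=grid, mask=m, s0=s0, metadata=meta)


def reconstruct_stack(tm: TrainedModel, sparse_stack: CESTImageStack) -> CESTImageStack:
    """Map every masked pixel's sparse spectrum through the trained model.

    Unmasked pixels are never read; they are filled with NaN in the
    output and excluded from all downstream metrics.  The output grid is
    the model's bound dense grid.
    """
    if tm.sparse_grid is None or tm.dense_grid is None:
        raise ValueError("model is not bound to offset grids")
    if sparse_stack.grid != tm.sparse_grid:
        raise ValueError(
            "stack grid does not match the model's sparse grid: "
            f"{sparse_stack.grid.offsets_ppm.tolist()} vs {tm.sparse_grid.offsets_ppm.tolist()}"
        )
    H, W, _ = sparse_stack.shape
    mask = sparse_stack.mask
    out = np.full((H, W, len(tm.dense_grid)), np.nan)
    vals = sparse_stack.data[mask]  # (n_masked, K)
    if vals.shape[0]:
        out[mask] = predict(tm, vals)
    return CESTImageStack(data=out, grid=tm.dense_grid, mask=mask.copy(),
                          metadata={"model": tm.model_config.architecture})


def lorentzian_reconstruct_stack(sparse_stack: CESTImageStack, dense: OffsetGrid,
                                 config=None) -> CESTImageStack:
    """Baseline reconstruction: fit the multi-pool Lorentzian model to each
    masked pixel's sparse spectrum and evaluate it on the dense grid.

    Pixels sharing a spectrum (common in noiseless phantoms) are fitted
    once.
    """
    from .lorentzian import evaluate_lorentzian, fit_lorentzian
    from .spectrum import ZSpectrum

    H, W, _ = sparse_stack.shape
    mask = sparse_stack.mask
    out = np.full((H, W, len(dense)), np.nan)
    vals = sparse_stack.data[mask]
    if vals.shape[0]:
        uniq, inverse = np.unique(vals, axis=0, return_inverse=True)
        dense_uniq = np.empty((uniq.shape[0], len(dense)))
        for i, row in enumerate(uniq):
            fit = fit_lorentzian(ZSpectrum(sparse_stack.grid, row, check_bounds=False), config)
            dense_uniq[i] = evaluate_lorentzian(fit, dense).z
        out[mask] = dense_uniq[inverse]
    return CESTImageStack(data=out, grid=dense, mask=mask.copy(),
                          metadata={"model": "lorentzian"})


def save_stack(stack: CESTImageStack, path) -> None:
    """Write NIfTI volume + JSON offsets sidecar (+ mask/S0 NIfTIs)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(stack.data.astype(np.float64), np.eye(4)), str(path))
    base = str(path)
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    sidecar = {
        "offsets_ppm": list(map(float, stack.grid.offsets_ppm)),
        "metadata": stack.metadata,
        "has_mask": stack.mask is not None,
        "has_s0": stack.s0 is not None,
    }
    Path(base + ".offsets.json").write_text(json.dumps(sidecar, indent=1))
    if stack.mask is not None:
        nib.save(nib.Nifti1Image(stack.mask.astype(np.uint8), np.eye(4)), base + ".mask.nii")
    if stack.s0 is not None:
        nib.save(nib.Nifti1Image(stack.s0.astype(np.float64), np.eye(4)), base + ".s0.nii")


def load_stack(path) -> CESTImageStack:
    path = Path(path)
    data = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    base = str(path)
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    sidecar = json.loads(Path(base + ".offsets.json").read_text())
    mask = None
    if sidecar.get("has_mask"):
        mask = np.asanyarray(nib.load(base + ".mask.nii").dataobj).astype(bool)
    s0 = None
    if sidecar.get("has_s0"):
        s0 = np.asanyarray(nib.load(base + ".s0.nii").dataobj, dtype=float)
    return CESTImageStack(data=data, grid=OffsetGrid(sidecar["offsets_ppm"]),
                          mask=mask, s0=s0, metadata=sidecar.get("metadata", {}))
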