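"""Reconstruction quality metrics for CEST image stacks.

Four instruments, applied frame-by-frame (one frame per offset) over the
ROI mask: the absolute error modulus (|recon - truth| as percent of the
normalized Z signal), pooled ordinary-least-squares regression of the
reconstruction on the ground truth with its coefficient of
determination, the structural similarity index (Gaussian 11x11 window,
sigma 1.5, K1 = 0.01, K2 = 0.03, data range 1.0), and the peak
signal-to-noise ratio in dB at data range 1.0.

Unmasked pixels are ignored entirely: MAE, PSNR and the regression index
only masked pixels, and SSIM replaces unmasked pixels by a constant
before windowing so their values can never leak in.  Identical frames
yield PSNR = +inf, which is reported as-is per offset and excluded from
the grand mean with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import CESTImageStack

__all__ = [
    "EvaluationReport",
    "abs_error_modulus",
    "pooled_regression",
    "regression_r2",
    "ssim_per_offset",
    "psnr_per_offset",
    "ssim_pair",
    "summarize",
    "evaluate_stacks",
    "table2",
]

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # radius 5 -> 11-sample window
_K1, _K2 = 0.01, 0.03


def _check_pair(recon: CESTImageStack, truth: CESTImageStack) -> np.ndarray:
    if recon.grid != truth.grid:
        raise ValueError("reconstruction and truth are on different offset grids")
    if recon.data.shape != truth.data.shape:
        raise ValueError("stack shapes differ")
    if not np.array_equal(recon.mask, truth.mask):
        raise ValueError("stack masks differ")
    return recon.mask


def abs_error_modulus(recon: CESTImageStack, truth: CESTImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel-per-offset |recon - truth| x 100 (NaN outside the mask)
    and its per-offset mean over the mask."""
    mask = _check_pair(recon, truth)
    err = np.abs(recon.data - truth.data) * 100.0
    err[~mask] = np.nan
    per_offset = err[mask].mean(axis=0)
    return err, per_offset


def pooled_regression(truth_values: np.ndarray, recon_values: np.ndarray) -> tuple[float, float, float]:
    """OLS of reconstructed on true values: (slope, intercept, R^2) with
    R^2 = 1 - SS_res/SS_tot."""
    x = np.asarray(truth_values, dtype=np.float64).ravel()
    y = np.asarray(recon_values, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("regression needs at least two points")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0.0:
        raise ValueError("R^2 undefined: ground truth is constant")
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: reconstruction is constant")
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(slope), float(intercept), float(r2)


def regression_r2(recon: CESTImageStack, truth: CESTImageStack) -> tuple[float, float, float]:
    """Pooled OLS of reconstructed on true Z over all masked pixels and
    offsets."""
    mask = _check_pair(recon, truth)
    return pooled_regression(truth.data[mask], recon.data[mask])


def ssim_pair(x: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None,
              data_range: float = 1.0) -> tuple[float, np.ndarray]:
    """Gaussian-weighted SSIM between two 2-D frames.

    Returns (masked mean over the border-cropped map, full SSIM map).
    Unmasked pixels are replaced by 0 before filtering so they cannot
    influence the result.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if mask is not None:
        x = np.where(mask, x, 0.0)
        y = np.where(mask, y, 0.0)
    filt = lambda im: gaussian_filter(im, _SSIM_SIGMA, truncate=_SSIM_TRUNCATE)
    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cxy = uxy - ux * uy
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    smap = ((2 * ux * uy + c1) * (2 * cxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = int(_SSIM_TRUNCATE * _SSIM_SIGMA + 0.5)  # 5
    inner = np.zeros(x.shape, dtype=bool)
    if min(x.shape) > 2 * pad:
        inner[pad:-pad, pad:-pad] = True
    else:  # frame smaller than the window: no border crop possible
        inner[:] = True
    sel = inner if mask is None else (inner & mask)
    return float(smap[sel].mean()), smap


def ssim_per_offset(recon: CESTImageStack, truth: CESTImageStack) -> np.ndarray:
    """Mean SSIM per offset frame, averaged over masked pixels."""
    mask = _check_pair(recon, truth)
    K = recon.data.shape[2]
    return np.array(
        [ssim_pair(recon.data[:, :, k], truth.data[:, :, k], mask)[0] for k in range(K)]
    )


def psnr_per_offset(recon: CESTImageStack, truth: CESTImageStack,
                    data_range: float = 1.0) -> np.ndarray:
    """PSNR (dB) per offset frame over masked pixels; identical frames
    give +inf."""
    mask = _check_pair(recon, truth)
    diff = (recon.data - truth.data)[mask]  # (n_masked, K)
    mse = np.mean(diff.astype(np.float64) ** 2, axis=0)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(data_range**2 / mse)


@dataclass(frozen=True)
class EvaluationReport:
    per_offset_mae_pct: tuple[float, ...]
    per_offset_ssim: tuple[float, ...]
    per_offset_psnr_db: tuple[float, ...]
    slope: float
    intercept: float
    r2: float
    mean_mae_pct: float
    mean_ssim: float
    mean_psnr_db: float
    n_pixels: int
    n_offsets: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def per_offset_frame(self, offsets_ppm) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_ppm": np.asarray(offsets_ppm, dtype=float),
                "mae_pct": self.per_offset_mae_pct,
                "ssim": self.per_offset_ssim,
                "psnr_db": self.per_offset_psnr_db,
            }
        )


def summarize(mae_per_offset: np.ndarray, ssim_vals: np.ndarray, psnr_vals: np.ndarray,
              regression: tuple[float, float, float], n_pixels: int) -> EvaluationReport:
    """Assemble per-offset curves and pooled regression into one report.

    Grand means are plain means over offsets; infinite PSNR frames are
    excluded from the PSNR mean (with a warning).
    """
    psnr_vals = np.asarray(psnr_vals, dtype=float)
    finite = np.isfinite(psnr_vals)
    if not finite.all():
        warnings.warn(
            f"{int((~finite).sum())} offset frame(s) have infinite PSNR "
            "(identical images); excluded from the PSNR mean",
            stacklevel=2,
        )
    mean_psnr = float(psnr_vals[finite].mean()) if finite.any() else float("inf")
    slope, intercept, r2 = regression
    return EvaluationReport(
        per_offset_mae_pct=tuple(float(v) for v in mae_per_offset),
        per_offset_ssim=tuple(float(v) for v in ssim_vals),
        per_offset_psnr_db=tuple(float(v) for v in psnr_vals),
        slope=slope, intercept=intercept, r2=r2,
        mean_mae_pct=float(np.mean(mae_per_offset)),
        mean_ssim=float(np.mean(ssim_vals)),
        mean_psnr_db=mean_psnr,
        n_pixels=int(n_pixels), n_offsets=len(mae_per_offset),
    )


def evaluate_stacks(recon: CESTImageStack, truth: CESTImageStack) -> EvaluationReport:
    """Run all four instruments on a reconstruction/truth stack pair."""
    mask = _check_pair(recon, truth)
    _, mae = abs_error_modulus(recon, truth)
    ssim_vals = ssim_per_offset(recon, truth)
    psnr_vals = psnr_per_offset(recon, truth)
    reg = regression_r2(recon, truth)
    return summarize(mae, ssim_vals, psnr_vals, reg, int(mask.sum()))


def table2(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """Methods x {SSIM, PSNR} summary table (plus MAE% and R^2 columns)."""
    return pd.DataFrame(
        {
            name: {
                "SSIM": r.mean_ssim,
                "PSNR": r.mean_psnr_db,
                "MAE%": r.mean_mae_pct,
                "R2": r.r2,
            }
            for name, r in reports.items()
        }
    ).T
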