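"""The multi-pool Lorentzian baseline and where it fails.

Fits the 6-pool Lorentzian model (baseline + fixed centers/widths, free
amplitudes) to a simulated sparse spectrum, evaluates it on the dense
grid, and compares the reconstruction error inside and outside the
[-2, 2] ppm band.  With only three sparse samples between -2 and 2 ppm
the interpolation through the water/MT region is poorly constrained,
which is the baseline's characteristic failure mode.
"""

import numpy as np

import cestrecon as cr

tissue = cr.midpoint_tissue()
pulse, scanner = cr.SaturationPulse(), cr.ScannerConfig()
sparse = cr.simulate_zspectrum(tissue, pulse, scanner, cr.sparse_default())
dense_truth = cr.simulate_zspectrum(tissue, pulse, scanner, cr.dense_default())

fit = cr.fit_lorentzian(sparse)
recon = cr.evaluate_lorentzian(fit, cr.dense_default())

print("fitted pools (amplitude @ center, width fixed):")
for p in fit.pools:
    print(f"  {p.amplitude:.4f} @ {p.center_ppm:+.1f} ppm (w = {p.fwhm_ppm} ppm)")
print(f"baseline z0 = {fit.z0:.4f}, residual at the 11 inputs = {fit.residual:.2e}")

err = np.abs(recon.z - dense_truth.z) * 100
inner = np.abs(recon.grid.offsets_ppm) <= 2.0
print(f"\ndense-grid MAE inside [-2, 2] ppm: {err[inner].mean():.2f}%")
print(f"dense-grid MAE outside:            {err[~inner].mean():.2f}%")
print("the error concentrates between -2 and 2 ppm, where the sparse "
      "protocol has few samples")
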