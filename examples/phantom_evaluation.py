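"""Pixel-wise reconstruction of a digital brain phantom, fully scored.

Builds a 32x32 three-region phantom (gray-matter-like, white-matter-like
and tumor-like tissue inside an elliptical brain mask), trains a small
TCN-LSTM, reconstructs the dense image stack pixel by pixel, and prints
the four quality metrics: absolute error modulus, pooled regression R^2,
SSIM and PSNR.
"""

import numpy as np

import cestrecon as cr
from cestrecon.imaging import reconstruct_stack
from cestrecon.phantom import PhantomSpec, make_phantom

spec = PhantomSpec(height=32, width=32, noise_sigma=0.0, seed=0)
sparse_stack, dense_truth, labels = make_phantom(
    spec, cr.sparse_default(), cr.dense_default())
values, counts = np.unique(labels[labels > 0], return_counts=True)
print(f"phantom: {int(sparse_stack.mask.sum())} brain pixels, "
      f"region sizes {dict(zip(values.tolist(), counts.tolist()))}")

ds = cr.generate_dataset(2000, seed=0, progress=True)
model = cr.build_model(cr.ModelConfig(architecture="tcn_lstm"), seed=0)
tm = cr.train(model, ds, cr.TrainingConfig(epochs=8, seed=0), progress=True)

recon = reconstruct_stack(tm, sparse_stack)
report = cr.evaluate_stacks(recon, dense_truth)

print(f"\nmean MAE: {report.mean_mae_pct:.2f}% of normalized Z")
print(f"pooled regression R^2: {report.r2:.5f} (slope {report.slope:.4f})")
print(f"mean SSIM: {report.mean_ssim:.4f}   mean PSNR: {report.mean_psnr_db:.2f} dB")
print("SSIM near 1 and MAE below 3% mean the reconstructed offset frames "
      "are visually indistinguishable from the ground truth")
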