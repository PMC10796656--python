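# cestrecon

Dense CEST Z-spectrum reconstruction from sparse acquisitions.

CEST (chemical exchange saturation transfer) MRI detects dilute solute
protons — amide, guanidyl/amine, hydroxyl, NOE- and MT-coupled pools —
through their saturation transfer to water. The measurement is the
Z-spectrum, the normalized water signal Z(δ) = Mz(t_sat)/M0 as a
function of the saturation offset δ (ppm), acquired one image per
offset. Dense spectral sampling (101 offsets over −6…6 ppm) enables
quantitative analysis but is slow; this package reconstructs the dense
spectrum pixel-by-pixel from an 11-offset sparse protocol, reducing the
number of acquisitions by 1 − 11/101 ≈ 89%.

It is aimed at CEST-MRI methods researchers who want the full workflow
in one importable library:

- **`cestrecon.bm`** — 7-pool Bloch–McConnell simulation under
  continuous-wave saturation (B1 = 1.2 μT, t_sat = 1.5 s, 7 T defaults):
  dM/dt = A·M + b per offset, solved as
  M(t_sat) = expm(A·t_sat)(M0 − M_ss) + M_ss, M_ss = −A⁻¹b, with a
  stiff-ODE fallback. Tissue parameters (f_s, k_sw, T1, T2 per pool) are
  sampled uniformly within an in vivo bounding box to build paired
  sparse/dense training sets of any size.
- **`cestrecon.nn` / `cestrecon.training`** — five sequence-to-sequence
  regressors (RNN, LSTM, GRU, TCN, and the hybrid TCN-LSTM) mapping the
  11-vector to the 101-vector, written as a compact pure-numpy stack
  with hand-derived backpropagation, trained with Adam on MSE (batch
  512, lr 1e-3 halved every 5 epochs, dropout 0.2, 7:3 split).
- **`cestrecon.lorentzian`** — the classical multi-pool Lorentzian fit
  Z(δ) = z0 − Σ A_i(w_i/2)²/((w_i/2)² + (δ−c_i)²) as the non-learning
  baseline.
- **`cestrecon.imaging` / `cestrecon.phantom`** — pixel-wise
  reconstruction of H×W×K image stacks (NIfTI + offsets sidecar), and
  three-region digital brain phantoms for validation.
- **`cestrecon.metrics`** — absolute error modulus (%), pooled
  regression R², SSIM and PSNR, masked and per offset.

## Worked example

```bash
python examples/train_and_reconstruct.py
```

generates 2,000 paired spectra, trains a TCN-LSTM for 8 epochs and
prints:

```
validation spectra: 600
validation MAE: 1.51% of normalized Z
pooled regression: slope 0.9627, intercept 0.0257, R^2 0.98679
```

i.e. on held-out simulated spectra the reconstructed dense Z-values
deviate from the truth by 1.5% of the normalized signal on average, and
regressing reconstruction on truth over all 600×101 value pairs gives a
near-identity line. (At the benchmark scale of 20,000 pairs and 20
epochs the same model reaches well under 1% MAE; 3% is the conventional
acceptability threshold for reconstructed CEST images.)

Other narrative examples: `examples/simulate_spectra.py` (the
simulator), `examples/lorentzian_baseline.py` (the baseline and its
characteristic failure between −2 and 2 ppm),
`examples/phantom_evaluation.py` (image-stack reconstruction with all
four metrics).

A thin CLI exposes the same workflow
(`cestrecon simulate|train|phantom|reconstruct|evaluate|end2end`); every
run writes a manifest with config hash and seeds.

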