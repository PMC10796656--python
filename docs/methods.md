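# Methods

## Problem

CEST (chemical exchange saturation transfer) MRI measures the Z-spectrum
— the normalized water signal Mz/M0 as a function of RF saturation
frequency offset — pixel by pixel. Quantitative analysis wants a dense
spectrum (here 101 offsets, −6…6 ppm), but every offset is a separate
acquisition, so dense sampling is slow. This package reconstructs the
dense spectrum from an 11-offset sparse acquisition
F = [−6.00, −3.60, −2.64, −1.68, −1.20, 0.96, 1.92, 2.76, 3.36, 3.96,
6.00] ppm with sequence-to-sequence models trained purely on simulated
data, cutting the number of acquisitions by 1 − 11/101 ≈ 89% (≥ 2/3).

## Bloch–McConnell simulator

Magnetization of P exchanging proton pools under continuous-wave
saturation evolves as dM/dt = A·M + b in the frame rotating at the RF
frequency. Per pool: a 3×3 Bloch block with R1 = 1/T1, R2 = 1/T2,
off-resonance Δω_i = (δ_i − δ_RF)·γB0·10⁻⁶ and nutation ω1 = γB1
coupling My↔Mz. Exchange is star-topology between water and each of the
six solute pools (amide +3.5, guanidyl/amine +2, hydroxyl +1.3,
NOE −1.6, MT −2.4, NOE −3.5 ppm), applied to all three components with
rate k_sw out of the solute and the mass-balance rate
k_ws = k_sw·f_s/f_w out of water. b carries the recovery terms f_s/T1.
The MT pool is an ordinary three-component Lorentzian Bloch pool (its
T2 is supplied like any other pool's); super-Lorentzian lineshapes are
out of scope.

With constant A (CW), the solution from thermal equilibrium is closed
form: M(t_sat) = expm(A·t_sat)(M0 − M_ss) + M_ss with M_ss = −A⁻¹b.
If A's condition number exceeds 1e12 the solver falls back to adaptive
stiff integration (LSODA with the analytic Jacobian, rtol 1e-10); the
same integrator is the independent oracle in the tests, where the two
paths agree to |ΔZ| < 1e-6 across the sampling box. Constants:
γ = 2.6752218744×10⁸ rad s⁻¹ T⁻¹; positive ppm is downfield of water.
Defaults: B0 = 7 T, B1 = 1.2 μT, t_sat = 1.5 s, no recovery delay,
no readout modelling, no B0/B1 inhomogeneity.

Training data sample 20 free parameters independently and uniformly:
(f_s, k_sw, T2) per solute plus water (T1, T2); solute T1 is fixed at
1 s, water f_s at 1. The bounds (stored in SI units) are the in vivo
box used throughout: e.g. water T1 ∈ [1, 3] s, amide f_s ∈ [0.1, 3]×10⁻³
with k_sw ∈ [1, 100] s⁻¹, MT f_s ∈ [10, 200]×10⁻³ with T2 ∈ [0.01, 0.1] ms.
Spectra are noiseless by default; optional i.i.d. Gaussian noise on Z
exists for robustness experiments. Since all 11 sparse offsets lie on
the dense grid, each tissue is simulated once on the 101-point grid and
the sparse rows are extracted (tested against direct simulation).

## Reconstruction models

Five architectures map the 11-vector to the 101-vector; all are
implemented in a small pure-numpy layer library with hand-written
backpropagation (validated against finite differences):

- **rnn / lstm / gru** — two stacked recurrent layers, hidden size 128,
  with ReLU and dropout on the sequence passed between the layers (the
  cells keep their canonical tanh/σ internals).
- **tcn** — four residual blocks of weight-normalized dilated causal
  convolutions (kernel 3, dilations 1/2/4/8, 64 channels, ReLU and
  dropout inside each block).
- **tcn_lstm** — the TCN stack produces an 11×64 feature sequence which,
  concatenated with the raw spectrum (short-range path), feeds a single
  LSTM (hidden 128). The TCN supplies dilated (long-range) context, the
  LSTM the sequential memory.

Two design choices make these encoders trainable in the few hundred
optimizer steps a desk-scale run affords. First, the regression head is
an affine map over the **whole** hidden sequence (flattened), not just
the final hidden state: with zero-initialized gate biases an LSTM's
forget gates sit at 0.5, so the final state initially remembers only
the last couple of offsets, and learning to open the gates consumes
most of the step budget (a "final-state" head mode is retained as an
option). Second, every model carries a trainable linear bypass from the
11 inputs straight to the 101 outputs, initialized to the
piecewise-linear interpolation matrix between the two offset grids — a
data-independent, purely geometric starting point — while the encoder
head starts at zero. The untrained model therefore predicts exactly the
interpolation baseline and the network learns the correction, the same
residual convention used throughout modern sequence regression. Without
the bypass the required weight magnitudes exceed what Adam can
accumulate under the decaying-lr schedule at this scale (each parameter
moves at most ~lr per step, and the 5-epoch halving caps the total
movement), which shows up as a hard validation plateau an order of
magnitude above the attainable error.

Training: Adam on MSE, batch 512, lr 1e-3 halved every 5 epochs
(0-based: lr(e) = 1e-3·0.5^⌊e/5⌋), dropout ratio 0.2, 7:3
train/validation split by seeded permutation, best-validation-epoch
checkpoint, no early stopping, no input normalization (Z already lies
in [0, 1]). Weights default to fan-in-scaled normal draws
(std = 1/√fan_in), which keeps activations and the trained weight
magnitudes on the order of the initial draw; a constant-std recipe is
available through `weight_init_std`, and weight-normalized kernels
always start at their raw draw (g = ‖v‖). The output head is a single
affine map — no autoregressive decoding, since the output grid is
fixed. Inputs are Z-values only (one channel); an optional channel
carrying the ppm offsets exists but is off by default because the
sparse grid never varies.

Models train on CPU in float32; determinism holds run-to-run under a
fixed thread configuration and is asserted in the tests.

## Lorentzian baseline

The non-learning comparison fits Z(δ) = z0 − Σ A_i·(w_i/2)²/((w_i/2)² +
(δ−c_i)²) to the 11 sparse points by bounded trust-region least squares
(amplitudes ∈ [0,1], z0 ∈ [0.5,1.1], xtol 1e-10, ≤2000 evaluations,
fixed init: z0 = max z, amplitudes 0.05). A fully free 6-pool model
(19 parameters) is unidentifiable from 11 points, so the default fixes
the six centers at {0, 3.5, 2, −1.6, −2.4, −3.5} ppm and the widths at
literature-typical values (2.0, 1.0, 1.5, 1.5, 25.0, 3.5 ppm),
fitting 7 parameters. A free-widths mode exists and warns. Evaluated on
the dense grid, the baseline's error concentrates in [−2, 2] ppm, where
the sparse protocol has only three samples — reproduced in the tests.

## Image pipeline and phantoms

Stacks are H×W×K cubes (offset trailing, row-major, inclusion masks);
on disk, NIfTI + JSON offsets sidecar. Normalization to Z is explicit
(data = raw/S0) and optional. Reconstruction maps each masked pixel
through the trained model; unmasked pixels are NaN and never read.

The digital phantom is an elliptical brain mask with three regions
(gray-matter-like cortex, white-matter-like inner ellipse, tumor-like
disc). Region parameters ship as YAML presets chosen inside the sampling
bounds — e.g. the tumor preset has elevated amide f_s (2.6×10⁻³), longer
water T1 (2.5 s) and reduced MT — and are validated against the bounds
so phantoms stay inside the training domain. Noise is additive Gaussian
on Z (Rician effects are negligible at Z-level SNR and out of scope).
The phantom emulates piecewise-constant tissue with sharp boundaries;
it does not emulate partial-volume mixing, B0/B1 inhomogeneity,
motion, or spatially correlated noise, so passing phantom tests shows
the pixel-wise mapping and the pipeline plumbing are correct — not that
in vivo data with those confounds would reconstruct equally well.

## Evaluation

Per offset frame over the mask: mean absolute error modulus
(|recon − truth|·100), SSIM (Gaussian 11×11 window, σ 1.5, K1 = 0.01,
K2 = 0.03, data range 1.0 — stacks hold normalized Z; masked mean over
the border-cropped map, unmasked pixels replaced by a constant before
windowing), and PSNR = 10·log10(1/MSE) dB (identical frames give +inf,
reported per offset but excluded from the grand mean with a warning).
Pooled regression: OLS of reconstructed on true Z over all masked
pixels × offsets, R² = 1 − SS_res/SS_tot; R² is undefined (error) for
constant inputs. The in-package SSIM is tested to 1e-6 against
scikit-image's implementation.

## Scale choices

The validation benchmark used by the tests and by
`scripts/acceptance.py` runs at 20,000 simulated pairs and 20 epochs per
architecture — sizes at which every architecture's validation R² and the
3% error threshold are meaningful while the full five-architecture run
completes in minutes on one CPU core. The full-scale recipe
(350,000 pairs, 50 epochs) remains available through `generate_dataset`
and the `TrainingConfig` defaults for users with the time budget.

## Known limitations

- CW saturation only; pulsed trains and shaped pulses are out of scope.
- MT is Lorentzian; semi-solid pools with super-Lorentzian lineshapes
  would need a different absorption model.
- The models are bound to the exact sparse/dense grids they were trained
  on and refuse other grids by design.
- Training uses plain minibatch Adam with no augmentation or noise
  injection; robustness to measurement noise depends on adding noise to
  the training data (supported but off by default).
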