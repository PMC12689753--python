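# Methods

## Signal model and problem setting

The package targets T2 mapping with a single-coil multi-slice multi-echo
spin-echo (MSME) acquisition. Each pixel's echo train follows the
mono-exponential model S(S0, T2, TE) = S0·exp(−TE/T2) with a *complex*
amplitude S0 (the parameter triple is p = (T2, Re S0, Im S0)); stimulated
and indirect echoes, multi-component T2, and B0/B1 effects are outside the
model. The amplitude derives from tissue properties as
S0 = PD·(1 − exp(−TR/T1)). The default schedule is 16 echoes at
TE = 10, 20, …, 160 ms with TR = 7000 ms.

Acquisition is modeled by the multi-contrast encoding operator
E_Ω = [M_{Ω₁}F, …, M_{Ω_P}F]ᵀ: per echo, an *orthonormal, centered* 2-D
DFT followed by a binary phase-encode line mask. Unitary scaling makes
Parseval/adjoint identities exact in tests and keeps the k-space noise
variance equal to the image-domain noise variance. Masks are 1-D Cartesian
line patterns: a fully sampled central block of max(2, 4%·H) lines plus
outer lines drawn without replacement with probability proportional to a
Gaussian density in |k_y| with σ = H/4 (a standard retrospective
variable-density CS-MRI protocol; the width is a package choice). Each echo
gets an independent draw, giving temporally incoherent sampling across the
echo train. The per-echo sampled-line count is round(H/AF).

## Networks

**Reconstruction module** (`f_rec`): a deep cascade of convolutional
denoisers with closed-form data-consistency (DC) steps. One cascade is
x ← x + D(x) (a residual CNN on the 2P real channels of the P complex
echoes), followed by FFT, the DC step, and inverse FFT. The DC step with
weight ν replaces estimated k-space values on the sampling set by
(k + ν·y)/(1 + ν); the default ν = ∞ is hard replacement, appropriate for
the closed-form unrolling this module follows, and makes the invariant
"measured coefficients are never altered" exact to machine precision. The
final convolution of each cascade is zero-initialized so an untrained
cascade is the identity plus DC. Desk preset: 2 cascades × 3 convolutions
with 16 filters (3×3); full preset: 5 × 5 with 64 filters. Echoes are
processed jointly as channels so the CNN can exploit cross-echo redundancy.

**Mapping module** (`f_map`): a pixel-wise fully connected network (4
hidden layers × 128 rectifier units by default) from the length-2P pixel
vector (real parts then imaginary parts, echo order) to the parameter
triple. The T2 output passes through a smooth bounded positivity transform
T2 = t2_min + (t2_max − t2_min)·σ(z) with t2_min = 1 ms and t2_max =
3000 ms; boundedness keeps exp(−TE/T2) inside the data-consistency loss
finite for any network output. Input normalization by the first-echo
magnitude (with magnitude and phase re-injected) exists behind a config
flag but is off by default, so the network consumes the raw echo vector.

Both modules are implemented in numpy and differentiated with reverse-mode
autodiff (HIPS `autograd`); convolutions are expressed as sums of shifted
tensor contractions so both passes stay in BLAS. Weight initialization is
variance-scaled and seeded from the config.

## Losses and training

L_total = λ_r·L_r + λ_p·L_p + λ_dc·L_dc with λ_r = 1, λ_p = 10⁻²,
λ_dc = 10⁻⁶. L_r is the squared error between ground-truth and
reconstructed multi-contrast images (2P real channels), L_p the squared
error on the three parameter channels jointly, and L_dc the squared error
between measured k-space and E_Ω S(p_rec). Each term defaults to the
literal squared L2 norm (per batch element) — the convention the λ
defaults are calibrated for: the *relative* weight of L_p against L_r is
then 3/(2P)·λ_p regardless of resolution, whereas a mean-over-elements
reduction (available as an option) silently boosts L_p by the element-count
ratio (~10× for 16 echoes) and lets the parameter loss dominate the
reconstruction loss. Since Adam's updates are invariant to the overall
loss scale, only these relative weights matter. Training
uses Adam at 10⁻⁴, slices shuffled across cases per epoch, a freshly drawn
mask set per batch (regenerating the undersampled input from the stored
noisy fully sampled k-space), validation on fixed stored masks each epoch,
and early stopping when validation L_total fails to improve for 10
consecutive epochs (best-validation weights returned). Validation uses
L_total; the choice of the total rather than a sub-loss is a package
decision.

Model variants: **A** trains both modules end-to-end with all three losses;
**C** trains `f_rec` alone with L_r only and uses least-squares fitting at
inference; **D** trains `f_rec` with all three losses where the maps inside
L_p/L_dc come from the *frozen* pretrained `f_map` (keeping those losses
differentiable), again with least-squares fitting at inference; **F** is
the zero-fill + least-squares baseline with no training.

**Mapping-module pretraining.** `f_map` is pretrained by supervised
regression on a synthetic dictionary: T2 ~ U[10, 2500] ms, |S0| ~
U[0.05, 1], phase ~ U[0, 2π), noiseless decay curves by default
(configurable SNR). The loss is the mean squared parameter error with the
T2 channel divided by a scale constant (150 ms by default): without this
balancing the millisecond-magnitude T2 channel dominates the objective by
four orders of magnitude and the O(1) amplitude channels are effectively
untrained (observed as ~13% median |S0| error versus ~1% with balancing).
Pretraining runs 25k Adam steps at 2·10⁻³ (stepped down ×0.3 at 60% and
85% of the run), batch 512. Noiseless pretraining teaches the analytic
inverse of the signal model; robustness to reconstruction residue is left
to end-to-end fine-tuning.

## Synthetic dataset

The generator emulates a brain-phantom-derived simulation protocol without
any external data: randomized nested-ellipse head phantoms (scalp/skull
rim ⊃ CSF ⊃ gray-matter ribbon ⊃ white-matter core, 0–3 lesion blobs in
white matter, slice radii tapering like ellipsoid cross-sections), a
tissue table of representative 1.5–3 T literature values — CSF (PD 1.00,
T1 4000, T2 2000), gray matter (0.86, 1200, 100), white matter (0.77, 800,
80), rim (0.30, 400, 50), lesion (0.90, 1400, 150) — S0 from the TR
saturation formula, per-case normalization to max |S0| = 1, signal
synthesis, unitary FFT, and complex white Gaussian k-space noise with one
shared scale across echoes calibrated *on the realized draw* so the
magnitude-image PSNR of the first echo equals 40 dB exactly (full-image
PSNR, peak = max noiseless magnitude). Undersampling is applied
retrospectively per slice. Full-scale protocol: 20 cases split 16/2/2 with
60 slices at 256×256 (960 training slice records); desk preset: 10 cases
8/1/1 with 12 slices at 64×64, chosen so the complete study (dataset,
pretraining, end-to-end training, evaluation) runs on one CPU core in tens
of minutes.

What the phantom does *not* model: real cortical geometry and partial
voluming (tissue boundaries are hard), B0/B1 inhomogeneity, multi-coil
encoding, and through-plane effects. Passing the scaled-down experiments
therefore demonstrates that the pipeline's operators, losses, and training
mechanics are correct and that the method beats its baselines under the
simulated conditions — not that specific NRMSE values transfer to real
anatomy, whose tissue values and resolution differ.

## Evaluation

NRMSE(x, y) = ‖x − y‖₂,Φ / ‖x‖₂,Φ with x the ground truth, reported in
percent; T2 NRMSE on the T2 map, S0 NRMSE on the complex-magnitude S0 map,
both over the same region Φ. Φ is the foreground mask |S0_gt| > 0.05·max
|S0_gt| (threshold configurable). This choice matters for absolute
numbers: including empty background would deflate the normalizer's
denominator contribution and the errors alike. Note that with a
long-T2 CSF compartment the T2 norm over Φ is dominated by CSF, so the T2
NRMSE largely reflects relative CSF accuracy — the hardest regime, since
TE ≤ 160 ms samples only the top 8% of a 2000 ms decay. PSNR is
10·log₁₀(L²/MSE_Φ) with L the peak ground-truth intensity (the
literal sum-of-squares variant is available behind a flag; the
conventional MSE form is the default because the 40 dB calibration level
is only meaningful under it). Summaries are mean ± sd over test slices.

## Numerical choices and degenerate inputs

- Least-squares fitting is complex variable projection: for fixed T2 the
  optimal S0 is (Σ w_i x_i)/(Σ w_i²) with w_i = exp(−TE_i/T2); T2 is found
  by a 256-point log-spaced grid scan on [1, 3000] ms plus golden-section
  refinement to 10⁻³ ms, vectorized over pixels. Complex fitting is
  unbiased under complex Gaussian noise (magnitude fitting, available
  behind a flag, is Rician-biased). All-zero signals return (t2_min, 0, 0)
  with a degenerate flag; estimates at the bounds are flagged as clamped.
- T2 = 0 is permitted only on background (S0 = 0) pixels and the signal
  there is defined as 0.
- Mask generation requires round(H/AF) ≥ center lines; violations raise.
- The echo-count reduction experiment selects an evenly strided subset of
  the 16-echo schedule (indices round(linspace(0, 15, P))), covering the
  full TE range; for P = 4 that is TE = {10, 60, 110, 160} ms.
- Dataset splits, phantom geometry, noise draws, masks, batch order and
  weight initialization all derive from explicit seeds; regenerating a
  dataset from the same config is bit-identical.

## Known limitations

- The desk-scale network (2 cascades, 16 filters) and training budget are
  deliberately small; absolute NRMSE at desk scale is not comparable to a
  full-scale GPU-trained model, and full-scale runs with this numpy
  implementation would be slow. In particular, at 64×64 with AF = 5 only
  ~13 phase-encode lines are measured per echo and the scalp/skull rim and
  CSF become 1–2-pixel rings; their reconstruction error dominates the S0
  NRMSE (the T2 NRMSE is less affected because the jointly fine-tuned
  mapping network compensates artifact structure when estimating decay
  rates, while S0 inherits the image intensity error directly). Scaled-down
  S0 accuracy is therefore reconstruction-limited, not mapping-limited: the
  pretrained mapper is an order of magnitude more accurate on clean images
  than the full pipeline is on undersampled data at this scale. A second
  desk-scale effect compounds this: inside the unweighted parameter loss
  the T2 channel (ms magnitude) outweighs the O(1) amplitude channels by
  orders of magnitude, so during end-to-end fine-tuning on artifacted
  inputs the amplitude outputs are essentially unanchored and their
  accuracy varies noticeably from seed to seed, while T2 accuracy is
  stable. Desk-scale S0 errors should be read with that caveat; T2 is the
  robust desk-scale readout.
- The tissue table is a design choice, not fitted to any subject; absolute
  NRMSE values depend on it (notably the CSF T2).
- Single-coil Cartesian encoding only; the exact variable-density law is a
  package choice.
- The u-net direct-mapping baseline and the low-rank + sparse iterative
  reconstruction baseline from the surrounding literature are out of
  scope; comparisons here are against the zero-fill and least-squares
  classical pipeline and the trained ablations (C, D).
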