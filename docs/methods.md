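# Methods

`nadd_ct` implements noise-augmented deep denoising (NADD) for low-dose CT
end to end: it simulates fan-beam CT rawdata from synthetic 2D patient
phantoms, injects projection-domain Poisson noise, generates noise-only
realization images, and trains channel-augmented convolutional denoisers
against unaugmented and parameter-matched baselines. This note records the
models, the assumptions, the tunable parameters, and the design choices made
where the design was genuinely open.

## The physical model

### Geometry

A circular fan-beam acquisition with a flat detector: source-isocenter
distance R_F = 650 mm, isocenter-detector distance R_D = 420 mm, 1024 views
over 360°, 720 detector columns of 1.2 mm, reconstructed on a 512×512 grid of
0.5 mm pixels (the `clinical` preset). Cone-beam acquisitions reconstructed with
the Feldkamp algorithm reduce, on the central detector row, exactly to 2D
fan-beam filtered backprojection, so the package implements the 2D central-
slice equivalent; full 3D reconstruction is out of scope. A `desk` preset
(128×128 grid at 2 mm, 256 views, 272 columns of 2.4 mm) keeps every
experiment runnable in minutes on one CPU core. All distances are in mm;
images are in Hounsfield units (HU), with air at −1000.

### Forward projection and reconstruction

The forward operator X integrates the linear attenuation coefficient
μ = μ_water·(1 + HU/1000) along source→detector-pixel rays using Joseph's
method (stepping along the dominant ray axis with linear transverse
interpolation). μ_water = 0.0192 mm⁻¹, a monochromatic ≈70 keV convention;
only the scale of the line integrals matters for the noise model, not the
spectrum.

The inverse X⁻¹ is fan-beam FBP for a flat detector: the detector is rescaled
to a virtual detector through the isocenter, rows are cosine-weighted and
convolved with a band-limited ramp kernel (Shepp-Logan apodization by
default, Ram-Lak selectable), and backprojection applies the R_F²/U² distance
weight; the full-scan redundancy (every line measured twice over 360°)
contributes the factor ½. The operator is linear to floating-point
tolerance — the property that makes reconstructions of sinogram
*differences* meaningful noise-only images. Validation: forward projections
of analytic disks match chord-length integrals to <1% away from edges;
project-then-reconstruct on smooth phantoms has <0.1% relative RMSE inside
the 80% field of view at desk geometry; a disk's HU value is recovered at its
center to within a few HU.

### Noise injection

The noise operator Q converts a sinogram p to expected photon counts
I = I₀·e^(−p), draws k ~ Poisson(I) independently per detector pixel, and
log-converts back: p̂ = −ln(max(k, floor)/I₀). I₀ is uniform over the
detector — no heel effect, bowtie filtration or tube-current modulation —
and the Poisson mean may be any non-negative real. The count floor
(default 0.5) guarantees a finite logarithm under photon starvation; the
underlying sources are silent on zero-count handling, so the floor is a
declared implementation decision with no effect at the intensities used
(counts ≪ 0.5 are never the typical case at 10% dose here).

Dose levels: `I0_standard` defaults to 1×10⁵ photons/pixel — an absolute
scale chosen once as a realistic body-CT magnitude; only the low/standard
*ratio* is physically prescribed. Low dose is `dose_factor = 1/10` (90% dose
reduction), the medium-dose preset is 1/4. The standard-dose target also
receives one (weak) application of Q, so input and target share noise
*texture* but differ in magnitude by √10 in the image domain (verified by
ROI noise-std ratios through the linear FBP).

Noise-only realizations are rₙ = Q(q) − q, always computed from the *noisy*
measured sinogram q — the data available at inference time — never from the
clean p. Their reconstructions hₙ = X⁻¹rₙ are zero-mean images carrying the
patient-specific noise covariance: for eccentric cross-sections the noise
power is strongly anisotropic (directional high-pass energy ratio > 1.5,
typically 2–3 at desk scale), for near-circular sections it is isotropic
within ~2%. In the cross-dose experiment the realizations injected into
medium-dose (25%) inputs are deliberately kept at the low-dose intensity,
reproducing the noise-level mismatch of that protocol.

Randomness: every consumer draws from `numpy` Philox counter-based streams
spawned hierarchically (cohort → subject → slice; dose seed → realization),
so realizations are order-independent, adding subjects never perturbs
earlier ones, and the full chain is bit-reproducible from two integers
(phantom seed, dose seed).

## Phantoms

Bodies are smooth ellipses of soft-tissue background (20–60 HU) containing
2–5 non-overlapping hyper-/hypodense elliptical inserts (contrast ±30–300 HU)
that give the denoiser lesion-like structure; air outside is −1000 HU and
edges are anti-aliased by supersampled coverage. Two regimes are generated:
*eccentric* (axis ratio ≥ 1.8, drawn in 1.9–2.4 — shoulder-like sections
whose long attenuation paths produce correlated streak noise) and
*non-eccentric* (ratio ≤ 1.2). The thresholds are package conventions; the
regimes themselves are what the evaluation distinguishes. Slices of one
subject share the body outline and differ in insert placement, emulating
neighbouring slices of one scan.

What the generator does *not* emulate: anatomically realistic organ
structure and texture, bone/contrast extremes, 3D continuity between slices,
detector cross-talk and electronic noise. Passing tests therefore
demonstrate the *mechanism* of noise augmentation under controlled,
correctly-correlated noise — not clinical performance, which depends on
anatomy and vendor noise characteristics outside this model.

## Networks

CNN10 is a three-layer CNN: conv(9×9, (1+N)→n₁) + ReLU, conv(3×3, n₁→n₂) +
ReLU, conv(5×5, n₂→1), with n₁ = 64, n₂ = 32, trained by MSE against the
standard-dose target. The noise-augmented CNN10+N takes the low-dose image
plus N noise-only channels (channel 0 is always g; channels 1..N are the
realizations in index order). The trainable-parameter count is

    n₁·s₁²·(1+N) + n₁ + n₂·s₂²·n₁ + n₂ + s₃²·n₂ + 1

(76,353 for CNN10+10) and is cross-checked against enumeration of the
instantiated weight tensors. The parity baseline widens n₁ to the smallest
value reaching the augmented count — n₁ = 205, 76,683 parameters — to
separate augmentation benefit from raw capacity. An architecture-agnostic
augmentation contract (`augment_input_channels`, `BackboneDescriptor`) lets
third-party backbones participate by declaring their first layer; deeper
residual or adversarially trained denoisers are deliberately not bundled.

Implementation choices:

* Convolutions are same-padded so slice-level inference needs no cropping
  (a declared deviation from the valid-convolution original of this
  architecture family, recorded in the model metadata).
* The network runs on NumPy (im2col convolutions over BLAS, hand-derived
  gradients, Adam). Gradient correctness is verified against finite
  differences in the test suite.
* Weight initialization is He fan-in (seeded), with one deliberate
  exception: **the first-layer weights of the noise channels start at
  zero** ("silent start"). An augmented network then begins functionally
  identical to a freshly initialized unaugmented one and recruits the noise
  channels only where their gradient reduces the loss. Without this, the
  randomly-initialized noise-channel weights inject independent noise into
  the prediction and the network spends most of a short training budget
  un-learning them; with it, augmentation can only help or be ignored at
  any training length. Zero is a measure-zero saddle only in the trivial
  sense; the cross-channel gradient is generically nonzero.
* Training draws random patches (the receptive field is 15 pixels; desk
  training uses 16×16 patches so each Adam step is cheap), optionally
  permutes the noise channels per sample (they are exchangeable by
  construction — i.i.d. realizations — so this is a symmetry-respecting
  augmentation that equalizes gradient signal across channels), and decays
  the learning rate on a cosine schedule with best-validation selection.
  Inference is always full-slice.

## Pipeline and experiment protocol

Per slice: p = X(phantom); one application of Q at low dose gives the input
sinogram, an independent application at standard dose the target; FBP gives
g and the target image; N realizations come from the low-dose sinogram. One
dataset is generated at the maximum N of the arm grid, and arms with smaller
N use a channel prefix — realizations are i.i.d., so every arm trains on
identical data and differs only in input-channel count.

Normalization is global per channel over the *training split only*
(subject-level splits, never slice-level; a leakage audit test mutates test
subjects and asserts the normalizer is unchanged). The N noise channels
share one pooled statistic since they are identically distributed; the
target is standardized with the g-channel statistics so predictions
de-normalize on the input's HU scale. A per-image alternative was
considered and rejected: global statistics keep the affine map identical
across slices, which the fixed-range metrics assume.

Training hyperparameters are exposed in `TrainConfig`; the canonical
defaults (Adam, lr 10⁻⁴, batch 16, 64×64 patches, 50 epochs) suit full-scale
runs and are declared non-canonical to any published protocol, whose
hyperparameter-optimized values are not public. The desk preset
(`desk_train()`: lr 2×10⁻³ cosine-decayed, batch 8, 16×16 patches,
80 epochs × 50 steps) was sized so the full four-arm experiment finishes in
roughly a quarter hour on one CPU core.

Evaluation computes SSIM, PSNR and VIF per test slice against the
standard-dose target and averages per arm; pairwise one-sided Wilcoxon
signed-rank tests (α = 1%) compare each arm with the unaugmented CNN10. The
cross-dose mode re-applies the trained checkpoints — no retraining — to
25%-dose inputs with low-dose-intensity realizations.

### What the desk experiment does and does not show

At desk scale (10 subjects split 6/2/2, 8 slices each, 75% eccentric, 16
test slices) the augmentation effect is real but small in absolute SSIM,
and its expression depends on optimization budget: noise channels are only
useful through *nonlinear, variance-adaptive* filtering, which emerges late
in training, while any quasi-linear use of independent noise channels
strictly hurts MSE. Within a CPU-minutes budget the N=3 arm expresses the
benefit robustly (uniformly positive per-slice improvements), whereas N=10
— ten times the noise-channel weights to recruit — remains within
run-to-run tolerance of the baseline rather than clearly above it. This
mirrors, in compressed form, the published observation that a few
realizations already capture most of the benefit; full expression of the
monotone trend up to N=10 requires training budgets (and data volumes)
beyond a desk-scale CPU run.

## Metrics

* **PSNR**: 10·log₁₀(peak²/MSE) with a *fixed* evaluation range of 2000 HU
  (covering the display windows relevant for soft tissue and lung), so
  scores are comparable across slices; identical images are flagged
  infinite, not raised.
* **SSIM**: mean local SSIM, 11×11 Gaussian window (σ = 1.5), K₁ = 0.01,
  K₂ = 0.03 on the same 2000 HU range (scikit-image backend).
* **VIF**: pixel-domain visual information fidelity — four Gaussian scales,
  Gaussian-scale-mixture variance partition, sensor-noise variance
  σₙ² = 2 on the 8-bit-equivalent normalized range; implemented in-package
  from the closed form (score 1 for a perfect copy; decreases under noise
  and blur; undefined for a constant reference).
* Metrics are computed over the full slice without a body mask.
* **Wilcoxon signed-rank, one-sided**: exact enumeration of the null for up
  to 25 nonzero differences via a dynamic program over doubled integer
  ranks (mid-ranked ties handled exactly; zeros dropped), normal
  approximation with continuity and tie correction beyond. Verified against
  independent brute-force sign enumeration and a second implementation.

## Numerical and degenerate-input conventions

NaN/Inf anywhere in images or sinograms is rejected at container
construction. HU below −1000 is a domain error for attenuation conversion.
All-zero metric differences make the signed-rank test undefined (error, not
silent p = 1). Training aborts with a diagnostic on NaN loss. Realization-
count mismatches at inference are errors, never silent truncation or
padding. Float32 is used for images, stacks and network weights; float64
for sinogram physics and metric accumulation.

## Known limitations

* 2D only; no cone-beam rows, no iterative reconstruction, no scatter or
  beam hardening.
* The noise model is pure Poisson counting noise with uniform I₀;
  electronic noise and detector cross-talk are excluded.
* Only the CNN10 family is bundled; deeper backbones enter through the
  augmentation contract but are not trained here.
* Desk-scale results are mechanism demonstrations under synthetic anatomy;
  absolute metric values are not comparable to clinical-data studies.
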