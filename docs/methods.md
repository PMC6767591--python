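# Methods

This note records the models the package implements, the numerical
conventions it commits to, and the reasoning behind the design choices
that were genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model and SNR objective

The steady-state spoiled-gradient-echo signal is
S(θ,TR,TE) = (1−E₁)sinθ/(1−E₁cosθ)·e^(−TE/T₂*) with E₁ = e^(−TR/T₁).
Relaxation defaults are the published in vivo values for perfluoropropane
at 3 T: T₁ = 12.4 ms, T₂* = 2.2 ms. For a fixed FOV, matrix and total
scan budget T_scan, the figure of merit is the relative SNR

SNR ∝ √(FOVₓFOV_yFOV_z·T_scan/(Nₓ²N_y²N_z²·TR·BW))·S(θ,TR,TE),

implemented as a single square root over the whole rational factor. The
grouping under the radical is a declared convention: since the geometry
factors are constant during any one optimization, regrouping them rescales
the whole surface uniformly and cannot move the argmax; only relative
values are meaningful.

### Timing model

For a nonselective block pulse, τ = (θ/360)/(γB₁) with γ(¹⁹F) =
40.05 MHz/T (overridable for other nuclei). The readout lasts 1/BW for BW
in Hz/pixel (Nₓ samples at dwell 1/(BW·Nₓ)), so

- TE_min = τ/2 + t_encode + (1/BW)/2,
- TR_min = TE + (1/BW)/2 + t_spoiler.

Real scanner gradient timing is vendor-specific and not public; the two
lumped overheads are therefore plain configuration with defaults
t_encode = 0.5 ms and t_spoiler = 1.0 ms. Consequently the optimizer's
printed optimum (40°, 450 Hz/pixel under defaults) is a property of this
hardware model, not a universal constant; the qualitative structure of the
surface (a single interior optimum, the sharp SNR loss just below the
optimal flip, the B₁ plateau above ~2 µT) is robust to these constants and
is what the acceptance tests assert.

### SAR model

Time-averaged deposition is modelled as SAR = C·B₁²·(τ/TR). No public
coefficient exists for the ¹⁹F chest birdcage, so the default C is
calibrated by assuming the reference in vivo protocol (B₁ = 4 µT, θ = 50°,
TR = 7.5 ms) operates exactly at the 10 W/kg local-torso limit. This is
an explicit calibration assumption — substitute a measured coefficient for
a real coil. TR is extended to max(TR_min, C·B₁²τ/limit), which puts a
binding point exactly on the limit.

### Grid search

Defaults: flip 0–90° in 1° steps, BW 10–1500 Hz/pixel in 10 Hz steps, B₁
fixed at 4 µT unless a grid is given (0.1 µT resolution suggested). Grid
points with zero bandwidth or B₁ get SNR 0. Ties break deterministically
toward smaller flip, then smaller BW, then smaller B₁ (first-maximum scan
order).

## Phase-encode sampling

**Elliptical shutter.** Signed k-space indices with the DC line at N//2
(the `fftshift` centre), semi-axes ⌊N/2⌋ per axis, boundary inclusive; an
axis of length 1 contributes zero. This is the standard 3D gradient-echo
shutter convention and retains exactly 592 of the 32 × 25 phase encodes of
the reference protocol. Note the consequence for symmetry: on even axes
the window is symmetric about the DC index (k → 2⌊N/2⌋ − k), not about the
geometric array centre.

**Poisson disc.** The literature names the pattern class, not an
algorithm, so the contract here is: greedy dart throwing (random candidate
order, accept at ≥ r from all accepted points) with the 8 × 7 centre block
always forced; r tuned by 25 bisection steps to approach the target count;
then random trim/fill (never touching the centre block) to hit
n = round(window/accel) exactly. Density is uniform — on a 32 × 25 matrix
a variable-density disc leaves too few samples at the k-space edge. All
randomness flows from one integer seed; identical inputs give bit-identical
masks. The readout axis is always fully sampled; undersampling acts on
(ky, kz) only.

## Reconstruction

Zero-filled reconstruction is the unitary centred inverse FFT (DC at
N//2), with optional symmetric k-space zero-padding for sinc interpolation
(intensity-rescaled so interpolation does not change the image scale).

CS reconstruction minimizes ‖y − DFm‖₂² + λ‖Ψm‖₁ by proximal gradient
descent:

- **Step size 1** is exact, not heuristic: with unitary F and a binary
  selection mask, DF has spectral norm 1.
- **Ψ** is an orthonormal Daubechies-4 decomposition (PyWavelets,
  periodization mode), depth 2, with per-axis zero-padding to a multiple
  of 2² and at least 28 samples so no band drops below the filter length.
  Deeper decompositions on the 25–32-point phase-encode axes would push
  coefficient counts below the filter support and reintroduce boundary
  artefacts, which is why "maximum possible depth" was rejected.
- **Cycle spinning:** one uniformly drawn 3D circular shift per iteration
  (seeded), applied before Ψ and inverted after Ψ⁻¹, approximating a
  translation-invariant transform and suppressing blocky artefacts.
- **Normalized λ:** data are scaled so the zero-filled reconstruction's
  99th-percentile magnitude is 1, making a given λ transferable across
  datasets; λ = 0.05 is the package default.
- **Iterations:** exactly 50 by default. Because the randomized shift
  changes the effective regularizer each iteration, the objective is
  mildly nonmonotone near convergence; the solver therefore returns the
  iterate with the lowest objective seen, and aborts with diagnostics if
  the objective ever exceeds 10× its initial value.
- Signal averages are combined by complex mean in k-space before
  reconstruction.
- Single receive channel: a volume (birdcage) coil has an essentially flat
  sensitivity, under which sensitivity-weighted multi-coil formulations
  collapse to the identity-sensitivity problem solved here. Multi-coil
  sensitivity estimation is out of scope.

λ selection retrospectively undersamples a fully sampled dataset,
reconstructs per candidate λ, and minimizes RMSE against the fully sampled
magnitude image over lung voxels only (default: voxels above half the 99th
percentile). Whether that RMSE should be computed on magnitude or complex
images is not settled practice; magnitude is implemented. On the synthetic
study data the minimizer lands at λ = 0.01 with 0.05 within ~10% of the
minimum RMSE — the choice is data-dependent, which is why the package
asserts only that the curve has an interior minimum.

## Phantom

The phantom emulates a breath-hold fluorinated-gas ventilation image on
the acquisition axes (x readout/superior–inferior, y right–left, z
anterior–posterior): two ellipsoidal lungs (semi-axes 0.33/0.16/0.30 of
the FOV, ~4.3 L total at default size; `lung_scale` cubes into volume to
emulate between-subject spread), a trachea descending to a carina with two
main bronchi (full signal, flagged by the airway mask so the exclusion
rule is exercised), seeded spherical zero-signal defects, and a
multiplicative low-frequency shading field of ±15% emulating coil
inhomogeneity.

The shading field is an *additive* combination of one low-order cosine per
axis, peak-normalized. This keeps the in-lung intensity deviation within
~2.5 standard deviations of its spread, so on a noiseless image the
mean − 3 SD threshold never clips genuine lung signal and ventilated
volume is recovered exactly — a property a peak-heavy field (e.g. a
product of cosines) does not have.

k-space simulation is the unitary centred FFT plus i.i.d. complex Gaussian
noise of per-channel σ per average; NSA averages are simulated literally
and combined by complex mean, so the effective noise is σ/√NSA and the
background magnitude image is Rayleigh with SD √(2−π/2)·σ/√NSA. Noise
calibration bisects σ (geometrically, fixed seed) until the measured ROI
SNR hits a target; the study regime targets SNR 11.7, the published cohort
mean.

What the phantom does **not** emulate: real thoracic anatomy and
partial-volume gradations at lung boundaries, T₂* decay during the
readout, B₀ inhomogeneity, motion, gas redistribution during breath hold,
and inter-breath-hold registration error. Agreement statistics on phantoms
are therefore far tighter than any in vivo cohort's (correlation ≈ 1,
limits of agreement a few tens of millilitres); passing tests demonstrate
the pipeline's internal consistency, not clinical equivalence.

## Metrics

- SNR = 0.66 × mean(signal ROI)/SD(noise ROI), using the printed
  two-decimal Rayleigh correction; `rayleigh_correction()` returns the
  exact √(2−π/2) ≈ 0.6551. ROIs are 4 cm discs on a coronal slice by
  default (spherical ROIs available). Zero noise variance is an error.
  Note that apparent SNR measured on a CS reconstruction is inflated:
  soft-thresholding suppresses background noise, shrinking the noise-ROI
  SD without a corresponding gain in true sensitivity.
- Ventilated volume: threshold = mean − 3·SD of the image over a
  statistics region, ventilated = voxels ≥ threshold minus the airway
  mask, volume in litres. The region over which the source protocol took
  "mean signal" is ambiguous; the default here is voxels above 50% of the
  99th-percentile magnitude. A looser cut (e.g. 10%) admits enough of the
  Rayleigh background tail at SNR ≈ 12 to drag the mean down and the SD up
  until the threshold falls below the noise floor and the measurement
  degenerates to the whole FOV — the 50% default keeps the statistics on
  lung signal down to single-average SNR (~5). The region is a parameter
  wherever it matters.
- VDP = 100·(total − ventilated)/total with total lung volume taken from
  the phantom ground truth (standing in for the ¹H-derived lung
  segmentation of a real study).
- Bland-Altman: bias = mean paired difference, limits of agreement =
  bias ± 1.96·SD (sample SD), Pearson correlation, paired t statistic
  bias/(SD/√n) with a two-sided p from the t distribution.

## Problem sizes and determinism

The default study grid is 64 × 32 × 25 (the in vivo phase-encode matrix
with a halved readout axis), chosen so a full eight-phantom agreement
study with calibration, reconstruction at three accelerations and a λ
sweep completes in about a minute; full-size phantoms are available by
passing the acquisition matrix. Every stochastic component — phantom
defects, shading, noise, pattern generation, cycle-spinning shifts — is
driven by explicit integer seeds, and the pipeline manifest records all
seeds and array hashes so runs are reproducible bit-for-bit.

## Known limitations

- The SAR coefficient and gradient-timing overheads are calibration
  assumptions; optimizer outputs shift with them and should be re-derived
  per site/coil.
- The CS solver is plain ISTA; it is deterministic and adequate at these
  matrix sizes but slower-converging than FISTA/ADMM variants.
- Poisson-disc generation is O(n²) dart throwing — fine for phase-encode
  grids, not meant for megapixel masks.
- Thresholded VV degrades gracefully but measurably below SNR ≈ 5; no
  claim is made for severely hypoventilated cohorts where defect and noise
  intensities overlap.
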