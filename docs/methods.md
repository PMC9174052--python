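# Methods

This note documents the models, parameter choices and numerical
conventions behind `qsmpipe`, and what the built-in phantom validation
does and does not demonstrate about real data.

## Forward model and phantom simulator

A susceptibility distribution χ(r) (ppb) shifts the static field by the
fraction δ(r) given, in k-space, by the unit dipole response
D(k) = 1/3 − (k·b̂)²/‖k‖². Discrete frequencies are physical
(k_i = n_i/(N_i·Δx_i)), so anisotropic voxels (default 0.8 × 0.8 × 3 mm)
are handled without resampling. Two conventions are fixed here:

* **D(0) = 0.** The forward field is mean-free, consistent with QSM
  estimating *relative* susceptibility only; absolute offsets are later
  fixed by CSF referencing.
* **Evenness.** On even-sized grids the ±Nyquist frequencies alias onto
  one bin, which breaks D(k) = D(−k) for oblique field directions; the
  kernel is symmetrized (average of D(k) and D(−k)) so real volumes stay
  real under filtering. For the default +z field direction this is a
  no-op.

The forward convolution is evaluated on a grid zero-padded 2× per axis
and cropped, suppressing circular wrap-around (the padded box edge is
why the "uniform χ gives zero field" identity is exercised unpadded).

The phantom places ellipsoidal regions (16 subcortical-style structures,
a ventricle at χ = 0, a white-matter compartment at −30 ppb, one lesion)
inside an ellipsoidal brain. The complex signal per coil c and echo n is

    S = M ρ_c exp(−TE_n/T2*) exp(i(θ_c + 2π γ̄ B₀ δ·10⁻⁹ TE_n)) + ε,

with γ̄ = 42.576 MHz/T, mono-exponential T2* decay, smooth low-order
polynomial coil magnitudes ρ_c, and complex Gaussian noise ε. All
randomness derives from a single seed; identical specs reproduce
identical bytes.

**Coil phase offsets.** Simulated offsets are a random constant plus a
near-linear spatial trend (scaled so a full 200 mm head would span about
π peak-to-peak) plus a weak curved component (0.1 rad SD, 25 mm
correlation length). The physical scale matters: coil sensitivity varies
over centimetres regardless of the simulated matrix size, and tying
offset roughness to the grid instead would make small desk-scale
phantoms unrealistically hostile to any smoothing-based offset
estimator. The flip side is a documented limitation: the channel
combination's offset-smoothing step (Gaussian, σ = 4 in-plane voxels,
scaled by voxel anisotropy through-plane) is close to unbiased for such
smooth offsets; offsets with strong structure at the few-voxel scale
would bias the combined phase, and the phantom does not probe that
regime.

## Reconstruction chain

**Channel combination.** The Hermitian product Σ_c S_{c,2}·conj(S_{c,1})
cancels the per-coil offsets; its unwrapped angle, extrapolated linearly
to TE₁ (zero phase at TE = 0), predicts the field-induced phase at echo
1. Removing it from the echo-1 data exposes each coil's offset, which is
smoothed wrap-safely on the unit phasor (mask-normalized so the brain
edge does not blend in zeros) and subtracted before a complex sum with
|S| magnitude weighting (switchable to |S|²). Combined magnitude is
root-sum-of-squares, invariant to any phase manipulation.

**Laplacian unwrapping.** φ = ∇⁻²[cos φ·∇²sin φ − sin φ·∇²cos φ] with
both Laplacians spectral; the inverse zeroes the DC bin and the output
mean over the mask is set to zero (absolute phase is not recoverable).
Two numerical details carry most of the accuracy: (1) the volume is
mirror-padded to twice its size before the FFTs, making the implicit
periodic extension continuous and suppressing boundary ringing
(interior RMS error ≈ 0.007 rad on a 6π-span ramp); (2) the phase is
zeroed outside the mask *before* the transform — zero-magnitude voxels
carry uniform random phase, and because the inverse Laplacian is global,
leaving them in place injects smooth errors into the brain interior (in
measurement this was a ~13× noise amplification and the single largest
error source in the whole chain).

**Phase reliability and mask lineage.** Per echo, each voxel's
reliability is 1 − g/π with g the mean absolute wrapped phase difference
to its six face neighbours; thresholds 0.7 (echo 1) and 0.6 (echo 2)
refine the input brain mask (Mask1 → Mask2) and again after background
removal (→ Mask3), removing air-interface voxels whose steep phase
corrupts the inversion.

**Echo combination.** Unwrapped phases are merged with weights
TE_n·e^(−TE_n/T2*)/Σ (T2* fixed at 40 ms), ≈ (0.380, 0.620) at
9.4/20 ms. Since phase is linear in TE, the sum equals the phase at the
effective echo time TE_eff = Σ w_n TE_n ≈ 15.97 ms, which the ppb
conversion uses; the weighted sum operates on phase, not frequency, with
the TE bookkeeping compensating.

**V-SHARP.** Background sources are annihilated via the spherical mean
value property of harmonic functions. Sphere radii run from 12 mm down
to the largest voxel dimension in 1 mm steps; each voxel keeps the
high-pass result of the largest sphere fitting inside the mask around
it, and the output mask is the smallest-sphere erosion. Deconvolution
uses the largest-radius filter with TSVD truncation at 0.05
(configurable). The operation is linear and, on the phantom, removes
≥ 98% of an external source's RMS while preserving an internal dipole
field at r > 0.95.

**Dipole inversion.** Stage (a) solves
argmin‖W(F⁻¹[D F[χ]] − δ)‖₂ by LSQR (max 50 iterations, tolerance
1e−3), with W the normalized combined magnitude inside the mask and —
important for accuracy — χ *supported on the mask only*: an
unconstrained solution lets susceptibility leak outside the brain and
systematically underestimates ROI values. Stage (b) marks the
ill-conditioned cone |D| < 0.1. Stage (c) estimates the streaking
component as the image whose spectrum lives in that cone and whose
spatial gradients best match the first-pass solution under inverted
gradient-magnitude weights w = 1/(1 + |∇χ₀|/mean|∇χ₀|) (LSQR, 30
iterations), and stage (d) subtracts it. The TKD inversion
(χ = F⁻¹[F[δ]/D_t], D_t = sign(D)·max(|D|, 0.2)) serves as an
independent cross-check; the two agree at r > 0.99 inside phantom ROIs.
Inversion runs on the native grid (the field is already masked and the
brain does not touch the box edge at the default geometry).

**CSF referencing** subtracts the median χ over the ventricle mask —
median for robustness to partial volume; idempotent and rank-preserving.

## IDPs

Per modality (χ, T2*) the stage emits 18 IDPs: 16 subcortical medians
(masks eroded per axial slice with a 3 × 3 8-connected kernel;
substantia nigra not eroded but refined once by excluding χ < 0 voxels —
the structure is reliably paramagnetic; the refinement is skipped for
T2* input where negativity carries no meaning), the lesion contrast
(lesion mean minus normal-appearing white-matter median — a global
reference offset cancels), and the same contrast with lesion volume
regressed out (simple least squares with intercept, cohort-level).
T2* comes from the two-point fit T2* = ΔTE/ln(M₁/M₂), with
non-decaying voxels flagged invalid. The macroscopic field-gradient
confound is the ROI median of the absolute through-slice finite
difference of the total (pre-V-SHARP) field, intended as a regressor for
T2* IDPs only, whose thick-slice estimates are biased by intra-voxel
dephasing.

## Association statistics

IDP and phenotype vectors are cleaned by the 6×MAD rule (MAD unscaled —
the rule is stated in MAD units; a 1.4826 normal-consistency factor is
switchable), then quantile normalized: ranks (average for ties) map
through Φ⁻¹ at plotting positions (rank − 0.5)/m, after which the vector
is centered and rescaled to unit sample SD. The rescaling is deliberate:
finite-m normal quantiles have sample SD below 1 (≈ 0.97 at m = 100),
while the procedure is defined as producing mean 0 and SD 1. Confound
regression always includes an intercept, drops collinear columns with a
warning, and is refit per column on that column's complete rows, so each
association carries its own degrees of freedom; associations use
pairwise-complete Pearson r with two-sided t-based p (minimum 40
complete pairs in the scan, mirroring the phenotype-inclusion rule).
Bonferroni control is applied as a −log₁₀P threshold
(−log₁₀(α/m) = 7.10 for m = 629,460 at α = 0.05; the genome-wide
variant is 7.5 + log₁₀(36) = 9.06), with Benjamini–Hochberg step-up as
the FDR alternative. Voxel-wise association maps re-run the full
per-vector preprocessing per voxel; the aging-style contrast is a
voxelwise difference of group means.

## Scaled-down validation conditions

Desk-scale problem sizes, chosen as the package's reference conditions:

* **Parameter recovery**: 64 × 64 × 48 grid, 32 coils, magnitude
  SNR ≈ 50, regions at +100/+60/−50/0 ppb placed deep — as subcortical
  nuclei are — so they survive the 12 mm V-SHARP erosion, 3 seeds.
  Recovered medians land within ~10% with exact sign and rank order.
* **Repeat-imaging cohort**: 50 participants at 48 × 48 × 32 with the
  maximum SMV kernel scaled to the smaller head (≈ 7.7 mm), 8 coils;
  per-participant region χ drawn with 25% between-subject spread
  (population-imaging scale for deep grey matter over a 45–82-year age
  span); anatomy fixed across the two scans, acquisition noise and coil
  profiles redrawn. Cross-scan IDP correlation for the iron-rich
  structures (pallidum, substantia nigra) exceeds 0.99 under these
  conditions.

What passing these tests shows: the chain is internally consistent,
unit-correct, and stable under realistic noise and coil conditions at
desk scale. What it does not show: robustness to real anatomy
(non-ellipsoidal brains, veins, calcifications), motion, flow, chemical
shift, imperfect masks or registration — none of which the phantom
emulates — nor any cohort-level biological finding, which requires real
population data.

## Degenerate inputs and tie-breaks

Zero-MAD vectors skip outlier removal with a warning; constant
covariates yield centered residuals; empty ROIs after erosion or
refinement produce missing values, never exceptions; empty CSF masks,
single-echo input, or masks thinner than the smallest sphere raise typed
errors. LSQR hitting its iteration cap returns the best iterate with a
logged warning (the residual is non-increasing by construction). Ranks
tie-break by averaging. A p-value of exactly zero is reported at the
smallest positive float so −log₁₀P stays finite.
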