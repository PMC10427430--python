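# Methods

## Physical model

Each scene pixel is modelled as a depolarizer–retarder sandwich acting
on the probe state:

    S_out = brightness · M_Δ(a, b, c) · M_R(δ, θ) · S_illum

with M_Δ = diag(1, a, b, c) a diagonal depolarizer and M_R a linear
retarder of retardance δ ∈ [0, π] and fast axis θ. Diattenuation is
omitted from the default scene model (tissue diattenuation is typically
very small) but is fully supported by the algebra and the decomposition,
and the Mueller-chain tests exercise it with |D| ≤ 0.2. The component
order M_Δ·M_R matches the order assumed by the polar decomposition, so
simulation and decomposition are mutually consistent by construction.

Conventions (the source system never states its own): S₃ > 0 is
right-circular; the retarder matrix at θ = 0 maps (S₂, S₃) by a rotation
of +δ, so right-circular light through a quarter-wave plate at θ = 0
emerges at +45° linear. All angles are radians internally; degrees
appear only at the CLI. Signed quantities (fast axis, S₃ sign) are
convention-internal; every reported magnitude (A_δ, A_dep, T_dep, D) is
convention-free.

The default illumination is the measured probe state
(1.000, −0.002, 0.028, 0.999) — almost pure right-circular with
residual linear polarization of degree 0.028. Analytic identities such
as A_δ = |sin δ| hold exactly only for the ideal state (1, 0, 0, 1);
with the measured state the reconstructed retardance shifts by at most
the residual dolp (≈ 0.03, verified by test). Exact round-trip tests
therefore use the ideal state; realism tests use the measured one.

## Snapshot (DoFP) forward model and reconstruction

A pixel under a micro-polarizer at angle α records

    count = gain · exposure · ½(S₀ + S₁ cos 2α + S₂ sin 2α) + offset

followed by optional Poisson shot noise, Gaussian read noise, clipping
and round-half-up quantization (default bit depth 8). The super-pixel
layout is 90° 45° / 135° 0° in reading order, with pixel (0, 0) the 90°
site; other sensors are supported via a layout permutation. In
depolarization mode a quarter waveplate is inserted in front of the
mosaic; its fast axis is fixed at 135° so that the 0° sub-image
analyses right-circular light and S₃ = I₀ − I₉₀ is positive for a
right-circular return (the sign is conventional; only |S₃| enters the
depolarization map).

Fixed-pattern correction inverts the per-pixel gain/offset model. The
calibration estimator uses flat-field frames of uniform unpolarized
illumination: each pixel's gain is its dark-subtracted mean count
divided by the mean over all same-orientation pixels — gains are
identifiable only up to one scale per orientation, which cancels in the
ratio-based maps.

Demosaicing interpolates each orientation's 2-strided lattice with the
normalized 3×3 bilinear kernel; native sites are reproduced exactly and
affine intensity fields are interpolated exactly in the interior.
Boundaries use edge-replicated support; quantitative tests exclude a
2-px border, and round-trip guarantees hold ≥ 2 px from region
boundaries (demosaic averaging mixes regions at edges — a real effect,
not an artefact).

Known estimator bias, kept deliberately: for a strongly retarding,
weakly depolarizing medium the circular-ratio map overestimates
depolarization, A_dep = 1 − |cos δ| even when none is present, because
the emergent light still carries linear components. The test suite pins
this curve across δ ∈ {0, π/6, π/4, π/3, π/2}. Likewise A_δ is a
(slightly) biased estimator under shot noise (Rician-type lift of
√(S₁²+S₂²)); at ~10³-count signals the bias is below the Monte-Carlo
resolution of the patch-mean test.

Exposure masking follows the pre-gamma intensity reference: invalid
where S₀/2 exceeds 95% (overexposed) or falls below 3% (underexposed)
of 2^bitdepth − 1. Validity is carried as a mask, never as sentinel
values; pure green is applied only at render time. Gamma (default 1/2)
and unsharp sharpening (radius 2 px, amount 0.8) are display-only and
excluded from all quantitative paths.

## Mueller polarimeter and decomposition

Generator states are built as M_qwp(π/2, θ)·M_pol(0)·(1,0,0,0)ᵀ for
θ ∈ {−45°, 0°, 30°, 60°}, renormalized to S₀ = 1; analyzers are the
first rows of the six analyzer element matrices. The 24×16 forward
operator (rows a_j ⊗ w_k, analyzer-major) has condition number ≈ 6.3
for these angles; reconstruction is one batched least-squares solve
(pseudo-inverse), bit-identical to a per-pixel loop and exact to 1e−10
on noise-free data. The estimator choice (least squares over all 24
measurements rather than a 16-measurement direct inversion) is the
natural contract for an over-determined acquisition. Instrument
matrices are exact by construction in simulation; a nominal-vs-true
perturbation can be emulated by passing a perturbed instrument to the
reconstruction, treating calibration error as a noise setting.

The polar decomposition factors the m₀₀-normalized matrix as
M_Δ·M_R·M_D: the diattenuator from the first row (3×3 block
√(1−D²)·I + (1−√(1−D²))·D̂D̂ᵀ), then m_Δ = ±√(m′m′ᵀ) via symmetric
eigendecomposition with the sign of det m′, then m_R = m_Δ⁻¹m′.
Eigenvalues below 1e−12 switch to the pseudo-inverse branch and set a
per-pixel `degenerate` flag; the depolarization scalars remain defined
there. R is taken on the principal branch [0, π], so A_δ = sin R is
non-injective above π/2 — inherent to the definition, not a defect.
|D| is clipped just below 1 to keep M_D invertible on (unphysical)
boundary inputs.

## Scene simulator

Two stock scenes emulate the study's test objects:

* **M phantom** — an "M"-shaped uniform retarder (default δ = π/3, one
  fast axis drawn from the seed) over a purely depolarizing background
  (default factor 0.15), brightness-matched so intensity contrast is
  zero by construction. Its synthetic white-light image is colourless
  grey with seeded sensor noise (σ = 0.004), making the retardance/colour
  contrast ratio large by design of the physical phantom, not of the test.
* **Larynx scene** — normal mucosa δ ~ U(50°, 80°), circular
  depolarization factor c ~ U(0.1, 0.4) (strongly depolarizing);
  cancer δ ~ U(0°, 15°), c ~ U(0.5, 0.8) — low retardance *and* low
  depolarization. Linear factors follow a = b = 0.5 + 0.5c (circular
  states decay faster than linear in backscattering tissue). Blood
  patches (brightness 0.02) fall below the underexposure threshold;
  specular patches (brightness 10, partially depolarized with factor
  0.7 from surface scatter) saturate both analyzer channels and trip
  the overexposure threshold in both modes. The fibre fast-axis field
  is spatially smooth (Gaussian correlation 6 px): real collagen
  orientation is correlated, and i.i.d. axes would cancel S₁/S₂ under
  demosaic averaging. The white-light image adds low-frequency colour
  mottle (amplitude 0.05, correlation 20 px) so the colour cue overlaps
  between classes at the unit level, as in white-light endoscopy of
  early lesions.

Class δ and c values are stated defaults chosen to reproduce the
qualitative tissue findings (no numeric per-tissue retardance values
exist to match); downstream claims are therefore ordering and
significance properties, not absolute tissue values. The two-layer
epithelium/lamina-propria picture is emulated phenomenologically
through these distributions; polarized Monte-Carlo light transport,
wavelength dependence and surface-geometry effects are out of scope.

All randomness flows from one seed through named substreams
(`SeedSequence([seed, crc32(stage)])`), so adding a stage never shifts
another stage's draws and same-seed regeneration is bit-identical.

## Analysis layer

RMS contrast uses the sample standard deviation (1/(n−1) divisor) on
[0, 1]-scaled channels; the median form reduces to |m₁−m₂|/√2. Grid
units (default 16×16 px; 30×30 for strip sampling) tile from the
region's bounding-box corner; a unit is dropped if it is not fully
inside the region or contains ≥ 1 exposure-invalid pixel — a
conservative, configurable exclusion rule. Unit means are treated as
independent samples. The Mann–Whitney U test is two-sided, exact for
both n ≤ 20 without ties, otherwise normal-approximate with tie
correction (the method used is reported).

The classifier is a linear-kernel SVM (C = 1.0) on features
z-standardized on the training split, with a seeded 0.6/0.4
train/test split (stratification optional, off by default; a
single-class split is resampled with the next seed and warned about).
ROC/AUC are computed on the test split by sweeping the decision
function; sensitivity/specificity are reported at decision value 0.
AUC sensitivity to C ∈ {0.1, 1, 10} is a test-suite concern, not part
of the contract.

The retardance index thresholds hue on the closed interval
[0.05, 0.45] (golden/dark-green interference colours of birefringent
fibres), computed before any gamma adjustment, and averages the
luma-weighted grey level (0.2989, 0.5870, 0.1140) on the 0–255 scale;
an empty mask yields index 0.

## Problem sizes and numerical choices

Simulated scenes default to 256×256 (512×512 runs in well under two
minutes end to end on one CPU); the strip-classification analogue uses
360×660 so that three 30-px strips yield 22 adjacent units each (66
samples). The Mueller recovery suite uses 1000 random media.
Physicality tolerance is 1e−9 for noise-free algebra; decomposition
degeneracy threshold 1e−12 on eigenvalues of m′m′ᵀ; quantization is
clip-then-round-half-up. S₀ = 0 pixels are marked invalid rather than
producing NaNs.

## Limitations

* The simulator validates the reconstruction algebra and statistics; it
  does not model radiative transport, so passing tests demonstrate
  correctness of the pipeline, not clinical performance on tissue.
* Snapshot-path and Mueller-path retardance agree exactly only for
  non-depolarizing, non-diattenuating media under ideal circular
  illumination; depolarization with a = b scales the snapshot estimate
  by a (the simplified partial-Stokes approach is not as rigorous as
  full Mueller polarimetry).
* The hardware calibration procedures of the original instruments
  (micro-polarizer diattenuation calibration, eigenvalue calibration)
  are replaced by the gain/offset model and exact-by-construction
  instrument matrices respectively.
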