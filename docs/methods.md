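# Methods

This note documents the models, algorithms and numerical choices behind
`orgpet`, what the synthetic data do and do not emulate, and the known
limitations.

## Digital phantom

The phantom is the unit everything else operates on: a 3-D SUV-scaled grid
(default 40×40×48 voxels at 4.07 mm isotropic — the pixel spacing of the
emulated reconstruction) holding a warm uniform background (1 SUV) and one
or more hot lesions.

**Lesion model.** Each lesion is a Gaussian radial profile with
σ = radius/2, i.e. the stated radius is the 2σ point (≈ 13.5% of the peak
excess remains at r = radius). The default lesion (radius 16 mm, peak 8 SUV)
approximates a pancreatic primary of ~14 ml at moderate FDG avidity. Two
heterogeneity components make the lesion more than a smooth blob:

* a **necrotic core** — a negative Gaussian blob whose depth is set so the
  un-blurred object equals the requested core SUV (default 2.5) at the core
  center, offset from the lesion center;
* an **intra-lesional texture field** — a seeded, correlated (10 mm
  correlation length), zero-mean multiplicative random field with 30% SD
  applied to the lesion excess. Real PDAC lesions show regional and
  multifocal uptake variation; a smooth blob would have almost no texture
  for the radiomic features to measure.

**Point-spread function.** The reconstruction PSF is Gaussian with 3.0 mm
FWHM. Because a Gaussian blob convolved with a Gaussian PSF is again
Gaussian (variances add; the peak scales by (σ_l²/(σ_l²+σ_p²))^{3/2}), the
PSF is folded in *analytically* and the result sampled at voxel centers. At
4.07 mm voxels the PSF σ is only 0.31 voxels, where a discrete convolution
kernel degenerates to a near-delta; the closed form avoids that
discretization error entirely. The texture field is rendered at voxel scale,
where the sub-voxel PSF is negligible by the same argument. A test verifies
the rendered peak against an independent 4× resolution numerical-convolution
oracle to 2%.

**Breathing waveform.** The surrogate signal is the cos-power model
z(t) = A·cos²ⁿ(πt/τ): amplitude A (default 15 mm cranio-caudal), period τ
(default 4 s), and exponent n controlling the end-expiration dwell
(default n = 2; the signal spends most of each cycle near baseline, which is
precisely why amplitude gating is data-efficient). Optional per-cycle
amplitude jitter (seeded Gaussian fraction, default 5%) and a linear
baseline drift emulate irregular breathing. Sampling must satisfy
dt < τ/8; the default acquisition is 150 frames of 0.4 s over 60 s.

**Acquisition model.** Frames stand in for list-mode data: frame k is the
truth with the lesion foreground (truth minus background) rigidly translated
along the cranio-caudal axis by the instantaneous amplitude, using exact
single-axis linear interpolation (implemented by array slicing; it conserves
foreground mass to machine precision for shifts inside the grid and moves
the intensity centroid by exactly the commanded shift). Poisson noise on
counts = noise_scale × SUV (default 12.5 counts/SUV per frame, putting the
per-frame coefficient of variation near 10% at the lesion peak) is applied
per frame. Ungated and gated images are voxelwise **means** over (subsets
of) frames, so both live on a common SUV scale regardless of how many
frames are kept.

What the frame proxy does *not* emulate: sinogram/list-mode physics,
scatter and randoms, attenuation, TOF, iterative reconstruction, deformable
motion, and — importantly — count-matched statistics between gated and
ungated images (the gated mean uses ~35% of the frames, so it is noisier by
~√(1/0.35); the emulated clinical protocol instead matches the data volume
of both reconstructions). Equal-duration frames also equate time fraction
with data fraction, so duty cycle is measured over frames.

## Optimal amplitude window

Given n amplitude samples and duty d, the gating contract is: the narrowest
closed interval [L, U] with both endpoints at attained sample values
containing at least k = ⌈d·n⌉ samples; ties in width are broken toward the
smallest L (end-expiration, the physiologically stable phase). The
production algorithm sorts the amplitudes and slides a window of k order
statistics (O(n log n)); for at-least-k coverage the optimum is always
attained at sample values, so this search is exhaustive over the candidate
set. An independent O(n²) brute-force search over all ordered sample-value
pairs ships in the package as a test oracle; a 100-trace randomized test
asserts exact width equality, including heavily tied (quantized) traces.

## Segmentation

The metabolic tumor volume is the 40% SUVmax isocontour: threshold =
fraction × max over (seed region minus exclusions), mask = the 26-connected
component of above-threshold voxels containing the maximum voxel. The
reference maximum is computed *after* exclusion subtraction so adjacent
physiological uptake (duodenum, biliary stent) cannot set the threshold.
26-connectivity mirrors the texture-matrix neighborhood. In synthetic runs
the "manual annotation" is emulated deterministically: the bounding box of
the truth lesion foreground, extended along the motion axis by the maximal
displacement (an annotator outlines the motion-smeared lesion on the blurred
image), dilated by 2 voxels. SUVmax and the threshold are recomputed per
reconstruction (ungated and gated VOIs are delineated independently).

## Feature panel

All texture features are computed on the VOI discretized to a fixed **count**
of 255 equal-width bins over the in-VOI min–max range (level =
⌊(v−min)/width⌋+1, maximum mapped to the top bin; a constant VOI maps to
level 1). Fixed-count relative binning makes every texture feature invariant
to adding a constant to all in-VOI intensities (verified by a property
test).

* First order: population Variance/STD, Skewness m₃/m₂^1.5, Kurtosis m₄/m₂²
  (non-excess: a normal sample gives 3), histogram Entropy (bits) and Energy
  over the 255-bin histogram. Zero-variance VOIs return 0 for
  skewness/kurtosis rather than erroring.
* GLCM: 13 unique offsets of the 26-neighborhood at distance 1, symmetrized
  per direction, features computed per direction and averaged (unweighted)
  over non-empty directions: Contrast, Dissimilarity, Homogeneity.1
  (inverse difference), Homogeneity.2 (inverse difference moment),
  Correlation (returned as 1 for a single-level VOI), Joint/Sum/Difference
  entropies from the joint, p_{x+y} and p_{x−y} distributions.
* GLRLM: maximal equal-level straight runs per direction (runs break at the
  VOI border), seven standard run-length features, direction-averaged. Run
  lengths are found by a vectorized forward-extension pass.
* GLSZM: 26-connected equal-level zones (single matrix, stored sparse as
  (level, size, count) triplets), nine standard size-zone features.

The `.1/.2/.3` suffixes on the three GLCM entropy names are deliberate: they
reproduce the exact column headers used in the output tables of the emulated
analysis toolchain, so downstream tables keep column-name compatibility.

Every one of the 35 features is checked against an independently coded
literal-definition oracle (explicit loops, dictionaries, flood fill) on 50
random VOIs to 1e-9 relative, plus analytic limits (constant VOI,
checkerboard, single runs/zones) and property tests (permutation invariance
of first-order features with a texture counterexample; intensity-shift
invariance).

## Survival layer

* **Paired comparison**: two-sided Wilcoxon signed-rank via scipy, zero
  differences dropped, exact null for ≤ 25 non-zero pairs, normal
  approximation with continuity correction above. A Monte-Carlo test
  confirms type-I error calibration at α = 0.05.
* **Cox model**: univariate, on standard-scaled features (population SD), so
  the HR is per 1 SD. The partial likelihood uses Efron tie handling and is
  maximized by Newton–Raphson with step halving, convergence at
  |score| < 1e-8, 100-iteration cap, steps clipped to ±2 to tame the first
  iteration. Monotone likelihood (|β| > 10) is flagged as separation; a
  constant covariate as degenerate; < 10 events warns. The solver is
  cross-checked against lifelines' CoxPHFitter, against a dense grid search
  of the partial likelihood on small cohorts, and by a 200-replicate
  parameter-recovery simulation (planted log-HR 0.5, n = 300, 20% censoring:
  unbiased mean and ≥ 90% CI coverage).
* **Log-rank / KM**: Kaplan–Meier curves and the two-group log-rank test
  come from lifelines; an internal vectorized log-rank (hypergeometric
  moments) powers the cutoff search and is verified against lifelines, a
  hand-computed toy example, and the 1-df chi-square law under permutation.
  For a binary covariate with distinct event times the Cox score test at
  β = 0 equals the log-rank chi-square (asserted to 1e-6).
* **Optimal cutoffs**: maximally selected log-rank statistics. Candidates
  are the unique feature values between the 10th and 90th percentiles; both
  groups must have ≥ max(5, 10% of n) subjects; ties go to the smaller
  cutoff. The reported p-value is the naive log-rank p — it is
  anti-conservative under maximal selection, no multiple-testing correction
  is applied anywhere in the table (the emulated analysis applies none
  across its 70 tests), and the docstrings say so.
* **Synthetic survival**: exponential event times with proportional hazards
  on chosen standardized features, baseline λ₀ = ln2/40 per week (40-week
  median at null — the emulated cohort's median overall survival), and
  independent uniform censoring whose upper bound is solved (Brent) so the
  expected censoring fraction hits the target (default 20%).

## Cohort pipeline

Each synthetic subject draws lesion peak (log-normal, 20% SD around 8 SUV),
lesion radius (±2 mm around 16 mm), and motion amplitude (±3 mm around
15 mm) from an independent RNG substream seeded by (global seed, subject
index), so a subject's data are independent of cohort order and size. Per
subject: phantom → 150-frame acquisition → ungated (all frames) and gated
(35% duty) means → per-reconstruction 40% isocontour VOIs → 35-feature
vectors. Cohort outputs: tidy features table, per-feature paired Wilcoxon
table, survival times generated from the planted standardized features
(default: log-HR 0.5 on the gated Sum Entropy), per-feature ×
per-reconstruction Cox HRs and optimal cutoffs, and a manifest (config,
seed, versions, config hash) from which every output is regenerable. CSV
floats are written at 9 significant digits; a fixed seed reproduces outputs
byte-for-byte.

Default cohort size is 69 subjects (matching the emulated study); the test
suite and acceptance script run 20–50 subjects to keep runtimes in minutes.

## What passing tests show — and what they do not

The phantom reproduces the *mechanism* under test: end-expiration dwell
makes a 35% duty cycle fit in a ~2 mm amplitude window, and undoing motion
blur raises single-voxel and mean uptake while shrinking the isocontour
volume. These directions are asserted over 50 seeded subjects with paired
Wilcoxon significance.

Two directional claims about real lesions are *not* reproduced by this
phantom, deliberately left as documented limitations rather than tuned into
existence:

* **First-order entropy (and the GLCM entropies) decrease on gated
  phantoms.** With 255 fixed-count bins and VOIs of ~100–300 voxels, nearly
  every voxel occupies its own histogram bin, so entropy tracks
  log₂(voxel count) — and the gated VOI is always smaller. On patient data
  entropy increases with gating because motion correction reveals genuinely
  multifocal uptake structure; rigid translation of a static lesion cannot
  create structure that was not rendered.
* **Skewness and kurtosis changes are geometry-dependent** (~50/50 across
  seeds here), for the same reason.

Conclusions about those specific features on real data should not be drawn
from this phantom; conclusions about SUVmax/SUVmean/MTV directions, the
gating optimality, the feature definitions, and the survival statistics are
fully supported by the oracle and property tests.

## Numerical details worth knowing

* Gating duty k = ⌈duty·n⌉ with a 1e-12 guard against float fuzz on exact
  multiples; closed-interval inclusion on both window limits.
* The phantom validates that lesions (and, at acquisition time, the shifted
  foreground support at a 1e-12-relative threshold) stay ≥ 2 voxels inside
  the grid; violations raise rather than clip.
* Degenerate inputs return flagged identities instead of crashing the
  pipeline: constant VOI → entropies 0, Energy 1, Correlation 1; constant
  feature → scaled zeros with a warning; all-zero Wilcoxon differences →
  p = 1 flagged.
* Images travel as NIfTI-1 (RAS, mm spacing in the header, axis 2
  cranio-caudal), traces as `time_s,amplitude_mm` CSV, configs as YAML that
  round-trips losslessly.
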