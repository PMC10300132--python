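# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of froipipe. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Forward model

A voxel's time series is

    y(t) = baseline + Σ_c a_c(v) · (boxcar_c ⊛ h)(t) + drift(t) + ε(t)

where `a_c(v)` is the planted amplitude map of condition `c`, `h` the HRF,
drift a random combination of slow cosines and `ε` white Gaussian noise.
Two deliberate couplings make the generator exactly invertible by the
analysis in the noiseless limit:

* **Convolution.** The simulator and the design-matrix builder share one
  code path: boxcars are laid on a fine grid (dt = TR/16, fractional onsets
  kept), convolved with the peak-normalised difference-of-gammas kernel and
  sampled mid-TR. Noise-free simulation followed by OLS therefore returns
  the planted amplitudes to < 1e-8 (asserted in the tests).
* **Drift.** Simulated drift coefficients are drawn on the same
  discrete-cosine basis (periods > the 128-s high-pass cutoff) the GLM uses
  as drift regressors, so by the Frisch–Waugh theorem drift cannot bias
  task betas. Real scanner drift is of course not exactly band-limited;
  this is a generator idealisation, chosen so that drift handling is
  testable as an exact contract rather than approximately.

## Haemodynamic response

`h(t) = Γpdf(t; δ_p/σ_p, σ_p) − ρ·Γpdf(t; δ_u/σ_u, σ_u)`, normalised to
unit peak. Human defaults δ_p = 6 s, δ_u = 16 s, σ = 1 s, ρ = 1/6, 32-s
support (the canonical double gamma, peaking near 5 s). The dog preset sets
δ_p = 3.5 s so the sampled peak lands 2.5 s earlier — the midpoint of the
2–3 s advance reported for dogs. The exact fitted canine parameters are
site- and cohort-specific, so they are an exposed configuration default,
not a reproduction target.

## Motion, FD and scrubbing

Motion traces are sums of three slow sinusoids per axis (default wander
0.02 mm translation / 5e-4 rad rotation) plus sustained step displacements
("spikes") at random scans; a step produces exactly one framewise
displacement exceedance, which makes scrubbing counts predictable from the
spike specification. FD uses the displacement-sum convention with rotations
converted to arc length at a head radius of 50 mm (human) or 30 mm (dog; a
smaller head, not stated in the source protocol — chosen once here). Spike
rates default to 8% of scans for dogs and 1% for humans, mirroring the
reported scrubbed fractions. Scrubbed scans enter the GLM as one-hot
regressors; because a one-hot column absorbs its scan completely, a
single-scan artifact at a scrubbed scan cannot bias task betas.

## Ground-truth layout

`default_ground_truth` places inside an ellipsoidal brain (grid default
32 × 32 × 24 at the preset voxel size; the grid is configurable and the
test suite uses 24 × 24 × 18 and smaller):

* a `visual` slab responding equally to all six conditions;
* bilateral `body_gyrus` / `face_gyrus` regions responding to everything
  (images 2.5, scrambles 1.5 signal units over a baseline of 100,
  noise SD 2.0) — these play the role of anatomical search spaces;
* small bilateral `body_core` / `face_core` boxes inside the gyri
  (roughly a tenth of the space) where the preferred category responds at
  4.5 — the scale relationship that makes top-10% selection recover the
  core, as in real data where fROIs are small parts of a gyrus;
* an `animacy_patch` where the four animate conditions share one random
  multivoxel pattern (SD 1.5) absent for objects, plus per-block pattern
  jitter (SD 0.75) so trials of a condition are similar but not identical.

Amplitudes were chosen once to give comfortably detectable block-design
effects at n = 15, comparable to strong category-selective responses; they
were not tuned against any test outcome.

What the generator does **not** emulate: nonlinear neurovascular coupling,
spatially correlated noise, physiological noise spectra, susceptibility
artifacts, inter-subject anatomical variability (all subjects share one
grid and truth layout), or motion-by-susceptibility interactions. Passing
tests therefore demonstrate correctness of the analysis machinery and its
calibration under the stated model, not performance on real scans.

## Per-block (single-trial) estimation

Each block gets its own GLM with the target block's regressor plus one
combined regressor for all other blocks (runs modelled independently),
yielding 36 beta maps per participant. With the single combined nuisance
regressor this estimator is exactly unbiased only when a voxel responds
equally to every block; heterogeneous responses leak a small bias through
shared nuisance columns even at wide spacing. That is an inherent property
of the method, kept as-is for fidelity; the tests assert the exact property
in the homogeneous case and the pipeline relies only on pattern
*correlations*, which tolerate the shared bias.

## Searchlight RSA

Sphere offsets are all integer voxel offsets whose mm distance from the
center is ≤ r (dog preset: r = 4 mm on 1.5 mm voxels → 81 offsets) or < r
(human preset: r = 8 mm on 2 mm voxels → 251 offsets). The two boundary
conventions exist because the reported 251-voxel human sphere is consistent
only with an exclusive boundary on a 2 mm grid; both are implemented and
the preset documents the choice. Valid centers need ≥ 15 (dog) / 30 (human)
gray-matter voxels in the sphere. Correlations are computed across in-mask
sphere voxels between every unordered pair of distinct trials in a set
(cross-run pairs included; self-pairs never). |r| is capped at 1 − 1e-6
before the Fisher transform so identical patterns stay finite; zero-variance
trial patterns contribute no pairs. Pooled sets (faces, bodies, animate)
include cross-species pairs by default; `within_species_pairs_only`
preserves the alternative reading.

## Group inference

Sign-flip permutation of subject (difference) maps; exhaustive enumeration
of all 2^n sign patterns replaces sampling when 2^n ≤ the permutation
budget (n ≤ 12 at the default 5000). The cluster-defining threshold is the
two-sided t quantile at the preset p applied to the positive tail (all
reported contrasts are directed); clusters use 18-connectivity. Corrected
p is the rank of the observed extent in the max-extent null — with the
observed statistic added to the null when sampling, so p ≥ 1/(n_perm + 1);
under exhaustive enumeration p is a multiple of 1/2^n. Degenerate-variance
voxels get t = 0 with a warning. No variance smoothing is applied.
Repeated-measures ANOVAs use exact sums-of-squares / contrast-score
algebra (every effect of a 2×2 within design is a squared paired t); no
sphericity correction is applied, as the designs are 2- and 3-level and
balanced. FDR families group all planned comparisons answering one
question across fROIs.

## Numerical and design choices

* fROI size rounding: k = max(1, ⌈pct/100 · N⌉) per hemisphere — never
  empty in a tiny search space; ties in the target contrast break by voxel
  index, which also makes selections nested across increasing percentages.
* Hemispheres split on the sign of the world x coordinate (x ≤ 0 → left).
* Preference masking is strict (> 0).
* Sweep grid: {1, 5, 10, …, 100} percent.
* Resampling subsamples are drawn without replacement and sorted, so an
  n_sub = n draw reproduces the full-sample result bit-for-bit.
* All randomness derives from one master seed through SHA-256-hashed,
  named substreams (< 2^31); reruns produce byte-identical artifact trees,
  which the tests assert on the results manifest.
* Problem sizes used by the automated checks: the calibration suite runs
  200 null cohorts of 10 subjects on a 12 × 12 × 8 grid at 500
  permutations, and 300 null resampling cohorts of 20 subjects; the
  end-to-end recovery study runs 15 subjects on a 24 × 24 × 18 grid at 600
  permutations. These are the package's chosen desk-scale defaults for its
  own verification; all are configurable upward.

## Known limitations

* OLS without prewhitening (no AR(1) model); autocorrelated noise is also
  not simulated, so the calibration results do not speak to whitening.
* The permutation cluster test is mildly conservative at small n (add-one
  p-values plus extent discreteness), visible in the FWER calibration
  sitting slightly below the nominal 0.05.
* No atlas lookups, template registration, or real anatomical priors;
  "gyri" are geometric stand-ins.
* Run length is emergent from the jittered design (≈ 300–320 scans), not
  matched to any particular acquisition count.
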