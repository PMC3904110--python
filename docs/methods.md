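# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `riskconn`. The package reimplements, on a common 3 mm
isotropic grid, a resting-state fMRI analysis chain that relates a
composite risk-propensity trait to voxelwise functional connectivity, and
ships a synthetic-data generator so the whole chain is testable without any
imaging download.

## The composite trait score (GRP)

Fifteen scale/subscale scores enter the analysis: RPS; SSS thrill/adventure
seeking, experience seeking, disinhibition, boredom susceptibility; EPQ
extraversion, neuroticism, psychoticism, lie; TPQ novelty seeking, harm
avoidance, reward dependence; BIS attentional, motor, non-planning
impulsiveness. Because the instruments mix scales, PCA runs on the
correlation matrix. Components with unrotated eigenvalue > 1 are retained
(a strict inequality with a 1e-10 numerical guard so an identity
correlation matrix retains nothing), then varimax-rotated. Subject scores
use the regression method, `Z R⁻¹ Λ_rot`, with `Z` the standardized data,
`R` the sample correlation matrix and `Λ_rot` the rotated loadings; score
columns therefore have mean zero and roughly unit variance on the fitting
sample.

The risk component is identified automatically by a signed marker pattern
(+RPS, +SSS_TAS, +SSS_ES, +SSS_DIS, +EPQ_E, +TPQ_NS, −TPQ_HA): the rotated
component maximizing the |signed sum| of marker loadings is selected and
oriented so the sum is positive — high score means risk seeking. A tie
within 1e-6 raises rather than guessing.

**Varimax.** Rotation uses classic pairwise (Jacobi-style) sweeps with the
closed-form optimal planar angle per component pair, Kaiser row
normalization, tolerance 1e-8, at most 500 sweeps. Each planar rotation
increases the criterion, so the iteration cannot cycle. We found the
popular SVD fixed-point iteration stalls between two rotations on
symmetric two-block loading patterns (it approaches the optimum at a
vanishing rate); the pairwise algorithm reaches the grid-search optimum on
those cases, which the test suite checks against a dense angle search.

**Adequacy checks.** KMO is computed from the anti-image partial
correlations `q = -R⁻¹ᵢⱼ/√(R⁻¹ᵢᵢR⁻¹ⱼⱼ)` as `Σr²/(Σr² + Σq²)` over off-
diagonal pairs; Bartlett's sphericity statistic is
`−(n−1−(2p+5)/6)·ln det R` on `p(p−1)/2` degrees of freedom. Both are
advisory: they warn but do not block the fit.

**Sex comparison.** Welch's t by default; the pooled-variance test is
available for exact-replication attempts since the original report does
not say which was used.

## Preprocessing

Only the arithmetic steps are implemented: discard of the first k volumes
(default 10, equilibration), zero-phase band-pass 0.01–0.1 Hz, and
regression of the 6 motion parameters plus intercept. Registration-type
steps (slice timing, realignment, normalization) are out of scope because
synthetic data are generated directly on the common grid.

The band-pass is a 4th-order Butterworth applied forward and backward.
Forward–backward filtering with a 0.01 Hz lower cutoff has edge transients
whose decay is comparable to a 170-volume series, so we use the Gustafsson
initial-condition method, which chooses the pad so that forward and
backward passes agree; with it a mid-band (0.05 Hz) probe passes with gain
> 0.99 and a 0.2 Hz probe is attenuated below 2% on a 170-point series. An
ideal FFT brick-wall filter is available behind `method="fft"`. The
per-voxel mean is removed inside the filter (whether the original study
demeaned before or within filtering is unstated).

Confound columns are band-passed with the same filter before regression so
the projection cannot reintroduce stop-band energy. Motion QC excludes a
subject when any per-axis |translation| exceeds 2 mm or any |rotation|
exceeds 2° (strict inequalities, so exactly 2.0 is kept), and reports the
first offending axis/volume.

## Functional connectivity density (FCD)

Two voxels are functionally connected when their Pearson correlation is
strictly above `r_min` (default 0.6); negative and sub-threshold
correlations are non-edges. Zero-variance voxels have undefined
correlations; they contribute no edges, score zero, and are counted in the
output metadata. The graph is restricted to in-mask voxels.

* **Global FCD** of a voxel is its number of connections to all other
  in-mask voxels.
* **Short-range FCD** uses the growing rule: starting from the seed's
  spatial neighbours, a candidate joins the cluster when it is adjacent
  (26-neighbourhood by default; 6 and 18 selectable, and the choice is
  recorded in metadata because the short/long partition depends on it) to a
  voxel already linked to the seed by a continuous path of connected
  voxels *and* its own correlation with the seed exceeds `r_min`; growth
  iterates to closure. This equals the connected component containing the
  seed of {suprathreshold voxels} ∪ {seed} under the chosen adjacency,
  which is how it is computed (per-seed connected-component labeling on
  the candidate set's bounding box).
* **Long-range FCD** = global − short, exact at the raw integer stage; a
  negative value anywhere raises, since it can only arise from a growth-
  rule bug.

Count maps are Gaussian-smoothed (FWHM 8 mm default, σ = FWHM/(2√(2 ln 2))
per axis, computed on the full volume and re-masked, so values leak across
the mask edge as volumetric smoothers do) and then divided by their
in-mask mean, in that order; the normalized map has in-mask mean exactly 1.

## Seed-based RSFC

A seed's time series is the unweighted mean over its voxels. Per in-mask
voxel, Pearson r with the seed series is Fisher-transformed, z = atanh(r),
after clipping |r| at 1 − 1e-7 (machine-precision unit correlations stay
finite; clip events are counted). Zero-variance voxels get z = 0 with a
flag. The group "connectivity mask" that constrains seed-level inference
is a one-sample t-test of the z-maps against zero at a configurable
uncorrected voxel p (default 0.001) — the original threshold is unstated,
so it is explicit configuration, not a constant.

## Group inference

The voxelwise model is `y = b0 + b1·GRP + b2·sex + b3·GRP×sex` with GRP
mean-centered and sex coded female = 0 / male = 1. OLS runs per voxel;
each coefficient gets a t-map and the interaction a single-degree F-map
(t²), df = n − 4. With this coding the female conditional slope is `b1`,
the male slope `b1 + b3`, and their standard errors come from the
coefficient covariance (`Var(b1+b3) = V11 + V33 + 2V13`), which equals
sex-stratified OLS on centered GRP — both identities are tested.

**Cluster-extent correction.** Family-wise error is controlled by Monte
Carlo simulation of smooth null fields: per iteration, white Gaussian
noise on the grid is smoothed to the applied FWHM, re-standardized within
the mask, thresholded two-sided at the cluster-forming voxel p, and the
maximum suprathreshold cluster extent recorded; the minimum extent is the
smallest k whose exceedance probability across iterations is below α.
Defaults: voxel p 0.001 (0.005 for seed-level maps), α 0.05, 1000
iterations, 26-connectivity clusters. The simulation uses the *applied*
smoothing as the field smoothness since the intrinsic smoothness of real
data is not knowable for synthetic cohorts. At the reference scale — a
55,342-voxel gray-matter mask on the 61×73×61 3 mm grid at 8 mm FWHM —
this yields a minimum extent of 19 voxels = 513 mm³ (the acceptance suite
accepts 18–20 to absorb Monte Carlo and connectivity-convention
variability; in our runs the 6-, 18- and 26-neighbourhood conventions all
give 19). Thresholds are expressed in mm³ externally and voxels
internally (27 mm³ per 3 mm voxel); a non-multiple is rounded up.

Because no gray-matter mask is distributed with the analysis, the
full-scale simulation uses a synthetic stand-in: an ellipsoid shell
(cortical envelope minus a deep core) trimmed deterministically to exactly
55,342 voxels. Cluster statistics at fixed mask size are only weakly
sensitive to mask shape; the ±1-voxel acceptance band covers this.

**Simple slopes.** ROI means of the normalized maps are re-analyzed with
the same moderated regression; conditional slopes, SEs, t and p per sex
are read from the coefficient algebra (the moderated-regression probing
convention), and `slope_male − slope_female` equals the interaction
coefficient by construction.

## The synthetic-data generator

The generator produces the four inputs the chain consumes, under one
master seed with deterministically spawned per-subject streams (identical
seeds give bit-identical outputs).

* **Roster.** Staged exclusion flags (missing behavioural data → raw-image
  error → bad raw image → excess motion) assigned to disjoint subject
  sets, in that order, with exact requested counts; the retained subjects
  get an exact sex split. Defaults mirror the reference cohort: 324
  recruited, 5/3/12/15 excluded, 131 men + 158 women retained.
* **Questionnaire table.** A linear factor model: scores = Λ·latent +
  √ψ·noise with standard-normal latents, factor 1 (risk seeking)
  mean-shifted for males. The default Λ is the published rotated-loading
  pattern of the 15 scales on four components, with the display-suppressed
  cells at zero and the whole matrix scaled (×1.067) so the four
  components explain 55.8% of total variance, the level the original
  analysis reports — the visible cells alone reach only ~49%, so the
  published variance-explained line itself requires restoring that mass.
  The default male shift is 0.8 SD on the latent factor: observed scores
  attenuate the latent shift by the score–factor correlation (~0.91), and
  0.8 × 0.91 ≈ 0.73 reproduces the published observed score gap (means
  0.37 vs −0.31, pooled SD ≈ 0.94).
* **Motion traces.** Clean jitter (SD 0.1 mm/deg, clipped inside the QC
  bounds) for retained subjects; one planted spike (default 2.5, above
  both bounds) on a random axis/volume for subjects flagged for excess
  motion. A spike amplitude at or below the bound raises, since the
  flagged subject would pass QC.
* **BOLD.** Each region's voxels share a band-limited (0.01–0.1 Hz,
  brick-wall in the frequency domain, then standardized) latent signal;
  per-voxel white noise of SD σ (default 0.5) is added. Region-pair
  latent correlations follow `tanh(atanh(c₀) + β_sex·GRP)`: couplings are
  Fisher-z slopes per risk-score SD, which keeps every implied correlation
  inside (−1, 1) at any score and makes the planted seed-based z-slope
  equal the coupling by construction. Non-positive-definite latent
  correlation matrices (possible with ≥3 regions) raise with the subject
  named. In closed form, two voxels of the same region correlate at
  1/(1+σ²) raw, and voxels of regions a, b at `c_ab/(1+σ²)`; band-passing
  removes the out-of-band ~64% of the noise power, raising these to
  ≈1/(1+0.36σ²). The default two-region scene (baseline 0.71, male
  coupling −0.2, female 0) places the cross-region correlation just above
  the 0.6 edge threshold at GRP 0, so a negative male slope detaches the
  regions for higher-risk males — the planted moderation effect.

What the generator does **not** emulate: scanner drift, spikes and
physiological noise; anatomical variability and registration error;
spatially varying intrinsic smoothness; realistic motion-signal coupling.
Passing recovery tests therefore demonstrate the correctness and
calibration of the analysis chain, not its robustness to those real-data
complications.

## Validation studies and problem sizes

The studies in `riskconn.validation` (used by the test suite, the
acceptance script, and `analysis/05_recovery_studies.py`) run at sizes a
single CPU handles in minutes:

* density maps vs brute force: 25 random grids up to 6×6×6, exact equality
  required for all three maps under randomly drawn adjacency conventions;
* Monte Carlo extent at full reference scale: 1000 iterations on the
  55,342-voxel mask (~30 s);
* null calibrations: 1000 replicates (Bartlett, n=300, p=15) and 1000
  noise voxels (interaction F, n=100), both expected in 0.05 ± 0.02;
* seed-based recovery: 20 cohorts of 200 on a 10×10×6 grid, male slope
  sign correct in ≥ 18/20 with the female null retained;
* end-to-end density-map recovery: 10 cohorts of 200 on a 12×12×6 grid
  with a stable second region pair (so global-mean normalization stays
  defined for every subject), Dice of surviving interaction clusters with
  the planted pair > 0.3 in ≥ 80% of seeds. This study runs *unsmoothed*
  with a matched unsmoothed Monte Carlo threshold: synthetic subjects
  share one grid with no anatomical misalignment, so smoothing — whose
  purpose is absorbing registration error — only dilutes 16 planted voxels
  across a small grid and caps the achievable Dice regardless of
  detection;
* score construction: score–factor correlation at n=2000 (> 0.9) and the
  male > female comparison at p < 0.001 in ≥ 95 of 100 cohorts of 289.

## Numerical choices and degenerate inputs

* Correlations use exact vectorized arithmetic on demeaned, norm-scaled
  series; zero-variance series are defined as unconnected/z = 0 rather
  than NaN, always counted and flagged.
* Fisher clipping constant 1e-7; t statistics at zero residual variance
  are reported as ±inf (and F as inf) rather than NaN.
* The eigenvalue retention rule and the connectivity threshold are strict
  inequalities; QC bounds are strict ("greater than").
* mm³-to-voxel conversions round up with a warning when not exact.
* All stochastic components accept explicit seeds; the pipeline driver
  derives stage seeds from one master seed and embeds them, with the full
  resolved configuration, in every manifest.

## Limitations

Registration, physiological denoising and surface visualization are out of
scope. The growing algorithm is exact but per-seed; it is sized for the
desk-scale grids used here and for moderate whole-brain masks, not for
sub-millimeter data. The published cluster tables and β values of the
original cohort derive from raw data that are not publicly available, so
they cannot be reproduced numerically; the package instead reproduces the
two procedure-determined published numbers (289 retained subjects;
513 mm³ minimum extent) and validates everything else by planted-truth
recovery.
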