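# Methods

## The measure: regional homogeneity

Regional homogeneity treats each voxel's neighborhood as a panel of raters
ranking the scan's time points. For the *m* ≤ 27 in-mask series (the voxel
plus its 26-adjacent neighbors) of length *n*, each series is converted to
mid-ranks, the per-timepoint rank sums *R*ₜ are formed, and the
tie-corrected Kendall coefficient of concordance is

W = 12·S / (m²(n³ − n) − m·ΣⱼTⱼ),  S = Σₜ(Rₜ − R̄)²,  Tⱼ = Σ over tie groups (t³ − t).

Properties the implementation relies on and the tests verify:

- W ∈ [0, 1]; W = 1 iff all series are rank-identical.
- Under independent series, E[W] = 1/m exactly (the rank-sum total is
  fixed, so S is a pure variance term). This anchors the white-noise
  calibration: for full 26-neighborhoods the in-mask mean must sit at
  1/27 ≈ 0.0370.
- W is invariant under any strictly monotone transform of each series —
  ReHo measures rank agreement, not amplitude.
- When every series in a neighborhood is constant the statistic is
  undefined; such voxels carry NaN (never 0) with a warning.

Neighborhoods are truncated at mask and grid boundaries rather than
dropped; the per-voxel size actually used (`m_used`, from 2 to 27) is
exported for QC, and voxels with fewer than 2 usable series are NaN.

### Concordance → correlation → Fisher z

Group statistics are run on Fisher-z values. Because the ReHo literature
mixes concordance- and correlation-scale quantities when applying Greiner's
relation r = sin(π·τ/2), three conversion modes are provided:

- `literal` (default): the W value itself is fed into Greiner's relation,
  r = sin(πW/2), z = atanh(r). This follows the most common published
  phrasing. Note W ∈ [0, 1], so these z values are non-negative.
- `mean_spearman`: the identity r̄ = (mW − 1)/(m − 1) converts W to the
  mean inter-series Spearman correlation, which is already Pearson-scale
  and is Fisher-transformed directly. This is the statistically cleanest
  reading (it can be negative for anti-correlated neighborhoods).
- `mean_tau`: the mean pairwise Kendall τ_b over the m series, then
  Greiner's relation. Exact but O(m·n²) per voxel, so intended for small
  grids or spot checks; the map route uses a sign-matrix inner-product
  formulation, and the scalar helper uses an independent pairwise
  computation, letting the two serve as cross-checks in the tests.

All modes are strictly monotone in local synchrony, so group contrasts are
substantively unaffected by the choice; correlations at |r| = 1 are clipped
to 1 − 1e−7 before atanh with a warning.

## Motion censoring

Framewise displacement follows the Power convention: the sum of absolute
backward differences of the six rigid-body parameters, rotations converted
to arc length on a 50 mm sphere, FD of the first volume defined as 0. The
source acquisitions do not state an FD formula or rotation units, so the
dominant convention was adopted (translations mm, rotations radians;
configurable to degrees on input).

The analysis window is the contiguous stretch (default 1600 volumes)
minimising total FD, ties broken toward the earliest start so runs are
reproducible. A participant is excluded when strictly more than
`round(0.05 × window)` volumes inside the window exceed 0.5 mm FD — at the
default window length that is "more than 80 of 1600", and a participant
with exactly 80 is retained. The retained 1600 volumes at TR 0.392 s span
627.2 s (10 min 27 s).

## Group inference

Two designs mirror the study questions (group coded R+ = 1, sex male = 1,
continuous covariates mean-centered):

- main effect: intercept, group, birth GA, PMA, sex; contrast on group;
- interaction: intercept, group, PMA, group × PMA, sex; contrast on
  group × PMA. Centering PMA before forming the product keeps the group
  column interpretable at mean PMA; a positive contrast means a steeper
  maturational slope in the R+ group.

Inference is by Freedman–Lane permutation: fit the nuisance-only model,
permute its residuals (whole rows, one exchangeability block), add back the
nuisance fit, refit the full model, and compare |t| values. Two-tailed p
values use the +1-smoothed estimator p = (1 + #{|t*| ≥ |t_obs|})/(1 + B),
which can never be 0 and whose exact null rejection probability at level α
is floor(α(B+1))/(B+1) — at B = 500 and α = 0.05 that is 25/501 ≈ 0.0499,
the value the calibration tests are centered on. When the requested
permutation count reaches n! the scheme switches to exhaustive enumeration
with a warning and the p value becomes the exact proportion. The seed is
mandatory; given (seed, B) every p map is bit-reproducible. Voxels whose
residual variance is at floating-point round-off of the response scale
(perfectly fitted, e.g. a constant response) are assigned t = 0 rather than
0/0 noise.

Multiplicity is controlled with Benjamini–Hochberg step-up FDR applied
within the voxel set under test: within each ROI separately for the ROI
analyses (each region is its own family, control regions included), and
across all in-mask voxels for the whole-brain exploratory maps. Significant
voxels are grouped into clusters by 26-connectivity (6/18 available), and
per-participant summaries take each participant's median z over the pooled
significant voxels — the same voxel set for everyone, so medians are
comparable and can be regressed on PMA per group (OLS with pointwise 95%
bands) to describe maturational trajectories.

## Demographics

The cohort table is summarised as median (range) per group with two-sided
Mann-Whitney U comparisons: exact enumeration when the pooled data are
tie-free and min(n) ≤ 8, otherwise the tie-corrected normal approximation
with continuity correction; the method used is recorded per row. A Student
t-test p value is reported alongside as a parametric reference, because
published demographic tables are not always explicit about the variant
actually used and the two can differ materially on skewed variables (e.g.
a near-central rank statistic can coexist with a moderate mean shift when
distributions are asymmetric).

## Synthetic data: what it emulates and what it does not

The generator's single synchrony mechanism is spatial Gaussian filtering of
white noise: smoothing FWHM (in voxels) is monotone in expected W and
analytically anchored at the independence limit (FWHM 0 ⇒ E[W] = 1/m).
Group effects and maturational trends are implanted either as extra
smoothing inside chosen atlas regions (full BOLD → ReHo route) or as
additive shifts of the Fisher-z maps (direct route used where thousands of
cohorts are needed). Atlases are disjoint spherical blobs packed into an
ellipsoidal mask — by default 16 analysis regions plus 1 control region,
mirroring a social-brain parcellation with an anterior-temporal control.
Optional AR(1) temporal filtering and random-walk motion traces with
configurable spike rates complete the fixtures.

Default cohort structure matches the emulated study: 18 participants per
group, 13 male / 5 female, PMA uniform over 39.3–44.9 weeks, TR 0.392 s,
2.15 mm voxels. The default test grid is 24³ voxels with 200 volumes so a
full cohort simulation runs in seconds; the acquisition-scale preset
(`SimulationConfig.acquisition_scale()`, 1600 analysed volumes) is available but
is not a test default. For the direct z-map cohorts the package's own
defaults, chosen a priori, are: between-subject voxelwise noise SD 0.15
(realistic for Fisher-z ReHo variation across infants), implanted group
effect 0.15 z in a 200-voxel region, and group-specific maturational slopes
of +0.1 z/week (R−) vs 0 (R+) — an interaction-scale effect whose expected
per-voxel t (≈3–3.5 at n = 36) lies in the regime reported for real
neonatal cohorts of this size.

What the generator does **not** emulate: hemodynamic response shape,
cardiac/respiratory physiology, scanner drift and multiband artifacts,
registration error, partial-volume mixing, or anatomically realistic
parcel geometry. Passing tests therefore demonstrate that the statistics
are correct and calibrated for data with controlled local synchrony — they
do not certify preprocessing choices on real acquisitions, which enter this
pipeline only after denoising and template-space registration.

## Numerical and design choices

- Ranks via mid-ranks (`scipy.stats.rankdata`); map-level W computed by a
  convolution formulation (per-voxel rank volumes, neighborhood sums with a
  3×3×3 footprint) that is algebraically identical to the scalar formula;
  the suite checks voxel-for-voxel agreement and 1e−12 agreement with a
  brute-force oracle.
- W is clipped into [0, 1] against float round-off; out-of-mask voxels are
  NaN in every exported map.
- Window-selection sums are rounded at 1e−12 before argmin so cumulative-
  sum jitter cannot break the earliest-start tie rule.
- Exclusion threshold `max_count` defaults to round(0.05 × window), giving
  the documented 80-volume limit at window 1600.
- BH-FDR via `statsmodels.stats.multitest`; connected components via
  `scipy.ndimage.label`; NIfTI I/O via `nibabel` (NIfTI-1, voxel size and
  TR carried in the header; all internal coordinates are 0-based voxel
  indices — the analyses are template-space, so no world-coordinate math is
  performed).
- Permutation streams for per-ROI tests derive from (seed, ROI label), so
  adding or removing a region never changes another region's p values.
- Motion exclusion runs before any group statistic. If exclusions
  unbalance the sexes the pipeline does not silently re-match; the seeded
  sex-matching subsample used at cohort construction is exposed separately
  as `neoreho.match_sex_ratio`.

## Known limitations

- The `literal` conversion mode yields non-negative z values by
  construction; studies wanting signed local correlation should use
  `mean_spearman`.
- `mean_tau` maps are quadratic in the number of time points and are not
  intended for full-resolution volumes.
- The permutation engine supports single-column contrasts (the two study
  models); F-tests over multi-column contrasts, TFCE, variance smoothing
  and cluster-mass inference are out of scope.
- Exhaustive enumeration is only triggered for very small cohorts (n! ≤
  requested permutations); for n ≥ 10 inference is always Monte-Carlo.
- The demographics module intentionally reports both rank-based and
  t-test p values; on this package's own packaged cohort table the two
  disagree for the more skewed variables, and the rank-based value is the
  primary output.
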