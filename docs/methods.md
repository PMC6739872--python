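# Methods

## Experimental model

The analysis targets a randomized block design with six conditions, the
spatial scales room → continent (index *s* = 1..6). A block is 12.5 s
(2.5 s target display followed by four 2.5 s comparison pairs) and is
followed by 7.5 s of fixation; a 24-block run therefore spans 480 s of
task plus lead-in/trailing fixation, acquired as 200 volumes at TR 2.5 s.
Each run is scale-balanced (blocks_per_run/6 blocks per scale; two
locations per scale alternating across blocks). Fixation is the implicit
baseline — no rest regressor is modeled.

## GLM

Each scale's predictor is the union of its blocks as a boxcar over the
full 12.5 s epoch, convolved with a canonical double-gamma HRF and sampled
at volume onsets (*t* = *i*·TR). The HRF is the difference of two gamma
densities — response peak delay 6 s, undershoot delay 16 s, dispersions
1 s, peak:undershoot ratio 1/6, 32 s support — normalised so the
continuous curve peaks at 1; all parameters are exposed. Convolution runs
on a 0.1 s grid, so every sampled column is a pure subsampling of the same
analytic curve regardless of TR. One intercept per run; nuisance columns
(motion, white-matter/CSF averages, drift regressors) are appended
unconvolved. High-pass filtering is available as cosine nuisance
regressors but is off by default for synthetic data, whose drift is a
single low-frequency cosine handled adequately by the AR model and
intercepts.

Voxel time series are scaled to percent signal change,
100·(x − mean)/mean per run-concatenated voxel; voxels with non-positive
(or sub-threshold) mean intensity are excluded, not raised. Betas are
estimated by two-pass prewhitening: OLS residuals → per-voxel Yule–Walker
AR(2) coefficients (closed-form 2×2 solve from biased autocovariances,
which guarantees a stationary filter; lag products never cross run
boundaries) → the filter x_t − φ₁x_{t−1} − φ₂x_{t−2} applied to data and
design with the first two rows of each run dropped (conditional
whitening) → re-estimation. A pooled-AR option averages φ across voxels.
Group summaries are one-sample random effects (mean, across-subject SE,
t; t is reported missing when SE = 0, never infinite). Contrasts are
paired across-subject t-tests on weighted beta combinations. Modulation
regressors multiply each block's boxcar by the subject's z-scored rating
(by location or scale, as the measure demands), convolve, and mean-center;
each modulator enters its own GLM, not orthogonalised against the task.

## Tuning characterisation

Scale sensitivity: single-factor repeated-measures ANOVA on the six betas
across subjects, F = MS_condition / MS_condition×subject with df
(5, 5(n−1)), uncorrected for sphericity (the all-zero-variance cell is
reported F = 0, p = 1). P-values are BH-FDR corrected over the analysis
mask at q = 0.01 and surviving voxels cleaned with a volumetric
connected-component threshold (default 5 voxels, 6-connectivity) — a
volumetric stand-in for a surface cluster criterion, since no surface is
rendered.

Tuning fit: the six betas are min-subtracted and fitted with
a·exp(−(s−c)²/(2w²)) by bounded trust-region least squares (bounds:
amplitude 0–100, center −100–100, width 0–100 with the lower width bound
nudged to 10⁻³), multi-start with the center initialised at each scale
1..6 to avoid local minima at boundary-tuned voxels. r² = 1 − SS_res/SS_tot
against the min-subtracted vector; flat vectors have undefined r² and fail
the r² > 0.7 gate. Because min-subtraction slightly deforms a true
Gaussian profile, even noise-free recovery carries a small deterministic
center bias (< 0.01 scale units for interior centers) — negligible against
the noise-driven error the gate controls. The ordinal preferred scale is
the argmax beta, ties broken to the lowest index.

## Gradient statistics

Within a region, gated voxels' preferred scale (Gaussian peak, or argmax
as the alternative universe — both supported and labeled) is averaged at
each coordinate along the chosen axis (posterior→anterior = increasing Y
by default); coordinates without gated voxels are omitted, not
zero-filled. The observed statistic is the least-squares slope of mean
preferred scale on coordinate (unweighted, matching per-coordinate
averaging; a voxel-count-weighted option exists). The null shuffles the
per-coordinate mean vector itself (not voxels) over coordinates; the
sampled p uses the add-one rule p = (1 + #{slope* ≥ slope})/(n_perm + 1),
one-sided for an increase. With ≤ 8 coordinates an exact enumeration over
all permutations is available (p = #{≥}/k!). Region p-values are BH-FDR
corrected. The per-subject variant fits the Gaussian per voxel on each
subject's own betas within the group-defined region, profiles, tests, and
FDR-corrects across subjects at 0.05, counting significant subjects;
subjects with no gated voxels are flagged and counted non-significant.

## ROI, event-related averages, overlap

ROI betas average each subject's betas over mask voxels first, then take
across-subject mean and SE (subject-mean-first). Event-related averages
align each block to the first acquisition at or after its onset (no
temporal interpolation) and average the percent-signal-change course over
the following 10 volumes (25 s at TR 2.5 s) per scale; truncated blocks
are dropped with a warning. Parcellation overlap is plain voxel counting:
100·|region ∩ label|/|region|, label 0 reported as unassigned.

## Geography and behavior

Pairwise distances between all items of a location use the Haversine
formula on a sphere of radius 6371 km (mean Earth radius, configurable);
only scales 3–6 enter, since room/building stimuli have no coordinates.
Environment size versus scale is the least-squares line of mean log10
distance per scale on scale index (mean-of-logs; a pooled per-distance
mode is exposed); zero distances are excluded with a count, and a 2-scale
fit is flagged under-determined. Rating analysis: Pearson correlation of
each measure with scale per subject (location-level measures use the
subject's per-scale mean), a two-tailed one-sample t-test of the r values
across subjects, and a one-way ANOVA across the six scales with
Tukey–Kramer post-hoc pairs (the Kramer adjustment handles unbalanced
groups). Within-subject z-transforms use the sample (n−1) SD.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes:
the block timing and per-run scale balance above; voxel tuning that is
exactly the Gaussian form the fitter assumes, with the true center an
affine function of the axis coordinate plus Gaussian jitter (clipped to
[1, 6]) inside a gradient region and constant in a control region;
AR(2)-correlated noise plus a single cosine drift over a positive
baseline; geographic items scattered at Rayleigh-distributed great-circle
distances along uniform bearings (spherical destination-point formula, so
continent-scale sets stay valid); and ratings whose expected correlation
with scale matches the empirically observed effects this design elicits
(familiarity −0.72, difficulty +0.39, first-person −0.81, third-person
+0.80), calibrated so
the target holds for the per-scale-mean correlation the analysis computes.
The BOLD task term is baseline·(1 + Σ_s r_s/100·c̃_s(t)) with regressors
centered within run, which makes the noise-free run mean equal the
baseline exactly and hence the percent-signal-change GLM recover the
injected responses to machine precision — the closed-loop identity the
test suite asserts.

Not emulated: motion and physiological artifacts, spatial noise
correlations, realistic anatomy or folded cortex, inter-subject anatomical
variability (a per-subject slope-jitter parameter stands in for gradient
geometry variation), and HRF variability. Passing tests therefore
demonstrate correctness of the estimators and calibration of the tests
under the assumed model, not robustness to real-data artifacts that
preprocessing must handle upstream.

## Default study conditions and problem sizes

The demo dataset uses 6 imaging subjects × 2 runs × 200 volumes on a
12×30×12 grid of 3 mm voxels (gradient region 5×24×6 voxels, control
4×24×6), tuning amplitude 1% signal change, width 1 scale unit, center
jitter 0.3 scale units, AR(0.3, 0.2) noise with innovation SD 0.5 (≈0.6%
of baseline), drift amplitude 0.3 at 128 s — chosen as a desk-scale cohort
whose effect size mirrors a robust fMRI block design. The behavioral
cohort is 19 rating subjects (the imaging subjects are its first
members), a typical sample for this kind of experiment. Calibration checks use 19
simulated subjects and 5000 null voxels (ANOVA), 500 null datasets
(permutation test), and 1000 tuned voxels at noise SD 0.15 (tuning
recovery). Pearson r on 6 support points is mildly inflated relative to
its population target (|E[r]| exceeds |ρ| by ≈0.03–0.05 at these n); the
recovery checks use a ±0.1 band accordingly.

## Numerical choices and degenerate inputs

- Permutation p can never be 0 (add-one rule); a constant profile reports
  slope 0, p = 1 with a flag rather than raising.
- SE = 0 anywhere (identical subjects, zero contrast variance) yields a
  missing t/p, never ±inf.
- Rank-deficient designs are rejected naming the collinear columns;
  blocks outside the acquisition window are rejected naming the block;
  missing ratings are rejected naming the block's location/scale.
- Voxels with zero-variance betas: ANOVA F = 0, Gaussian fit marked
  failed, gate false — excluded from profiles.
- All generators and tests are pure functions of their seeds; per-subject
  and per-stage seeds are spawned from the master seed via SeedSequence.

## Known limitations

Volumetric (not surface) cluster control; straight-line axis
parameterisation (no geodesic hippocampal axis); per-voxel AR(2) assumes
temporally stationary noise within run; the behavioral ANOVA pools
subjects rather than modeling subject as a random effect; the geographic
analysis takes coordinates as given (no geocoding).
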