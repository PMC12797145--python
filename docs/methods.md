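# Methods

This note documents the models, parameter choices and numerical conventions
of the `eegfmri` package, and what its synthetic cohorts do and do not
emulate.

## 1. Metric definitions and conventions

**BOLD preprocessing.** The first `drop_initial` frames (default 5) are
rejected; the mean white-matter and CSF series are regressed out per voxel
(with intercept); a frequency-domain boxcar band-pass keeps bins with
`0.01 <= f <= 0.1` Hz. The voxel mean is restored after both steps so that
mean-normalized metrics stay defined, which also makes the band-pass
idempotent. Spatial smoothing is a no-op by default: on the unitless
synthetic grid a physical FWHM is meaningless; a Gaussian option with sigma
in voxels exists for real data.

**RSFA** = temporal SD / temporal mean. The mean comes from the
mean-restored series (band-passing alone would zero the denominator); the SD
reflects the filtered fluctuation. Non-positive means yield NaN, not errors.

**gFCD** counts gray-matter voxels correlating with the index voxel at
`r >= 0.6`. **lFCD** grows a cluster from the index voxel by repeatedly
adding gray-matter voxels face-adjacent (6-connectivity) to a cluster member
that correlate with the *index* voxel at `r >= 0.6`; the count excludes the
index voxel, so 0 means no local connections. Both are validated against
exhaustive double-loop oracles. Constant series are defined to correlate
with nothing (degenerate synthetic voxels must not poison maps). Densities
are log-transformed as `log(1 + x)` **voxel-wise before** network averaging;
`+1` tolerates zero counts, and the before-averaging order is an explicit
choice (either order is defensible; this one is fixed and tested).

**BOLD sample entropy** uses `m = 3`, `r = 0.6 * SD` (population SD),
Chebyshev distance, self-matches excluded, with `n - m` templates at both
lengths; a constant series gives 0 (`-ln 1`). Neighbour counting uses a k-d
tree with the max-norm metric and is exactly equal to the naive O(n²) count.

**Seed-based FC**: seeds default to the voxel nearest each network centroid;
the network value is the mean Fisher z of non-seed network voxels against
the seed-mean series, with |r| capped at 0.999 to keep degenerate cases
finite.

**EEG spectra** use Welch averaging with Hann tapers, 0.5-Hz resolution
(`nperseg = rate / 0.5`) and 50 % overlap. Frequency bins belong to bands by
half-open intervals `[low, high)`, except gamma which closes at 50 Hz, so no
bin is counted twice. Fractional power divides each band's power by the
total 1–50 Hz power (fractions sum to 1 per source). Total power is
normalized by the **population** SD (ddof = 0) of per-source totals — the
convention that makes totals `{p, 3p}` map to `{1, 3}`.

**Imaginary coherence** is `|Im(S_uv / sqrt(S_uu S_vv))|` per bin; it is
zero for any zero-lag mixture of common sources, which is exactly why it is
used: instantaneous (volume-conduction-like) mixing cannot produce it.
Band-limited values are arithmetic means over a band's bins; the broadband
value is the mean over all 1–50 Hz bins. Network coherence is the mean over
all unordered within-network source pairs (an all-pairs choice; seed-to-rest
aggregation would also be defensible but is not implemented as the default).

**Complexity index (CI)**: the series (band-filtered first; the broadband CI
over 1–50 Hz is the headline variant) is coarse-grained by non-overlapping
means at scales 3, 6, 13, 21, 62; SampEn with `m = 2` and `r = 0.5 * SD` of
the *pre-coarse-graining* series is computed per scale; CI is the
trapezoidal area under the entropy-vs-scale curve. Keeping r fixed across
scales is the standard multiscale-entropy convention; because r scales with
SD, CI is invariant to amplitude rescaling.

## 2. Macrovascular correction

The venous reference is the series of the voxel with maximal fBV (ties
broken at the lowest linear index, with a warning), demeaned and normalized
by its maximum absolute value. For every voxel the integer lag in
`[-max_lag, +max_lag]` (default 3 frames ≈ 13.5 s at TR 4.5 s; the search
window is a package choice, configurable) maximizing the absolute Pearson
correlation over the overlapping window is selected; ties prefer the
smallest |lag|, then negative lags. Both directions are searched because the
perivascular transit direction is not known a priori. The lag-shifted
reference (zero-filled outside the recorded window, the same convention the
synthetic injector uses) is removed by per-voxel OLS with intercept; the
voxel mean is restored afterwards so RSFA's denominator survives. Residual
variance never exceeds the input variance, and re-applying the regression
with the same lag field is a no-op (the residual is already orthogonal);
re-estimating lags on pure-noise residuals can of course select a new
chance maximum, so idempotence is stated for a fixed lag field.

The regressor has the same shape at every voxel up to lag and gain. This is
the implemented approximation: per-voxel biophysical forward modelling of
vascular signal shapes (vascular-network simulation) is out of scope here,
and the fitted per-voxel coefficient plays the role of the per-voxel
amplitude.

Ordering: correction runs after initial-frame dropping and **before**
nuisance regression/band-pass, because the venous reference is broadband and
filtering first would hide the lag structure. The order is configurable.

## 3. Association model

For each (Y, X) pair and correction state the observation table has one row
per participant × network (140 rows at the 20 × 7 design). The pipeline is:
z-score Y and X (sample SD, ddof = 1) and the ±1-coded sex label; remove
rows outside `[Q1 - 1.5 IQR, Q3 + 1.5 IQR]` on Y or X (type-7 linear
interpolation quartiles — the fence depends on the interpolation rule, so it
is fixed); re-standardize; fit

```
Y ~ 1 + X + Sex + X:Sex
```

with a random intercept per participant (REML, lbfgs). The random-intercept
choice reflects the design: observations are repeated across networks
within participants, and the inter-participant question is the target. A
variant adds a crossed network random intercept (variance components over a
single group). Outlier removal operates on z-scored values and is followed
by re-standardization; this ordering is fixed by contract and asserted in
tests. Singular or non-converging mixed fits fall back to OLS and are
flagged — never silently.

Effect sizes are the standardized fixed-effect coefficients. The adjusted r²
is `1 - (1 - R2m)(n - 1)/(n - p - 1)` with `R2m` the squared correlation
between observed Y and the fixed-effects-only fitted values (marginal, so
participant-intercept variance counts as unexplained) and `p = 3`.
Benjamini–Hochberg FDR at `q = 0.05` runs separately within each correction
state's family; undefined p-values are never significant. The paired pre/post
adjusted-r² vectors are compared with a two-sided Wilcoxon signed-rank test
(Pratt handling of zeros; exact null for n ≤ 25 without zeros, else normal
approximation with continuity correction).

## 4. Synthetic cohorts

**What is emulated.** 20 participants (balanced sexes, +1/-1 coded) × 7
compact network blobs on a 16³ voxel grid; TR 4.5 s with 53 volumes from a
240-s run (frames = floor(duration / TR); the first 5 are dropped by the
analysis, mirroring steady-state rejection); EEG at 125 Hz for 240 s, 3
sources per network. Each network's neuronal driver is a sum of band-limited
Gaussian oscillations with power weights delta/theta/alpha/beta/gamma =
0.15/0.15/0.50/0.12/0.08 (alpha carries half the oscillatory power) plus a
broadband noise floor (RMS 0.05). The per-participant, per-network latent
amplitude `x ~ N(0,1)` enters the EEG as a lognormal amplitude
`exp(0.4 x)` and the BOLD as a fluctuation gain
`exp(beta * x * (1 + gamma_sex * sex))` with `beta = 0.5` and
`gamma_sex = 0.3` — the coupled metric pair is therefore network RSFA
against normalized total EEG power, both monotone images of the latent.
BOLD voxels are the rectified driver envelope convolved with a canonical
double-gamma hemodynamic kernel (peak 6 s, undershoot 16 s, ratio 1/6),
resampled to the TR grid, riding on a baseline of 100 with 2 % relative
fluctuation and unit-relative voxel noise (`noise_sd = 1`, which keeps
baseline within-network correlations near 0.5 — below the 0.6 FCD threshold,
so densities have headroom in both directions). EEG sources add independent
noise (RMS 0.3) and small per-source sample lags so that within-network
imaginary coherence is non-zero.

The vessel tree (trunk + branch) has fBV peaking uniquely on the trunk and
decaying to zero beyond a 2-voxel dilation. The venous reference is sub-0.1-Hz
filtered noise plus a 0.3-Hz respiratory component sampled at the TR (it
aliases into the pass-band, as real physiological oscillations do). The
confound adds `amplitude(v) * gain_p * reference(t - lag(v))` with
exponential spatial decay (scale 3 voxels, cut at 4 scales), lag growing
with distance up to 3 frames, and a per-participant lognormal gain — the
inter-participant variability is what degrades the EEG–fMRI association and
is what the correction recovers. Four of the seven network blobs lie within
the perivascular decay range; three are remote controls.

**Two generator levels.** The volumetric generator above exercises the whole
image pipeline. A metric-level generator (`simulate_metric_tables`) draws
network-wise observations directly from the participant-level model
`Y = beta X + beta_sex Sex + gamma X:Sex + u_p + eps`
(`u_p ~ N(0, 0.5²)`, `eps ~ N(0, noise_sd²)`, X standard normal with a
participant component) — the statistical skeleton the volumetric cohort
inherits. Coefficient-recovery and type-I-control checks use this level,
because only there does the injected `beta` live on the metric scale that
the model estimates; the volumetric level is used for the confound
inflation/recovery and r²-improvement properties, where only directions and
orderings are asserted.

**What is not emulated.** Realistic vascular anatomy, field-strength/TE
dependence, motion, slice timing, physiological recordings, EEG forward/
inverse modelling (sources carry network labels directly), and MNI geometry.
Passing tests therefore demonstrate correctness of the estimators and of the
pipeline's statistical behaviour under its own assumptions — not performance
on real acquisitions.

## 5. Problem sizes and determinism

Default problem sizes (16³ grid, 27-voxel networks, 3 sources/network) were
chosen so that a full 20-participant cohort generates in ~2 s and a complete
replicate of the coupled-pair analysis runs in a few seconds, making
many-replicate properties (100-replicate coverage, 50-replicate r²
comparison, 20-seed inflation tests) routine. All randomness flows from
explicit seeds through `numpy` `SeedSequence` spawning; identical configs
give bit-identical cohorts, and all writers use fixed row ordering and
`%.10g` floats so reruns produce identical files.

Known numerical edge cases: Fisher z capped at |r| = 0.999; constant series
correlate with nothing; zero-variance columns abort a pair with a reason;
all-zero fBV aborts correction with an instruction to supply a vessel mask;
EDF files are readable (via MNE) but not written — delimited TSV plus JSON
sidecar is the native EEG format.
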