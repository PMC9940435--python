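# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `msdyn`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## EEG preprocessing

Recordings are 16-channel 10–20 montages (Fp1…T6) sampled at 500 Hz.
The chain is: zero-phase FIR band-pass 1–45 Hz (windowed-sinc design with
automatic transition bandwidths; DC is attenuated below 0.1% and a 0.1 Hz
drift below 2% of its amplitude, verified numerically) → spherical-spline
interpolation of bad channels (montage positions from the standard 10–20
layout; more than two interpolated channels triggers a warning, since such
recordings are normally excluded) → common-average reference → selection of
five 10-s epochs. Epoch selection replaces expert artifact judgement with a
reproducible score: max absolute amplitude plus a channel-variance outlier
term; the lowest-scoring non-overlapping windows are kept in temporal
order.

## Microstate model

The instantaneous topography strength is the global field power — the
per-sample population standard deviation of the channel potentials. Maps at
GFP peaks (strict local maxima, thinned to at least 10 ms apart) are pooled
across all subjects of both groups into a single clustering, and per-subject
statistics come from backfitting the shared templates; per-group clustering
is available but not the default, because a shared template set is what
makes group comparisons of temporal parameters well-defined.

**Clustering** is the modified (polarity-invariant) k-means: assignment by
maximal squared spatial correlation, centroid update as the dominant
eigenvector of the GFP-weighted outer-product sum of assigned maps. The
fitted quality measure is the global explained variance (GEV): the
GFP²-weighted mean squared spatial correlation between each peak map and
its template. Iteration stops when GEV improves by less than 1e-7; the best
of 10 random restarts is kept; an emptied cluster is re-seeded from a
random map and logged. k is fixed at 4 (the standard resting-state choice);
a predictive-residual-variance criterion CV(k) = σ̂²·((n−1)/(n−1−k))² is
provided as a diagnostic, and on synthetic 4-template data it is minimised
at k = 4 while on pure noise it has no interior minimum.

**Labelling.** Templates are labelled A–D by globally optimal (Hungarian)
matching of absolute spatial correlations against packaged canonical
reference topographies, built from idealised 10–20 electrode positions:
two mirrored diagonal gradients (A, B), an occipital-maximum map with an
annular curvature term (C) and a fronto-central focal map (D). The diagonal
slope (0.65) and curvature weight (1.1) keep all pairwise |r| < 0.5 —
impossible for purely linear gradients, since three maps in the
two-dimensional linear field space force one pair to |r| ≥ 0.5. These maps
are synthetic approximations, not copies of any published atlas, and can be
overridden.

**Backfitting.** Two conventions are implemented. The default follows the
classical segmentation view that microstate transitions occur at GFP
minima: the recording is cut at GFP troughs (≥ 10 ms apart) and every
sample in an inter-trough window takes the label of the window's GFP peak,
the moment of highest topographic signal-to-noise. The alternative labels
every sample independently. In both modes, runs shorter than 10 ms are
dissolved into their neighbours at the split point maximising total
correlation (each dissolve merges runs, so the cleanup provably
terminates). Sample-wise labelling with the cleanup alone was measured to
leave 17–25% biases in occurrence/duration at SNR 5 because near-boundary
samples carry almost no signal; the trough-delimited default reduces the
mean per-subject relative error of all three temporal statistics to under
5%. Smoothing can be disabled (`min_segment_ms=0`).

**Temporal statistics.** Coverage is the assigned-sample fraction,
occurrence the number of maximal runs per second, duration the mean run
length; `coverage = occurrence × duration / 1000` holds identically on
fully assigned segmentations. Transition probabilities are estimated from
the *segment* sequence (not sample-to-sample), have zero diagonal by
construction, and rows of states with no exits are NaN and flagged. Epoch
aggregation pools counts, so runs never span epoch boundaries.

## Network functional connectivity

ROI time series are linearly detrended and band-passed 0.01–0.1 Hz with a
zero-phase 2nd-order Butterworth (filtfilt), appropriate for ~176-volume
series at TR = 2 s. FC is the Pearson correlation matrix; constant ROI rows
are flagged NaN rather than failing the subject. Network summaries average
raw correlations (no Fisher transform — an option exists in spirit but the
plain edge mean is the primary definition) over unordered ROI pairs:
off-diagonal upper-triangle within a network, the full rectangular block
between networks; negative edges are included. Subjects with mean Jenkinson
FD ≥ 0.2 are excluded (inclusive threshold) before group statistics.
Volumetric preprocessing is out of scope: the module starts at ROI×time
matrices. The packaged 400-ROI/7-network lookup table is a synthetic
stand-in with realistic per-network sizes (VN 61, SMN 77, DAN 46, VAN 47,
limbic 26, ECN 52, DMN 91); any user partition TSV is accepted.

## Statistics

Covariate adjustment is residualize-then-test: each feature is regressed on
[intercept, covariates] across all subjects by OLS (collinear columns
dropped with a warning) and the residuals are compared between groups with
a pooled two-sample t plus Cohen's d. The permutation test shuffles group
labels 10 000 times over the *precomputed* residuals (the covariate fit is
not re-estimated per permutation — stable, and exchangeability holds
because the residualization is group-blind); p = (1 + #{|t*| ≥ |t|}) /
(n_iter + 1). BH-FDR is applied to the parametric p-values, one family per
analysis block: 24 microstate features (12 temporal parameters + 12
transitions) and 28 network features (7 intra + 21 inter). Both raw and
FDR-adjusted p-values are reported for correlation families, since
conventions differ. Partial Pearson correlations residualize both variables
on the covariates; the 95% CI uses Fisher's z with SE 1/√(n − k − 3) and
the p-value the t distribution with n − k − 2 df. Demographic tables
reported as mean ± SEM are compared with the Welch-type
t = (m₁ − m₂)/√(SEM₁² + SEM₂²), and 2×2 count tables with the Pearson
chi-square without continuity correction. MIDAS scores are banded 0–5 /
6–10 / 11–20 / ≥21 into little-or-none / mild / moderate / severe
disability. Subgroup splits (disease duration > 5 y, attacks > 2 /month,
pain side, medication) reuse the same machinery and warn below n = 3.

## Synthetic cohort

The generator's defaults define the emulated study conditions: 24 patients
vs 26 controls; 16-channel EEG at 500 Hz, 50 s per subject (the five 10-s
epochs), SNR 5; BOLD with 176 volumes at TR 2 s over the 400-ROI partition;
sex ~ Bernoulli(0.16 male), ages ~ N(36, 9²) clipped to 18–60 drawn
identically for both groups; FD ~ N(0.075, 0.02²) clipped positive.

EEG: a segment-level Markov chain (uniform off-diagonal transitions for
controls) with gamma dwell times of shape 2 — dwell distributions are
empirically unimodal and non-exponential, and shape 2 avoids a pile-up of
1-sample segments — whose means are 70/70/80/75 ms for A–D, within the
canonical 60–90 ms range. Each subject scales each state's dwell mean by a
lognormal multiplier (σ = 0.12). Each segment gets a random polarity and a
half-sine amplitude envelope, so GFP peaks fall inside segments and GFP
troughs mark transitions — matching the peak-sampling and trough-cutting
logic of the analysis. SNR is the ratio of time-averaged signal variance to
white-noise variance, averaged over channels. Generating templates are the
canonical A–D reference maps, so planted state effects appear under their
like-named labels.

Patients: microstate-B dwell means ×1.35 and chain inflow ×1.3;
microstate-D ×0.70 both ways; intra-ECN connectivity −0.08 and DAN–ECN
−0.06 from control blocks (intra values 0.30–0.45, inter 0.07–0.18).
Patient MIDAS is a rounded nonnegative transform of a latent Gaussian
coupled at r = 0.5 to the subject's microstate-C dwell multiplier
(mean 7.2, SD 6.2, matching a mildly disabled cohort). These effect
magnitudes on the generating scale are free parameters of the generator,
not estimates from any cohort.

A feature-level generator (`simulate_feature_cohort`) draws the 52 canonical
features directly as unit-variance Gaussians with age/sex loadings and
planted standardized shifts — defaults are the reported effect sizes
d = 1.377/1.336/1.281 (B coverage/occurrence/duration),
−1.958/−1.743/−1.633 (D), −0.657 (intra-ECN), −1.633 (DAN–ECN). It is the
desk-scale surrogate for calibration and power studies where only the
inference machinery is exercised.

What the generator does *not* emulate: 1/f background EEG, alpha rhythms,
eye/muscle artifacts, volume conduction from dipolar sources, hemodynamic
convolution or motion structure in BOLD, and site/scanner effects. Passing
recovery tests therefore demonstrates correctness of the algorithms under
the stated generative assumptions, not robustness to every property of real
recordings.

## Verification results (computed by the validation suite)

* Demographic-table recomputation matches the published statistics to one
  unit in the second printed decimal (the published SEMs are themselves
  rounded, which bounds attainable agreement at ~0.01).
* GFP equals an independently coded population SD to < 1e-10 on 10⁵ maps.
* On the default 50-subject cohort at SNR 5: fitted templates match planted
  ones at |r| ≥ 0.95 (measured 1.00), mean per-subject relative errors of
  coverage/occurrence/duration are 2–5%, and the group-pooled empirical
  transition matrix is within 0.02 of the planted chain.
* Block-planted BOLD (400 ROIs, 5000 volumes): all 28 network summaries
  within 0.02 of the planted blocks.
* Under the global null (500 replicate cohorts), the permutation test
  rejects at 5.0% and the BH empirical FDR is ≈ 0.04.
* With the default planted effects, all six microstate features are flagged
  after FDR in ≥ 90% of replicate cohorts and the DAN–ECN drop in ≥ 90%;
  the intra-ECN effect (planted at d = 0.657) is detected in only ~20–30%
  of replicates — a 24-vs-26 design simply has little BH-adjusted power at
  that magnitude, so the flagged set equals the planted set exactly in only
  ~10–25% of replicates. This is a power limit of the design, not an
  algorithmic defect; the evaluation reports the rates rather than hiding
  them.
* Fisher CIs for the partial correlation cover a true r = 0.5 in ≈ 95% of
  draws at n = 24 with two covariates.

## Problem sizes and determinism

The validation studies run at the sizes quoted above (50-subject EEG
cohorts, 500 null replicates at 2000 permutation iterations, 50 power
replicates, 1000 CI simulations), chosen so the whole suite completes in
about a minute on one CPU while leaving Monte-Carlo error well inside every
asserted margin. All randomness flows from explicit seeds through
`numpy.random.default_rng`; identical (config, seed) pairs reproduce
datasets, fits and reports bit-for-bit.

## Known limitations

* EDF output uses a compact single-record 16-bit writer (round-tripped
  against an independent EDF reader in tests); exotic EDF features
  (annotations, multiple records, per-channel rates) are not supported.
* The trough-delimited backfit assumes transitions at GFP minima; for data
  where that assumption fails, `mode="sample"` gives the classical
  sample-wise labelling.
* Transition-probability inference treats segments as a first-order Markov
  chain; higher-order dependence is not modelled.
* The packaged partition is a synthetic stand-in; analyses of real data
  should supply the genuine atlas lookup table.
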