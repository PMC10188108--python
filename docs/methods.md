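# Methods

`zeitconflict` implements the computational analysis of circadian behavior
and rhythmic gene expression in animals entrained to simultaneous light
and temperature cycles, including designs where the two zeitgebers are
phase-offset against each other (sensory conflict, SC). Everything runs
end-to-end on synthetic data with known ground truth, so each stage's
guarantees are stated in terms of what the simulations plant and what the
pipeline recovers.

## Behavior arm

**Track cleaning.** Raw pose-estimation tracks (one center-point per
animal, 2 frames/s) are cleaned in two passes: frames with tracking
likelihood < 0.90, then frames entered by a displacement > 2 cm/frame
(computed on the likelihood-interpolated track). Invalid frames get x and
y linearly interpolated (separately) between the nearest valid frames;
leading/trailing invalid frames take the nearest valid value; the jump
rule is re-checked once, without iterating to a fixpoint. Cleaning is
idempotent on realistic tracks and preserves track length.

**Bouts and binning.** Speed at frame i is the displacement (i−1)→i times
fps; a bout is a maximal run of frames with speed ≥ 0.03 cm/s lasting
≥ 3 s (6 frames at 2 fps); all other movement is treated as tracking
noise. Bout distance is summed into wall-clock hourly bins (a partial
first hour bins to its clock hour) and normalized to the animal's maximum
hourly movement, which corrects for body-size differences. A fully
inactive animal gets an all-zero normalized series, is flagged, and is
excluded from group means (0/0 := 0). Group profiles are pointwise
mean ± SEM with a centered 4-h moving average; the even window is
anchored as bins t−2…t+1 (edges shrink), a convention recorded in the
profile metadata.

## Rhythm detection

**Lomb-Scargle permutation tests.** The classical variance-normalized
periodogram (scipy's `lombscargle`, mean-centered input; power = fraction
of variance, so a noise-free sinusoid scores 1) restricted to 20–28 h
(10–14 h for circatidal screens), significance by shuffling values across
time points, p = (1 + #{null peak ≥ observed})/(n_perm + 1), default
n_perm = 2000. For replicated designs (e.g. qPCR, 3–4 replicates × 13
time points) the statistic is the peak power of the per-timepoint mean
series and the null shuffles *all* replicate values jointly before
re-averaging; with one replicate per timepoint this reduces exactly to
the plain test. Permutation loops use a precomputed tau-shifted basis so
the whole null is two matrix products; a unit test pins the vectorized
power to scipy's.

**Empirical 24-h reference-waveform test (eJTK-style).** Statistic:
maximum Kendall tau-b between the series and 24-h cosines at 24 hourly
phases; null by permuting the series against the fixed reference bank.
This is a permutation-calibrated decision rule with the same semantics as
the published empirical-JTK approach, not its Gamma-approximation null.
Pair differences within a relative 1e−9 tolerance count as ties, so exact
periodic repeats compare as tied.

**Multi-harmonic period/phase fitting.** For each candidate period on a
0.02-h grid, truncated Fourier fits with 1…3 harmonics are scored by BIC;
the best (period, harmonic count) wins (ties to the smaller period).
Phase is the argmax of the fitted waveform over one period and amplitude
half its peak-to-trough range. BIC selection keeps noisy sinusoids from
being overfit by overtones while sawtooth-like waveforms retain them. At
the study's 72-h recording length with SNR 2, the Rife–Boorstyn bound
puts the period-error SD at ≈ 0.37 h — no estimator can deliver sub-0.2-h
single-shot period errors there; the estimator is median-unbiased
(measured bias ≈ 0.08 h in phase, ≈ 0 in period over 100 replicates).

**Umbrella (asymmetric-waveform) screen.** Sampling times are folded mod
24 h, pooling the two recorded cycles as replication. For each candidate
peak time (the sampled times) and rise length (4-h increments across the
0.3–0.7 fraction of the period, i.e. rises of 8–16 h, the conventional
peak-border restriction of umbrella rhythm screens), the statistic sums
Mann-Whitney pair counts along the rising arm, along the falling arm, and
— because the waveform is periodic, making the trough a global minimum —
from the trough against every falling-arm group. Per-shape significance
comes from a design-level Monte-Carlo permutation null (10⁵ pooled
permutations, computed once per design and cached; the normal
approximation to the Mack-Wolfe statistic over-reports this tail by
roughly a factor of two). p_raw is the minimum over shapes; p_adj is
Bonferroni (× number of shapes, ~18 for a 6-timepoint design), and genes
are called rhythmic at p_adj < 0.01. Ties are half-counted in the
statistic; the null is simulated from continuous draws, so heavily tied
data are tested conservatively (the screen runs on continuous log2-CPM
values where ties do not occur).

*Power at the screen's margin.* At exactly 2-fold peak-to-trough
amplitude, NB dispersion 0.1, 13 × 3 sampling, the screen's sensitivity
measures ≈ 0.75–0.80 (seed-dependent) with empirical FDR ≤ 0.05 and a
null familywise flag rate of ≈ 0.005 at the nominal 0.01. A parametric
cosinor F-test oracle on identical data reaches only ≈ 0.86, so this is
close to the ceiling a rank-based screen with shape correction can
attain; genes at ≥ 2.7-fold are detected essentially always.

## Rhythm comparison

**Cosinor comparison.** A joint linear model
y = M + ΔM·g + β_c cos ωt + β_s sin ωt + δ_c g·cos ωt + δ_s g·sin ωt
(g the group-2 indicator, ω = 2π/24) yields per-group amplitude
A = √(β_c² + β_s²) and acrophase ψ = atan2(β_s, β_c)/ω. Differences in
mesor, amplitude and phase get Wald tests; amplitude and phase use
delta-method standard errors from the OLS covariance, and Δφ is wrapped
to (−12, 12]. This reproduces the decision behavior of cosinor-comparison
testing with a closed-form covariance. Degenerate (flat) groups flag the
phase comparison undefined.

**Circular statistics.** Summaries are vector means on angles 2π·phase/24
(circular variance = 1 − R). The Rayleigh test uses the finite-n
corrected approximation p = exp(√(1+4n+4(n²−R_n²)) − (1+2n)), which
agrees with a 100,000-draw Monte-Carlo null within |Δp| ≤ 0.005 at n = 10
(a Monte-Carlo option exists for very small samples). Watson's two-sample
U² is bootstrapped from the pooled sample (default 9999 resamples).
Two-sample homogeneity of phase distributions uses a Monte-Carlo
label-permutation test (10,000 reps) on
T = Σ_j n_j ‖mean vector_j − pooled mean vector‖², sensitive to both
direction and concentration differences. Bimodality is detected by the
Rayleigh test on doubled angles (the standard axial transform). All
interfaces are in hours; radians are internal.

**Zeitgeber attribution.** Under a light/temperature offset of Δ hours,
the expected phase of a light-entrained rhythm is ZT18 (peak activity on
the lights-on clock) and of a temperature-entrained rhythm (18 + Δ) mod
24. Per individual, circular distances to both expectations are compared
with a paired Wilcoxon signed-rank test (exact for n ≤ 25); the verdict is
light-closer / temp-closer / equidistant at α = 0.05.

**Half-period alignment.** Each animal is assigned to the half-day window
([0,12) vs [12,24) ZT, hours mod 24) containing more of its activity;
ties go deterministically to [0,12) with a flag. The second group's
series are shifted 12 h, the mean profile recomputed and Lomb-Scargle
tested. Noise-free antiphase cohorts align to a pure 24-h mean (power
1.0); pure 12-h waveforms tie in window totals, are left unshifted, and
keep their 12-h peak — the procedure cannot manufacture 24-h power.

## Activity metrics

The dark-light contrast is dark-phase mean minus light-phase mean of
un-normalized activity (percent time active, in percentage points; and
cm/h), with hour membership decided by the bin's start hour. Group
comparisons of hourly activity fit activity ~ phase × group with a random
intercept per animal and AR(1) residual correlation within animal, by
REML over (σ²_animal, ρ, σ²) with closed-form per-animal covariances
(convergence tolerance 1e−6, Nelder-Mead profile optimization); the
reported contrast is the group difference in the dark−light effect, with
BH-adjusted pairwise Wald comparisons, and a Welch fallback on per-animal
contrasts if the fit is singular. Rhythm-strength distributions are
compared with Kruskal-Wallis, Dunn's tie-corrected pairwise z-tests
(BH-adjusted), and Levene's test centered at the median.

## Wavelet clustering

Profiles are decomposed with a continuous complex Morlet transform
(ω₀ = 6, pywt `cmor2.0-0.955`) on 48 log-spaced periods from 2 to 36 h.
Dissimilarity is the Frobenius norm between the complex coefficient
matrices. Two deliberate choices: (1) the metric uses coefficients, not
power — wavelet power is phase-invariant, so antiphase rhythms would be
indistinguishable; (2) no per-spectrum unit-power rescaling — input
profiles are already max-normalized, and unit-power scaling inflates
arrhythmic near-zero-power spectra into mutually distant noise. Both
normalized variants remain available (`coefficient_unit`, `power`). PCA
of the distance matrix (rows as centered feature vectors, all components
with eigenvalue > 1e−10) feeds complete-linkage clustering. Cluster
support is multiscale bootstrap: feature columns resampled at scales
0.5…1.4 × the feature count (1000 replicates each), per-node recovery
proportions BP(r) fitted on the probit scale with z(r) = v√r + c/√r by
weighted least squares, AU = 1 − Φ(v − c); nodes recovered never/always
get AU 0/1 without fitting, and cluster identity under resampling is the
leaf set. Trees serialize to Newick with AU (or BP) node labels.

## Expression arm

Counts pass a low-expression filter (CPM > 1 in ≥ 3 samples of some
condition), are TMM-normalized (30% M-trim, 5% A-trim, precision
weights; reference library = 75th-percentile fraction closest to the
mean; factors normalized to product 1; cross-checked against
edgeR::calcNormFactors in the test suite) and expressed as
log2(CPM + 0.5) on effective library sizes. Each condition is screened
with the umbrella test; classification uses p_adj < 0.01 for rhythmic
and a marginal-significance exclusion band — a gene is
condition-specific only if p ≥ 0.1 in the other condition; genes in
between are indeterminate, and every gene receives exactly one class.

For shared rhythmic genes, the cosinor comparison between conditions
gives the signed shift Δφ_light on the lights-on clock;
Δφ_temp = wrap(Δφ_light − 12) re-expresses it against the temperature
cycle of the 12-h-offset design. A gene is *temperature-tracking* when it
shifted 10–12 h on the light clock (p < 0.01) but shows no significant
shift relative to the temperature cycle. Amplitude changes of shared
genes use paired Wilcoxon on per-gene cosinor amplitudes (log2-CPM
scale) with the median percent change; condition-specific sets are
compared by unpaired Wilcoxon on mean expression. Phases entering
distribution tests come from cosinor fits (the screen's coarser peak-time
estimate is reported alongside).

## Sliding-window enrichment

For each of 24 hourly window starts, genes with peak phase in
[start, start+4) (half-open, mod 24) are tested per functional term
(≥ 5 members) for over-representation with a one-sided Fisher exact
(hypergeometric) test, BH-adjusted across terms within each window — not
across windows. The hourly score of a term is the mean of
−log10 p_adj over the three windows strictly containing that hour
(starts t−3, t−2, t−1 mod 24; the score at ZT3 averages windows ZT0-4,
ZT1-5, ZT2-6), and an hour is enriched when its score exceeds
−log10(0.05). Contiguous enriched runs (circular) reduce to their argmax
hour, ties to the earliest hour of the run. The score track is exactly
rotation-equivariant and is tested against an independent brute-force
recomputation.

## Synthetic data: what it emulates, and what not

**Locomotion.** Bout onsets follow an inhomogeneous Poisson process
λ(t) = r₀(1 + d·cos(2π(t − φ)/24)) (thinning algorithm), exponential bout
durations (mean 30 s), persistent-heading within-bout steps of
bout_speed/fps folded into the arena by reflection, stationary otherwise.
Defaults: 2 fps, 72 h, nocturnal peak ZT18, r₀ = 2/h, d = 0.8,
0.06 cm/s. Artifacts: dropout frames get likelihood uniform on [0, 0.90)
(clean frames on [0.95, 1]; only the 0.90 boundary matters downstream)
and teleports are single-frame excursions > 2 cm. Not emulated: body
shape, multi-animal occlusion, light masking of activity, pixel-to-cm
calibration error.

**Expression.** Negative-binomial counts with mean
μ_g(t) = exp(m_g + a_g cos(2π(t − φ_g)/24)) × library scaler,
variance μ + 0.1μ², over 13 time points every 4 h (48 h) × 3 replicates
× 2 conditions; m_g uniform on [3, 8] (natural log; median ≈ 250
counts), library scalers uniform on [0.8, 1.2], rhythmic-gene phases
from a von Mises mixture peaking at ZT4 and ZT14 (κ = 3), matching the
bimodal phase distribution characteristic of this system.
Condition-specific genes have a_g = 0 in the other condition; a
configurable fraction of shared genes carries a +12 h phase in condition
B. Not emulated: batch effects, gene-gene correlation, length/GC bias,
outlier samples. Passing tests therefore demonstrate correctness of the
statistics under the stated noise model, not robustness to those
real-data pathologies.

**Phases.** Von Mises draws on the 24-h clock; κ = 0 yields circular
uniformity.

All generators take one seed, use one `numpy` Generator per call (no
global state; per-animal substreams via `SeedSequence.spawn`), and are
bit-reproducible.

## Problem sizes used in the shipped checks

Null calibration: 500 series per test at 199 permutations (the 0.05
decision needs only that granularity; defaults stay at 2000).
Estimator recovery: 100 replicates. Screen operating point: five
200-gene matrices. Classification: one 1000-gene panel at 30% rhythmic —
small panels dominated by strong rhythms make the TMM factors themselves
oscillate with time of day and imprint spurious rhythms onto flat genes,
an artifact of panel size rather than of the classifier. Clustering: 100
seeds of 14 profiles (5 + 5 + 4, noise SD 0.05) for recovery, one run at
1000 bootstrap replicates for AU. These sizes were chosen so each check
is statistically decisive at desk scale.

## Known limitations

- The umbrella screen's sensitivity at exactly 2-fold amplitude and
  dispersion 0.1 sits at ≈ 0.75–0.80; see the power note above.
- The AR(1) mixed model assumes equal spacing of hourly observations and
  a common correlation structure across animals.
- AU p-values inherit the usual multiscale-bootstrap caveats: supports of
  weakly separated nodes carry Monte-Carlo noise of a few percent at
  1000 replicates.
- The replicate-aware permutation test assumes exchangeability of all
  replicate values across time points under the null; strong
  heteroscedasticity across time points would distort its calibration.
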