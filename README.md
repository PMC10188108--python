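# zeitconflict

Analysis toolkit for circadian experiments in which two zeitgebers —
light and temperature — entrain an animal simultaneously, possibly out of
phase with each other (*sensory conflict*). It was built for studies of
the sea anemone *Nematostella vectensis*, whose locomotor rhythms and
rhythmic transcriptome respond to both cues, but nothing in the code is
species-specific: it applies to any design with pose-tracked locomotion
and/or a gene × sample count matrix sampled around the clock under two
conditions.

The package covers, end to end:

- **Behavior**: cleaning of markerless-tracking output (likelihood < 0.90
  and > 2 cm/frame jumps removed and interpolated), movement-bout
  detection (≥ 0.03 cm/s sustained ≥ 3 s), hourly ZT binning with
  per-animal max-normalization, smoothed group mean profiles.
- **Rhythm detection**: variance-normalized Lomb–Scargle with permutation
  nulls (plain and replicate-aware, period bands 20–28 h or 10–14 h), a
  permutation-calibrated empirical-JTK 24-h test (max Kendall τ against
  hourly reference cosines), BIC-selected multi-harmonic curve fitting
  for period/phase/amplitude, and an umbrella (Mack–Wolfe-type)
  nonparametric screen for asymmetric 24-h waveforms with a design-level
  Monte-Carlo permutation null and Bonferroni correction over waveform
  shapes.
- **Rhythm comparison**: cosinor comparison of mesor/amplitude/acrophase
  between groups (y = M + A·cos(2π(t−φ)/24), joint model with Wald and
  delta-method tests), circular summaries, Rayleigh (raw and doubled
  angles for bimodality), bootstrapped Watson U², Monte-Carlo two-sample
  homogeneity, phase attribution to light vs temperature (paired
  Wilcoxon on circular distances to expected phases), and half-period
  alignment of antiphase sub-populations.
- **Activity metrics**: dark/light activity contrasts and group
  comparisons with a random-intercept + AR(1) mixed model (REML),
  Kruskal–Wallis/Dunn and Levene tests on rhythm strengths.
- **Wavelet clustering**: complex Morlet spectra (ω₀ = 6, periods
  2–36 h), phase-aware coefficient distances, PCA of the distance
  matrix, complete-linkage trees with approximately-unbiased (AU)
  multiscale-bootstrap support, Newick export.
- **Expression**: TMM normalization to log2 CPM, per-condition umbrella
  rhythm screens, shared/condition-specific classification with a
  marginal-significance exclusion band (p < 0.1), per-gene phase shifts
  on the light vs the temperature clock with temperature-tracking calls,
  amplitude and phase-distribution comparisons.
- **Sliding-window enrichment**: per-term Fisher tests of 4-h peak-phase
  windows, hourly scores averaging the three overlapping windows'
  −log10 adjusted p, enriched intervals and peak hours.
- **Synthetic data**: generators for bout-structured nocturnal
  locomotion (with tracking artifacts), negative-binomial count matrices
  with cosinor mean structure and planted condition-specific/shifted
  genes, and von Mises phase samples — all seeded and bit-reproducible,
  with ground-truth tables.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a study-sized cohort of 18 nocturnal animals recorded for three
days at 2 frames/s, process the tracks, and test the group mean for
rhythmicity:

```python
from zeitconflict import (BehaviorSimConfig, generate_tracks, clean_track,
                          detect_movement, bin_hourly, group_mean_profile,
                          lsp_permutation_test, mfourfit_estimate)

cfg = BehaviorSimConfig(seed=7, n_animals=18, duration_h=72)
tracks, truth = generate_tracks(cfg)
series = []
for tr in tracks:
    tr = clean_track(tr)                   # likelihood >= 0.90, jumps <= 2 cm
    mask, bouts = detect_movement(tr)      # >= 0.03 cm/s for >= 3 s
    series.append(bin_hourly(tr, mask))    # hourly ZT bins, max-normalized
profile = group_mean_profile(series)
res = lsp_permutation_test(profile.zt_hours.astype(float), profile.mean,
                           period_lo=20, period_hi=28, n_perm=2000, seed=1)
fit = mfourfit_estimate(profile.zt_hours.astype(float), profile.mean)
print(f"LSP peak power {res.statistic:.2f} at {res.period_h:.1f} h, p = {res.p_raw:.5f}")
print(f"fitted period {fit.period_h:.2f} h, peak phase ZT{fit.phase_h:.1f}")
```

```
LSP peak power 0.85 at 24.4 h, p = 0.00050
fitted period 24.44 h, peak phase ZT17.3
```

The group rhythm is detected at the permutation floor (p = 1/2001), the
periodogram peak sits near 24 h, and the fitted peak phase lands close
to the planted nocturnal peak at ZT18. On the expression side:

```python
from zeitconflict import synthetic
from zeitconflict.expression import normalize_counts, screen_rhythmicity, classify_genes

cfg = synthetic.ExpressionSimConfig(seed=7, n_genes=500, rhythmic_fraction=0.3,
                                    amplitude_range=(0.5, 1.0), shift_fraction=0.5)
counts, design, truth = synthetic.generate_expression(cfg)
mat = normalize_counts(counts, design)         # TMM + log2(CPM + 0.5)
res_a = screen_rhythmicity(mat, "Aligned")     # umbrella screen, cycles folded mod 24
res_b = screen_rhythmicity(mat, "SC")
print(classify_genes(res_a, res_b).value_counts().to_string())
```

```
arrhythmic    343
shared        150
b_specific      4
a_specific      3
```

All 150 planted rhythmic-in-both genes are recovered as shared
(150/150 here; the handful of specific calls are borderline false
splits among the 350 planted-arrhythmic genes at these strong
amplitudes).

A `zeitconflict` command-line interface wraps the same stages
(`simulate`, `track`, `rhythm`, `compare`, `metrics`, `cluster`,
`expression`, `enrich`); every seeded subcommand is byte-reproducible.

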