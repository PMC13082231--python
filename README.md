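# tidepulse

Annual-periodicity detection and seasonal-ecotype classification for
depth-resolved marine microbial time series.

Open-ocean prokaryote communities are sampled on roughly monthly cruises at
many depths, yielding amplicon sequence variant (ASV) relative-abundance
tables spanning years of observations. `tidepulse` answers three questions
about such data:

1. **Which taxa cycle annually?** Each taxon's per-depth monthly series is
   screened with a nonparametric umbrella rank test; taxa passing at
   p ≤ 0.05 are "pASVs" (periodic ASVs).
2. **Does the whole community cycle?** Pairwise Bray–Curtis dissimilarities
   grouped by month lag expose annual recurrence as dips at multiples of 12;
   the lag profile (and richness/Shannon series) get the same rhythm test.
3. **When does each periodic taxon peak?** pASVs are classified into
   winter-, spring-, summer-, or fall-peaking *seasonal ecotypes* from their
   season-averaged measured abundances, then aggregated into per-depth,
   per-clade seasonal profiles.

A synthetic-data generator plants known annual signals into realistic
depth × month community tables, so every stage is testable against ground
truth without any sequencing data.

## The statistic

For a monthly series folded into 12 phase groups, a candidate rhythm
*envelope* (peak phase φ, rise length r) predicts an ordering that climbs
from the trough to the peak over r months and descends over 12 − r. Its
score sums Mann–Whitney U counts over all group pairs the envelope orders:

S = Σ_{i<j≤r} U(g_i < g_j) + Σ_{r≤i<j} U(g_i > g_j),

with groups indexed from the trough and ties counted ½. One-sided p-values
against the exchangeable permutation null come from exact enumeration,
seeded Monte Carlo, or (default) a normal approximation using the *exact*
permutation mean and variance of S — derived in closed form for arbitrary
tie structure, so the default pipeline is fully deterministic. All 132
envelopes (12 phases × 11 rise lengths) are scanned and Benjamini–Hochberg
adjusted; the series-level p is the minimum adjusted value. This is the
peak-known umbrella test of Mack & Wolfe (1981) scanned over peaks and
shapes, the construction used by nonparametric rhythm screens of omics time
series.

## Worked example

```python
import tidepulse as tp

# 2000 taxa, one depth, 30% planted annual signals, 74 of 102 months sampled
table, truth, manifest = tp.simulate_community(tp.strong_signal_config(seed=42))
records, skips, profiles = tp.detect_pasvs(table, 25.0, bh_across_taxa=True, seed=42)
metrics = tp.evaluate_detection(truth, records)
fraction = tp.pasv_fraction_by_depth(table, records)[25.0]
```

This prints (seed 42):

```text
table: 2000 taxa x 74 samples
pASVs detected: 653 | skipped: 0
sensitivity: 1.000
false discovery proportion: 0.081
season recovery: 0.898
pASV abundance fraction at 25 m: 0.416
peak seasons: {'summer': 181, 'winter': 148, 'fall': 159, 'spring': 165}
```

All 600 planted periodic taxa are recovered (sensitivity 1.0); 8% of the
detections are taxa with no planted signal — their relative abundances
genuinely oscillate through compositional closure and interpolation, see
`docs/methods.md`. Around 90% of true positives are assigned the season of
their planted peak month, and the detected pASVs carry 41.6% of total
community abundance at this depth.

The same pipeline is scriptable from the shell:

```sh
tidepulse simulate --config sim.yaml --seed 1 --out sim/
tidepulse detect   --config detect.yaml --seed 1 --out out/
tidepulse community --config detect.yaml --seed 1 --out out/
tidepulse ecotypes  --config detect.yaml --seed 1 --out out/
```

## Output schemas

| File | Columns |
| --- | --- |
| `pasvs.csv` | taxon_id, depth_m, statistic, p_adjusted, peak_month, peak_season, rise_length, mean_relative_abundance, n_observed |
| `skips.csv` | taxon_id, depth_m, reason (`constant` / `insufficient_months`) |
| `pasv_fraction_by_depth.csv` | depth_m, abundance_fraction, count, count_fraction |
| `lag_series.csv` | depth_m, lag_months, mean_bc, n_pairs |
| `community_rhythm.csv` | depth_m, statistic, p_adjusted, n_lags |
| `pasv_profiles.csv` | taxon_id, depth_m, month (1–12), mean_relative_abundance |
| `season_fractions_by_depth.csv` | taxon_id, depth_m, winter/spring/summer/fall_mean, peak_season, tie |
| `group_depth_profiles.csv` | group, depth_m, peak_season, fraction |

Input formats: a taxa × samples TSV (header of sample ids, first column
taxon id) or BIOM v1 JSON matrix; sample metadata CSV with `sample_id,
cruise_id, year, month, depth_m`; optional annotation CSV with a `taxon_id`
column and one column per annotation source (ecotype labels are accepted
when two or more sources agree).

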