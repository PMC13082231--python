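# Methods

## The rhythm model

A taxon (or a community summary) observed on a monthly grid is tested for
annual periodicity against the *umbrella alternative*: there exists a peak
month such that expected abundance rises monotonically toward it and falls
monotonically back to a trough 12 months apart. The alternative is indexed
by an **envelope** — a peak phase φ ∈ {0..11} and a rise length
r ∈ {1..11}; r = 6 is the symmetric (cosine-like) shape, r ≠ 6 the
asymmetric (sawtooth-like) ones. With `peak_border = (0, 1)` all 132
envelopes are admitted.

For one envelope the score is a sum of Mann–Whitney U statistics over every
pair of phase groups the envelope orders (rising-arm pairs expect the
earlier phase below the later; falling-arm pairs the reverse; the trough
group anchors only the rising arm; ties count ½). The null hypothesis is
exchangeability of the observed values over time slots.

### Null distributions

Three routes to the one-sided p-value `Pr(S* ≥ S)`:

- **exact** — full enumeration of value-to-slot assignments, limited to
  N ≤ 9 observations (9! = 362 880 layouts).
- **montecarlo** — seeded permutation resampling with the add-one
  correction p = (1 + #{S* ≥ S}) / (1 + n_perm).
- **normal** (default) — Gaussian upper tail with continuity correction,
  using the *exact* permutation mean and variance of S. S is a quadratic
  permutation statistic S = Σ_{s≠t} w_st · b(π_s, π_t); its second moment
  decomposes over the overlap pattern of slot pairs (identical, shared
  source, shared target, chained, disjoint), each matched with the
  corresponding sum over the value-comparison matrix. The derivation is
  valid under arbitrary ties, reduces to the Mack–Wolfe (1981) peak-known
  closed form for tie-free data (verified against it and against full
  enumeration in the tests), and makes the default pipeline deterministic —
  no seed enters the `normal` path. Degenerate nulls (zero variance, e.g. a
  constant series) give p = 1.

Per series, the 132 envelope p-values are Benjamini–Hochberg adjusted and
the minimum adjusted value is the series-level p — mirroring the
"independent" multiplicity handling of nonparametric rhythm screens. The
best envelope minimizes the raw p, ties broken by earliest peak phase, then
most symmetric shape. Because everything is rank-based, results are
invariant under strictly increasing transforms of the series.

Empirically (and in the acceptance tests) the series-level test is
conservative on complete i.i.d. series: type-I error ≈ 0.02 at α = 0.05
across normal, lognormal and uniform noise.

## Time grid and interpolation

Irregular cruise samples are mapped to integer month slots
(12·Δyear + Δmonth from a configurable origin); same-month duplicates are
averaged, because the phase grouping needs one value per slot. Interior
gaps are filled by linear interpolation between the nearest observed
neighbors; leading/trailing gaps are never extrapolated. The
observed/interpolated mask is preserved: **the rhythm test runs on the
interpolated series, but every abundance fraction, climatology and season
mean uses measured values only.**

Interpolation is not free: filled slots are intermediate between their
neighbors, which breaks exchangeability and inflates the rhythm test's
per-series null rejection from ≈ 0.02 to ≈ 0.10 at α = 0.05 when 28 of 102
months are interpolated. This is a property of the interpolate-then-test
procedure itself, documented here because it bounds how clean the detected
pASV set can be (see "Known limitations").

## pASV detection and seasonal ecotypes

Per depth, every taxon's relative-abundance series is gridded, interpolated
and tested; taxa with adjusted p ≤ α (default 0.05) are pASVs. Constant
series (including all-zero taxa) and taxa observed in fewer than 12 months
are skipped with an explicit reason. The α cutoff is applied per taxon by
default; `bh_across_taxa=True` additionally Benjamini–Hochberg-corrects
across taxa — the FDR-controlling reading, used by the power/FDR study.

Seasons are calendar-month blocks (Dec–Feb winter, Mar–May spring, Jun–Aug
summer, Sep–Nov fall; December belongs to the winter of the following
January). A pASV's peak season is the argmax of its four season means,
each season mean averaging every *measured* observation in that season
equally across years (uneven cruise coverage therefore weights by
observation, not by year — the natural reading of season-averaged
percentages). Exact ties go to the earliest season in
winter→spring→summer→fall order and are flagged; a season with no
observations makes the taxon unclassifiable rather than guessed. Monthly
climatologies are calendar-month means of measured values. Group labels
(clade/ecotype) come from annotation input only; a label is accepted when
two or more annotation sources agree, missing labels never count toward the
pair, and two different doubly-supported labels raise an error instead of a
silent pick (it cannot happen with well-formed three-source input, so it
flags QC problems).

## Community-level periodicity

Bray–Curtis dissimilarity d = Σ|x−y| / Σ(x+y) between all sample pairs at
one depth is grouped by unsigned month lag (same-month duplicates are
averaged first; lag-0 pairs are excluded as uninformative for a period-12
test) and averaged per lag. The mean-dissimilarity-vs-lag sequence is then
itself rhythm-tested on the lag axis: an annually recurring community shows
dissimilarity minima every 12 lags. Richness (count of positive taxa) and
Shannon diversity (−Σ p ln p, nats) are computed per sample and tested the
same way on the month axis.

## The synthetic generator

The generator emulates the sampling design of a multi-year open-ocean time
series: 102 month slots (origin November 2014), 74 sampled with no gap
longer than 3 months (endpoints always sampled), up to 20 depths from 5 to
4000 m. Latent abundance of taxon i at month t is

λ_i(t) = exp(b_i + a_i · f((month(t) − φ_i) mod 12) + ε_i(t))

with baseline b ~ N(0, 1) per taxon×depth, waveform f a unit-amplitude
cosine or an asymmetric rise-r triangle (half of periodic taxa each, r
uniform on {1..11}\{6}), peak month φ uniform on 1..12, amplitude a drawn
from the configured distribution (0 for non-periodic taxa), and
multiplicative lognormal noise ε ~ N(0, 0.3²). Columns are closed to
relative abundance; optional multinomial resampling at a configured read
depth produces count tables. The fraction of periodic taxa per depth
defaults to a linear decline from 0.7 (shallowest) to 0.05 (deepest),
mimicking the depth attenuation of seasonality in the upper ocean.

Two named study configurations:

- **strong_signal_config** — one depth, 2000 taxa (mid-range of observed
  per-sample ASV richness in open-ocean surveys), 30% periodic, amplitude
  uniform on [1, 2], noise sd 0.3. Used for the power/FDR/phase study.
- **depth_gradient_config** — 10 depths (5→4000 m, geometric), 40 taxa,
  periodic fraction 0.7→0.05. Used for the depth-attenuation shape check.

What the generator does *not* emulate: sequencing error and chimeras,
taxon–taxon interactions, trends and regime shifts, particle export
dynamics, and real rank-abundance tails (dominant real taxa can exceed 10%
of reads; the lognormal baseline keeps dominance milder so that planted
truth stays identifiable). Passing tests therefore demonstrate correctness
of the statistical machinery under a known signal model, not performance
guarantees on any particular ocean dataset.

## Problem sizes and numerical choices

The validation studies use desk-scale sizes chosen to keep the full suite
fast while leaving the statistics well-resolved: 2000 null replicates per
noise family for calibration, 50 seeds × 2000 taxa for power, 20 seeds × 10
depths × 40 taxa for the depth gradient, 20 000 permutations when Monte
Carlo is compared against the normal approximation. Floating-point
comparisons inside the statistic use a 1e−9 slack so lattice-valued scores
(multiples of ½) compare exactly; relative-abundance closure is enforced to
1e−9. All stochastic paths take explicit integer seeds; the default
(`normal`) pipeline is seed-free and bit-reproducible.

## Known limitations

- **Interpolation inflates discovery.** With 74 of 102 months observed, the
  interpolate-then-test procedure rejects ≈ 10% of truly aperiodic taxa at
  α = 0.05 (vs ≈ 2% on complete series). Under the per-taxon cutoff the
  realized false-discovery proportion against planted truth in the
  strong-signal study is ≈ 0.25; the BH-across-taxa screen brings it to
  ≈ 0.15. Users wanting a cleaner set should use `bh_across_taxa=True` or a
  stricter α.
- **Compositional closure spreads periodicity.** When strongly periodic
  taxa carry a substantial share of total reads, closure makes *every*
  taxon's relative abundance oscillate. Detections caused this way are
  real features of the relative-abundance series, but false discoveries
  with respect to latent (absolute) periodicity. The effect shrinks roughly
  as 1/√(number of taxa) and with flatter rank-abundance distributions.
- The peak-season rule can misassign taxa peaking at season boundaries
  (e.g. a late-February peak split between winter and spring); about 10% of
  true positives at amplitude ≥ 1 and noise sd 0.3.
- No trend removal: a monotone multi-year trend is not annual rhythm but
  can interact with the umbrella ordering; detrend externally if needed.
- The exact null is limited to 9 observations; use Monte Carlo above that.
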