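# Methods

## Scope and model

`spikesig` analyzes 30-second extracellular recordings of single cerebellar
nuclei neurons from awake mice and asks whether the spike train alone carries a
disease "signature": control, ataxia, dystonia, or tremor. The analysis has
three stages: (1) summarize each train by 12 interspike-interval (ISI)
parameters, (2) fit a coarse decision tree (at most three splits) that maps the
parameters to a signature, and (3) compare cohorts of assigned signatures with
standard population statistics. A synthetic generator provides spike trains
with the statistical structure of the four phenotypes so the whole pipeline is
testable without recordings.

All parameter estimates assume recordings of exactly 30 s; shorter or longer
recordings bias several estimators (notably the pause and mode statistics), so
featurization refuses other durations unless explicitly overridden, and the
pipeline logs a warning when the override is used.

## The 12 spike-train parameters

With ISIs in ms and instantaneous firing rate IFR = 1/ISI in Hz:

| parameter | definition | regime notes |
|---|---|---|
| `firing_rate` | spike count / duration (spikes/s) | literal count over 30 s, not (n−1)/span |
| `mean_ifr` | mean(1/ISI) | heavy-tailed for pause-rich trains |
| `median_ifr` | median(1/ISI) | robust "typical" rate |
| `cv` | sd(ISI)/mean(ISI), sample SD (n−1) | global irregularity |
| `cv2` | mean of 2·abs(ISI_n − ISI_{n−1})/(ISI_n + ISI_{n−1}) | local, rate-robust irregularity; 0 regular, ~1 Poisson |
| `skewness` | 2(median_ifr − firing_rate)/(median_ifr + firing_rate) | in (−2, 2); large for bursty trains |
| `isi25`, `isi100` | % of ISIs strictly > 25 ms / > 100 ms | slow-firing / pause mass |
| `interburst_pause` | mean of ISIs > 5× mean ISI; 0 if none | mean pause length (ms) |
| `mode_fraction` | % of ISIs in the modal 1-ms bin | peakedness of the ISI histogram |
| `rhythmicity_index` | Σ accepted (a_i + b_i) / \|n_spikes − baseline\| | autocorrelogram oscillation strength |
| `oscillation_peaks` | number of accepted autocorrelogram peaks | integer ≥ 0 |

Decisions the definitions leave open, and how they are resolved here:

* **CV uses the sample (n−1) SD** — the default of standard statistical
  tooling; the oracle tests pin this choice.
* **Strict inequality** in the `isi25`/`isi100`/pause thresholds.
* **`mode_fraction` binning**: the ISI histogram is discretized into 1-ms bins
  [k, k+1); ties go to the smallest bin. 1 ms is the coarsest grid on which a
  perfectly regular train keeps 100% modal mass.
* **`interburst_pause` = 0 when no ISI exceeds the cutoff.** A qualifying mean
  can never be ≤ 5× mean ISI, so 0 is unambiguous and keeps the feature table
  dense for tree training.

## Autocorrelogram and oscillation detection

The autocorrelogram uses forward (positive) lags only: raw counts of ordered
spike pairs in 5-ms bins out to 1 s (200 bins). No normalization is applied
because the oscillation-acceptance thresholds are count-relative. The
*baseline* is the mean bin count over the 960–1000 ms tail window and the
noise SD is the sample SD of those eight bins — the tail is the only lag
region designated as reference.

Peak detection walks outward: the first peak is the highest bin with lag in
[10 ms, 1.5× mean ISI); the trough after a peak at lag L_n is the lowest bin in
(L_n, L_n + L_1]; the next peak is the highest bin in (T, L_n + L_1 + 10 ms].
Window bounds are read as lag *times* of the first/previous peaks — the only
reading that yields well-formed windows. A peak/trough pair is accepted when
a_i + b_i > 4·SD, or when the peak exceeds baseline + 2·SD while the trough is
below baseline − 2·SD; detection stops at the first rejected pair or when a
window runs past 1 s. The rhythmicity index divides the accepted (a_i + b_i)
sum by z = |n_spikes − baseline| (the absolute value guards degenerate tiny
trains).

Two boundary behaviors are worth knowing. First, a *noise-free* periodic train
keeps full-height correlation at 1-s lags, so the "noise" window contains the
oscillation itself, the tail SD is of the order of the peaks, and no peak is
ever accepted — the regression tests freeze this. Detection works as intended
on realistic trains whose rhythm decays by 1 s (e.g. renewal trains, whose
phase diffuses). Second, with 5-ms bins an oscillation needs a period of
several bins to be resolvable; periods near 10 ms sit at the binning limit.

## The coarse-tree classifier

A CART-style tree grown best-first with Gini's diversity index, capped at
three binary splits (four leaves), no surrogate splits. Candidate thresholds
are midpoints between consecutive distinct sorted values of each feature;
descent sends values < threshold left and ≥ threshold right. Leaf labels are
the majority class, ties resolved to the class with the larger training prior,
then to the canonical order control < ataxia < dystonia < tremor. Class priors
are empirical (training counts are unequal: 25 control vs 20 per disease
group).

**Determinism and tie-breaking.** Impurity decreases are compared in exact
rational arithmetic (Python `fractions`), so equal decreases are genuine ties
rather than float accidents. On cleanly separated classes — exactly what the
synthetic archetypes produce — *several* features can induce the identical
label partition, making the Gini decrease tie exactly; whatever rule breaks
the tie silently decides which parameter is reported as "the best
differentiator". The rule here, fixed a priori: prefer the split whose
threshold lies in the widest value gap relative to the node's feature range
(the most robust boundary), then the lowest feature index, then the lowest
threshold, then the earliest-created leaf. Row order of the training table
never matters. The exhaustive-search test oracle implements the same rules
independently.

In practice, on synthetic archetypal cohorts the root split lands on
`skewness` (widest relative margin), the control/ataxia node splits on `cv2`
or `cv` (their margins are statistically indistinguishable — both measure
regularity), and the dystonia/tremor node splits on `median_ifr`, whose margin
between the slow dystonia generator (~70 Hz median IFR) and the bursty tremor
generator (~155 Hz) is far wider than that of `isi25`. Real recordings, where
rate features overlap between groups, can select differently: the split
*variables* are a property of the data distribution, not of the algorithm.

**Model selection protocol.** Twelve stratified train/validation partitions at
the reference sizes (train 25/20/20/20, validation 8/4/4/4 per class), drawn
without replacement from RNG streams derived from (seed, split id). The
original partitions were not published, so the protocol — not the historical
splits — is what is reproduced. The selected model maximizes validation
accuracy; ties prefer fewer distinct split features, then the lower split id.
Threshold values are recovered from data and stored in the model JSON, never
hard-coded.

## Cohort statistics

* **Two-proportion z-test**: pooled proportion, no continuity correction —
  validated by exact reproduction of published z values (2.1128 and −2.094) on
  the corresponding counts. Degenerate pooled proportions (0 or 1) return
  z = 0 with a warning.
* **Enrichment chi-square**: 2×2 (df 1, no continuity correction) built
  one-vs-rest on both margins — origin group vs all other groups × signature
  vs all other signatures. The exact contingency construction behind the
  published tests is not stated; one-vs-rest is the assumption here. The
  identity z² = chi² on the same counts cross-checks both routes.
* **ANOVA + Tukey**: one-way ANOVA with Tukey–Kramer HSD (unequal group
  sizes; `scipy.stats.tukey_hsd`), cross-checked against statsmodels. The
  all-identical degenerate case returns F = 0 with all adjusted p = 1.
* **Tremor peak power**: mean-removed, Hann-windowed single full-segment
  periodogram (density scaling, so total power integrates to the signal
  variance within 1%); the peak is the maximum on (0, 30] Hz, excluding the
  zero-frequency bin. No Welch averaging — segmenting is not part of the
  reference procedure.

## Synthetic data generator

Renewal/mixture models per phenotype, each chosen as the simplest process
landing in the phenotype's qualitative regime with margins wide enough for
threshold recovery:

| phenotype | process | key resulting features |
|---|---|---|
| control | gamma renewal, shape 3, mean ISI 12 ms | ~83 spikes/s, CV2 ≈ 0.63, skewness ≈ 0.12 |
| ataxia | gamma renewal, shape 80, mean ISI 12 ms | CV2 ≈ 0.13, skewness ≈ 0 (very regular) |
| dystonia | mixture: p=0.85 gamma(2, mean 15 ms), else pause gamma(2, mean 150 ms) | ~28 spikes/s, skewness ≈ 0.82, isi25 ≈ 27% |
| tremor | 10-Hz cycles: burst of 1+Poisson(4) spikes, intra-burst ISIs gamma(5, mean 6 ms), rest of cycle silent, ±5 ms onset jitter | ~50 spikes/s, skewness ≈ 1.0, isi25 ≈ 20%, 100-ms autocorrelogram peak |

Per-cell RNG streams derive from (master seed, cell index) and are recorded in
the train metadata, giving bitwise reproducibility with independent streams.

What the generator does *not* emulate — and hence what passing tests do not
show about real recordings: measurement noise and sorting errors; overlap of
feature distributions between groups (real control and tremor firing rates
overlap; synthetic ones do not — which is why held-out accuracy here is ~100%
while published per-class rates on real data are 54–88%); slow nonstationarity
within a recording; and rhythm decay in the tremor train (the fixed 10-Hz
clock keeps autocorrelogram structure at 1-s lags, so the tail-noise-based
oscillation acceptance never fires on synthetic tremor cells, even though the
100-ms burst-period peak is plainly present in the raw autocorrelogram).

**Optogenetic paradigms** are modeled by thinning a homogeneous Poisson
process (default base rate 80 Hz, a typical control nuclei rate):
r(t) = base_rate·(1 − g·s(t)), with s(t) the light waveform — 50-Hz square
pulses (ataxia), the same pulses in ≥1-s blocks with 75%-probability 250-ms
pauses (dystonia), or 100-Hz pulses amplitude-modulated by a 10-Hz parabolic
envelope with a 50-ms off phase (tremor). Thinning with no rebound dynamics is
deliberately minimal: inhibition acts only while light is on. A consequence is
that the time-averaged rate drop is shallow (the tremor waveform's mean is
1/6), so thinned trains reach skewness ≈ 0.3–0.4 — well below the synthetic
archetypes — and an archetype-trained tree assigns them the control signature.
Reproducing the published majority assignments under stimulation would require
a stronger effective-inhibition model (e.g. rebound bursting after release
from inhibition), which is outside this package's scope; the limitation is
inherent to the thinning model, not a tuning issue.

## Numerical choices and problem sizes

* Timestamps in seconds (≥ µs resolution); ISIs reported in ms.
* Gini comparisons in exact rationals; margin ties compared at 1e-12.
* Autocorrelogram pair counting is O(n·k) (k = spikes within 1 s of each
  spike) and is verified against an O(n²) oracle up to 2000 spikes.
* Test and acceptance runs use cohorts of 85–105 cells, 10 master seeds for
  structure checks, 50 seeds per optogenetic paradigm, 100 000 ISIs for the
  exponential-CV limit — sizes at which every Monte-Carlo check is stable to
  well inside its asserted tolerance.

## Known limitations

* The tree reports *a* maximal-margin separating structure; on data with
  several perfect separators the reported split variables depend on the
  documented tie-break, and should be interpreted together with the margins.
* The oscillation walk assumes the 0.96–1.0 s lag window is noise; it is not
  for noise-free periodic or fixed-clock rhythmic trains.
* `mean_ifr` has infinite variance under the dystonia mixture (shape-2 fast
  component), so cohort means of that feature converge slowly.
* The CLI's `report` z-test compares one signature's proportion between two
  origin groups; multiple-comparison control across many such tests is the
  caller's responsibility.
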