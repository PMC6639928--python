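# Methods

This note documents the models and procedures implemented in `pondburst`,
the assumptions behind them, the synthetic study conditions the test suite
runs on, and the numerical choices a user may want to revisit.

## The study system

Explosive-breeding anurans reproduce in bursts of one to a few days,
triggered by heavy sustained rain filling temporary ponds. During a burst
the multi-species chorus raises the pond's sound pressure far above its
normal diel cycle. The pipeline assumes the monitoring design of such
studies: one autonomous recorder per pond sampling ~1 min every half hour
at 44.1 kHz/16 bit across a rainy season, co-located weather sensing, and
expert annotation of species presence in a subsample of recordings.

## Event detection

Each recording is reduced to the RMS of its waveform — a sound-pressure
proxy. The per-pond series is median-filtered over a centred 24-h window
(window length in samples rounded from duration/cadence and forced odd;
edges by reflection) to suppress the diel cycle and isolated spikes.
Outliers are values strictly above `Q3 + 1.5 × IQR`, with quartiles from
the whole deployment's smoothed series under the linear-interpolation
("type 7") quantile rule — the common software default; the multiplier and
the rule are parameters. Maximal outlier runs separated by less than
`merge_gap` (default 6 h) merge, and runs shorter than `min_duration`
(default 12 h) are dropped: these two defaults suppress single-sample
spikes while admitting the 24–70 h events the system produces, and they
replace the aural confirmation step a field team would perform. An
event's onset is its first flagged sample; the end is one cadence step
past the last (half-open), so an n-sample run lasts n × cadence.

Whether the quartiles should come from the raw or the smoothed series is
ambiguous in the field protocol this mirrors; both the values tested and
the quartiles here come from the smoothed series, which is the stricter
reading of "outliers in the smoothed series".

## The 48-h analysis window

Each event defines a window from 24 h before to 24 h after the onset,
partitioned into four half-open 12-h periods t1–t4. A 2-h subsample of a
window yields 24 recordings, 6 per period; ten events give the 240
annotated recordings the community analysis scrutinises.

## Weather features and onset prediction

Eight base variables (rain, temp, temp_var, rh, atm, atm_var, solrad,
phper) each yield six variants — instantaneous, lagged by 24/48/72 h, and
past-cumulative over 48/72 h — 48 predictors. Cumulation is a **sum** for
flux-like variables (rain, solar radiation; "amount in the last H hours")
and a **mean** for state variables. Observations are taken **daily** per
pond: a season of ~90 days across five ponds then yields ~435 rows after
dropping the first 72 h (incomplete history), matching the hundreds-of-
observations/2%-positive regime of seasonal monitoring data; the cadence
is a parameter. The variance variables are 24-h rolling variances of their
parent series, treated as sensor products.

The response marks the observation nearest each event onset (within half
the cadence by default). The classifier is a bagged ensemble of decision
trees (`max_features="sqrt"`), i.e. a random forest, with two choices
driven by the extreme class imbalance (~10 onsets in ~435 rows):

* `class_weight="balanced"` on the base trees, and
* `min_samples_leaf=50` for the onset pipeline. Fully grown trees isolate
  each rare positive into a pure in-bag leaf, so out-of-bag rows never
  inherit its vote and OOB recall collapses to zero; coarse leaves keep
  the balanced weights effective at prediction time. The generic
  `fit_predict_oob` keeps `min_samples_leaf=1` for balanced problems such
  as spectral-profile classification.

All error estimates are **out-of-bag**: each tree predicts only the rows
missing from its bootstrap sample, votes are aggregated per row, and
misclassification, true- and false-positive rates are computed from the
majority vote. Permutation importance is the classic per-tree measure:
each feature is permuted within a tree's OOB rows, the tree's accuracy
drop is recorded, and the mean drop over trees (5 permutation rounds by
default) is divided by its standard error — the scaled mean decrease
accuracy convention of random-forest software. Unscaled ensemble-level
drops are of order 10⁻³ here and statistically indistinguishable between
features.

An intrinsic limit worth knowing: the onset is defined as the *first*
trigger crossing, and later observations inside the same wet spell carry
strictly larger cumulative-rain values, so no static-feature classifier
can recover every exact onset row; on the default synthetic season the
test suite verifies OOB recall of onset rows of at least 0.6 (vs a 0.023
base rate), a false-positive rate of at most 0.15, and a positive
prediction within a day of the onset for at least 9 of the 10 events.

## Spectra and the D_cf index

Mean spectra use non-overlapping 512-point Hann-windowed frames;
magnitudes are averaged over frames; 256 bins (DC included, Nyquist
dropped) at sr/512 spacing. `mass` normalises the average to sum to one;
`log_profile` is `log(avg + ε·max(avg))` with ε = 10⁻¹², used as the
feature vector for classification. Amplitude scaling leaves `mass`
unchanged.

Focal call recordings qualify only when `20·log10(RMS_signal/RMS_noise)`
exceeds 30 dB (strict); the noise RMS comes from a user-marked silent
segment — marking is an input, not automated.

The cumulative spectral dissimilarity between two calls is
`D_cf = Σ_f |C1(f) − C2(f)| / (N − 1)` with C the cumulative `mass`. The
`1/(N−1)` constant is this package's normalisation: it bounds the index in
[0, 1] with the maximum attained by point masses at the grid's ends, and
makes the point-mass value exactly `|i − j|/(N − 1)`. On these normalised
spectra D_cf is the discrete 1-Wasserstein (earth-mover) distance divided
by (N−1), hence symmetric, zero only for identical masses, and triangle-
inequality-respecting.

## Crossed-DPCoA

Species are embedded by principal coordinates of the D_cf matrix
(double-centred Gram matrix of squared dissimilarities, eigendecomposition,
coordinates scaled by √eigenvalue). If a dissimilarity is not Euclidean
(eigenvalue < −10⁻⁸), the Lingoes additive correction (adding 2c to
off-diagonal squared dissimilarities, c = |most negative eigenvalue|) is
applied and logged. `"equidistant"` places all species at unit mutual
distance — the composition-only analysis.

Communities sit at the proportion-weighted centroids of their species.
The crossed analysis of factor A given factor B ("version 1": B moved to
the centre) subtracts from every community the weighted centroid of its B
level, computes A-level centroids of the centred cloud, and
eigendecomposes their weighted scatter. Community weights are uniform and
level weights are sums of member weights — the method family admits
alternatives, none dictated by the emulated protocol. Axis signs are fixed
by making the largest-magnitude species loading positive. Reported
community coordinates come in two flavours: raw projections (which remain
exactly at their species' centroids, a verifiable invariant) and
B-centred projections (the plotted configuration). The total inertia
equals the weighted sum of squared A-level centroid norms, checked against
brute force in the tests.

## Diversity indices

Richness counts nonzero proportions; Gini–Simpson is `1 − Σ pᵢ²`; Rao
quadratic entropy `Σᵢⱼ pᵢ pⱼ dᵢⱼ`. With unit distances Rao reduces to
Gini–Simpson exactly — a test identity. Presences become uniform
proportions (1/S per present species) because aural annotation scores
occurrence, not abundance; the table accepts abundance inputs unchanged.
Statistical comparison across periods (repeated-measures ANOVA and post
hocs) is delegated to standard statistical software and is out of scope;
the per-community index table is always emitted.

## The synthetic study conditions

The generator (`pondburst.synthio`) emulates the structure the analysis
assumes, with defaults frozen as the package's study conditions:

* **Season**: 5 ponds, 90 days from 10 Nov, 30-min recording cadence.
* **Rain**: hourly marked-Poisson bursts (exponential depths, mean 6 mm),
  base rate 0.02 h⁻¹ plus two Gaussian wet spells (sd 2 d, peak +0.6 h⁻¹)
  centred near days 25 and 65; each spell reaches each pond with a ±6-day
  arrival jitter, so onset dates decouple from the calendar.
* **Trigger**: an event starts at the first hour with >80 mm over the
  previous 48 h *and* >25 mm over the previous 24 h; duration uniform in
  24–70 h; refractory period of duration + 480 h. Under the defaults each
  wet spell triggers exactly one event per pond (10 per season); the test
  suite verifies the schedule against the trigger rule and the detector's
  exact recovery of it.
* **Amplitude**: RMS = base · diel · lunar · surge · noise, with a mild
  nocturnal diel cycle (peak/median 1.15), a bounded sinusoidal lunar-
  scale loudness modulation (period 29.5 d, amplitude 0.8, random phase
  per pond — moonlight strongly modulates tropical chorusing), lognormal
  per-recording noise (σ = 0.04), and a ×25 surge over each event. The
  bounded sinusoid is deliberate: its arcsine-shaped marginal puts the
  Tukey fence of the smoothed series *above* the quiet series' maximum, so
  the detector recovers onsets to one cadence step with no spurious
  events — the regime the emulated field data occupy (outbreaks far above
  anything the quiet soundscape produces).
* **Weather couplings**: temperature damping, solar attenuation and
  humidity follow *cloudiness* series that mix wetness with independent
  day-scale noise, and photoperiod is quantised to 1-min table resolution.
  These couplings are deliberately weak: the emulated system's
  non-rain variables carry only minor predictive power, and rain is the
  sole direct driver of events.
* **Species pools**: three spectrally dispersed pre-explosive species
  (0.4, 1.1, 6.5 kHz), three mid-frequency clustered explosive breeders
  (1.8, 2.5, 3.4 kHz — the two anchor frequencies are the system's
  documented mid-range calls), two shared mid-frequency species. Calls are
  Hann-windowed tone bursts (≥0.2 s, weak second harmonic) at
  species-specific rates. Within an event window the pre-explosive pool
  calls in t1–t3, the explosive pool in t3–t4, shared species throughout;
  t3 mixes both pools.
* **Annotators**: 3 observers, independent symmetric per-cell error 0.05;
  majority voting then has a closed-form per-cell error 3e²(1−e)+e³.

What the generator does **not** emulate: realistic call acoustics
(formants, amplitude modulation), propagation and attenuation, distance-
dependent SNR, overlapping-call masking, abundance variation, species
turnover between events, and observer biases that are correlated rather
than independent. Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under the stated statistical structure, not
performance on real field audio.

## Problem sizes used in the test suite

Tests run the full five-pond default season for detection and onset
prediction (435 daily observations, 500 trees, 5 permutation rounds), and
a reduced two-pond 55-day season for community analyses and the CLI;
stochastic claims (rain importance, Rao ordering) are evaluated over 20
seeds. These sizes are the package's chosen verification conditions; the
modules accept arbitrary sizes.

## Known limitations

* The detection chain's one-sample onset accuracy relies on surges that
  dwarf the quiet soundscape; weak surges near the Tukey fence blur onsets
  by design of the median filter (half-window latency).
* Exact onset-row OOB recall cannot reach 1.0 for first-crossing triggers
  (see above); event-level prediction is the meaningful metric.
* D_cf's normalising constant is a package choice; comparisons with other
  software should rescale accordingly.
* Crossed-DPCoA community/level weighting is uniform; abundance-weighted
  designs should pass explicit weights.
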