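# pondburst

Analysis of **explosive breeding events** in tropical anuran (frog and toad)
communities from long-duration pond recordings. Explosive breeders
concentrate their reproduction into a few rain-soaked days; dozens of males
of several species converge on temporary ponds and form a chorus loud
enough to dominate the local soundscape. `pondburst` turns a season of
automated recordings plus on-site weather into:

1. **Event detection** — per-recording RMS amplitude series, a 24-h running
   median to flatten the diel cycle, and the Tukey rule (values above
   `Q3 + 1.5 × IQR` of the smoothed series) to flag amplitude outbreaks,
   which are segmented into discrete breeding events of 24–70 h.
2. **Onset prediction from weather** — each of 8 weather variables
   (rainfall, temperature, temperature variance, relative humidity,
   atmospheric pressure and its variance, solar radiation, photoperiod) is
   expanded into 6 variants (instantaneous; lagged 24/48/72 h;
   past-cumulative 48/72 h), giving a 48-column predictor matrix. A bagged
   decision-tree ensemble (a random forest) classifies onset days,
   validated **out-of-bag** (OOB), with permutation importance (mean
   decrease accuracy, scaled by its standard error over trees).
3. **Community composition** — presence/absence annotations from several
   observers are majority-voted, tabulated per event and 12-h period
   (t1–t4 spanning 24 h before to 24 h after the onset), and ordinated by
   **crossed-DPCoA**: species live in a space reproducing their pairwise
   acoustic dissimilarities, communities at the centroids of their species,
   and the crossed nuisance factor (event or period) is moved to the
   centre of the space before extracting principal axes.
4. **Acoustic diversity** — mean spectra (FFT 512, no overlap, Hann
   window), the cumulative spectral dissimilarity **D_cf** between species
   calls, and per-community richness, Gini–Simpson (`1 − Σ pᵢ²`) and **Rao
   quadratic entropy** (`Σᵢⱼ pᵢ pⱼ dᵢⱼ`).

Because the field audio of such studies is rarely redistributable, the
package ships a first-class synthetic-data generator (`pondburst.synthio`)
that emulates the whole study with known ground truth: bursty two-spell
seasonal rainfall, rainfall-triggered events, diel + lunar amplitude
structure, species call templates in two pools (a spectrally dispersed
pre-explosive pool and a mid-frequency clustered explosive pool), and
imperfect annotators.

## Worked example

```python
from pondburst import (SimulationConfig, generate_weather, schedule_events,
                       generate_amplitude_series, detect_events, OnsetForest)

cfg = SimulationConfig(seed=0)           # 5 ponds, 90 days, 30-min cadence
weather, events, detected = {}, [], []
for i, site in enumerate(cfg.site_ids()):
    weather[site] = generate_weather(cfg, i)
    evs = schedule_events(weather[site], cfg, i)   # ground truth
    events += evs
    detected += detect_events(generate_amplitude_series(evs, cfg, i))

print(len(events), len(detected))        # -> 10 10
res = OnsetForest.from_weather(weather, events, n_trees=500, seed=0).fit()
print(res.summary())
```

The summary printed for this configuration ends with (abridged):

```
OOB misclassification: 0.1402
OOB true positive rate: 0.7000
OOB false positive rate: 0.1365
confusion (tp fp fn tn): 7 58 3 367
------------------------------------------------------------
top features (mean decrease accuracy):
  rain_cum72       +11.7641
  rain_cum48       +10.4373
  phper_inst       +3.7845
  ...
```

i.e. the detector recovers all ten injected events, and the past-cumulative
rainfall of the previous 48–72 h dominates onset prediction — the two
fingerprints of the explosive breeding system this package models. (The
ten onsets are 10 of 435 daily observations, so a 0.70 OOB true-positive
rate on exact onset days is ~30× enrichment over chance; at event level
9 of 10 events are predicted.)

The same pipeline is scriptable from a shell:

```bash
pondburst simulate --out ws --seed 0
pondburst detect   --rms ws/rms.csv --out ws
pondburst features --weather ws/weather.csv --events ws/events.csv --out ws
pondburst predict  --features ws/features.csv --out ws
pondburst dcf      --calls-dir ws/calls --out ws
pondburst ordinate --annotations-dir ws --events ws/events.csv \
                   --dcf ws/dcf_matrix.csv --out ws
pondburst diversity --annotations-dir ws --events ws/events.csv \
                   --dcf ws/dcf_matrix.csv --out ws
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter choices,
what the synthetic generator does and does not emulate, and known
limitations.
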