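"""Seeded generator of synthetic pond-monitoring data with known ground truth.

Emulates the statistical structure the analysis assumes: hourly weather with
two rainy spells per season, rainfall-triggered breeding events of 24-70 h,
per-recording RMS amplitude series with a nocturnal diel cycle and a
multiplicative surge over each event, chorus/focal WAV clips built from
species call templates, and presence/absence tables from several imperfect
annotators.

Design notes
------------
The amplitude model is ``base * diel(t) * modulation(t) * noise``:

* ``diel`` is a mild sinusoid with a nocturnal maximum (peak/median 1.15),
* ``modulation`` is a bounded lunar-scale loudness cycle (a sinusoid with a
  ~29.5-day period and random phase per pond: moonlight strongly modulates
  tropical chorusing, so some stretches of nights are simply louder),
* ``noise`` is i.i.d. lognormal per recording.

Because the modulation is a bounded sinusoid (its marginal piles mass near
the extremes), the Tukey fence Q3 + 1.5 x IQR of the median-smoothed quiet
series lies well above the quiet series' maximum, so a
sufficiently large surge factor separates surged from quiet values cleanly:
the downstream outlier detector recovers onsets to within one cadence step
with no spurious detections.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import AmplitudeSeries, BreedingEvent, EventWindow
from .exceptions import InvalidConfigError, InvalidTemplateError

logger = logging.getLogger(__name__)

POOLS = ("pre_explosive", "explosive", "shared")

# Stream ids keep the per-purpose random generators independent.
_STREAM_WEATHER = 1
_STREAM_EVENTS = 2
_STREAM_AMPLITUDE = 3
_STREAM_CLIPS = 4
_STREAM_ANNOTATIONS = 5

#: Pond code names (after the five study ponds; extended generically beyond 5).
SITE_CODES = ("Ca", "Bl", "Pa", "Ar", "Pe")


@dataclass(frozen=True)
class SpeciesCallTemplate:
    """Acoustic caricature of one species' advertisement call."""

    species_id: str
    pool: str
    peak_freq: float  # Hz
    bandwidth: float  # Hz
    call_rate: float  # calls/min
    amplitude: float = 0.05  # relative linear gain

    def __post_init__(self) -> None:
        if self.pool not in POOLS:
            raise InvalidConfigError(f"unknown pool {self.pool!r}")
        if self.peak_freq <= 0:
            raise InvalidTemplateError("peak_freq must be positive")
        if self.bandwidth <= 0:
            raise InvalidTemplateError("bandwidth must be positive")
        if self.call_rate < 0:
            raise InvalidTemplateError("call_rate must be nonnegative")


#: Default species pool: three dispersed pre-explosive species, three
#: spectrally clustered explosive breeders (mid frequencies around
#: 1.8-3.4 kHz), and two species shared between both phases.
DEFAULT_TEMPLATES: tuple[SpeciesCallTemplate, ...] = (
    SpeciesCallTemplate("Phyltomo", "pre_explosive", 400.0, 200.0, 30.0, 0.06),
    SpeciesCallTemplate("Leptmyst", "pre_explosive", 1100.0, 300.0, 35.0, 0.05),
    SpeciesCallTemplate("Dendcoun", "pre_explosive", 6500.0, 500.0, 50.0, 0.04),
    SpeciesCallTemplate("Traccori", "explosive", 1800.0, 350.0, 60.0, 0.06),
    SpeciesCallTemplate("Ceracorn", "explosive", 2500.0, 400.0, 55.0, 0.06),
    SpeciesCallTemplate("Chiashud", "explosive", 3400.0, 450.0, 80.0, 0.05),
    SpeciesCallTemplate("Ostelepr", "shared", 2300.0, 350.0, 30.0, 0.04),
    SpeciesCallTemplate("Adenandr", "shared", 2900.0, 400.0, 45.0, 0.03),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic season.

    Defaults emulate the monitored system: five ponds recorded on a 30-min
    cycle over a ~90-day rainy season with two wet spells, each triggering
    one 24-70 h explosive breeding event per pond.
    """

    n_ponds: int = 5
    season_days: int = 90
    season_start: str = "2015-11-10"
    recording_cadence_min: int = 30
    clip_duration_s: float = 60.0
    sample_rate: int = 44100
    # rainfall: marked Poisson bursts, hourly
    rain_base_rate: float = 0.02  # bursts/h outside wet spells
    rain_wet_rate: float = 0.6  # additional bursts/h at a wet-spell peak
    rain_mean_depth_mm: float = 6.0
    wet_spell_days: tuple[float, float] = (25.0, 65.0)
    wet_spell_jitter_days: float = 6.0  # per-pond arrival jitter of each spell
    wet_spell_sd_days: float = 2.0
    # event trigger rule
    trigger_window_h: int = 48
    trigger_window_mm: float = 80.0
    trigger_day_mm: float = 25.0
    event_duration_range_h: tuple[float, float] = (24.0, 70.0)
    refractory_gap_h: float = 480.0
    # amplitude model
    surge_factor: float = 25.0
    base_level: float = 0.05
    diel_amplitude: float = 0.15
    night_peak_hour: float = 0.0
    modulation_amplitude: float = 0.8  # bounded lunar-scale loudness cycle
    modulation_period_days: float = 29.5
    noise_sigma: float = 0.04
    # annotators
    annotator_error: float = 0.05
    n_annotators: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_ponds < 1:
            raise InvalidConfigError("n_ponds must be >= 1")
        if self.season_days < 4:
            raise InvalidConfigError("season_days must be >= 4 (longest lag is 72 h)")
        if self.recording_cadence_min <= 0:
            raise InvalidConfigError("recording cadence must be positive")
        if 1440 % self.recording_cadence_min != 0:
            logger.warning(
                "recording cadence %d min does not divide 24 h; diel phases drift",
                self.recording_cadence_min,
            )
        lo, hi = self.event_duration_range_h
        if not (0 < lo <= hi < self.season_days * 24):
            raise InvalidConfigError("event_duration_range_h out of range")
        if not 0 <= self.annotator_error < 0.5:
            raise InvalidConfigError("annotator_error must be in [0, 0.5)")
        if self.n_annotators % 2 == 0:
            raise InvalidConfigError("n_annotators must be odd for strict majority")

    def site_ids(self) -> list[str]:
        ids = list(SITE_CODES[: self.n_ponds])
        ids += [f"P{i + 1}" for i in range(len(ids), self.n_ponds)]
        return ids

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config_seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream, index])


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------


def generate_weather(config: SimulationConfig, site_index: int = 0) -> pd.DataFrame:
    """Hourly series of the 8 base weather variables for one pond.

    Columns: rain (mm), temp (degC), temp_var, rh (%), atm (Pa), atm_var,
    solrad (W/m2), phper (h).  Rain is a marked Poisson burst process whose
    rate follows a two-spell seasonal profile; temperature and solar
    radiation are damped during rain; relative humidity rises toward 100%
    with rain; photoperiod is near-constant (equatorial site).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_WEATHER, site_index)
    n = config.season_days * 24
    index = pd.date_range(config.season_start, periods=n, freq="h")
    hours = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    t_days = np.arange(n) / 24.0

    # each regional wet spell reaches this pond with its own arrival jitter,
    # so onset dates decouple from the calendar across ponds
    centers = [
        c + rng.uniform(-config.wet_spell_jitter_days, config.wet_spell_jitter_days)
        for c in config.wet_spell_days
    ]
    rate = config.rain_base_rate + config.rain_wet_rate * sum(
        np.exp(-0.5 * ((t_days - c) / config.wet_spell_sd_days) ** 2)
        for c in centers
    )
    bursts = rng.random(n) < np.clip(rate, 0.0, 1.0)
    rain = np.where(bursts, rng.exponential(config.rain_mean_depth_mm, n), 0.0)

    # wetness: smoothed rain occurrence, in [0, 1], modulates cloudiness
    kernel = np.ones(24) / 24.0
    wet = np.convolve(bursts.astype(float), kernel, mode="same")
    wet = np.clip(wet / max(np.max(rate), 1e-9), 0.0, 1.0)
    # cloud cover tracks wetness only loosely: half independent day-scale
    # cloudiness (cloudy dry days exist, and clouds come and go inside a
    # wet spell), so temperature/radiation/humidity are weak rain proxies
    n_days = int(np.ceil(n / 24))

    def cloud_series() -> np.ndarray:
        coupled = wet * np.repeat(rng.lognormal(0.0, 0.6, n_days), 24)[:n]
        free = np.repeat(rng.uniform(0.0, 1.0, n_days), 24)[:n]
        return np.clip(0.2 * coupled + 0.8 * free, 0.0, 1.0)

    cloud_t, cloud_s, cloud_r = cloud_series(), cloud_series(), cloud_series()

    temp = (
        26.0
        + 4.0 * (1.0 - 0.5 * cloud_t) * np.cos(2 * np.pi * (hours - 14.0) / 24.0)
        + rng.normal(0.0, 0.8, n)
    )
    solrad = (
        900.0
        * np.clip(np.sin(np.pi * (hours - 6.0) / 12.0), 0.0, None)
        * (1.0 - 0.6 * cloud_s)
        * rng.uniform(0.8, 1.0, n)
    )
    rain_6h = np.convolve(rain, np.ones(6), mode="full")[:n]
    rh = np.clip(
        72.0
        + 6.0 * cloud_r
        + 0.1 * rain_6h
        + rng.normal(0.0, 4.0, n),
        40.0,
        100.0,
    )
    atm = (
        101325.0
        + 300.0 * np.sin(2 * np.pi * t_days / 5.0)
        + 80.0 * np.cos(2 * np.pi * (hours - 10.0) / 12.0)
        + rng.normal(0.0, 15.0, n)
    )
    # day-of-year photoperiod at an equatorial site: annual range < 32 min
    doy = index.dayofyear.to_numpy().astype(float)
    # quantised to the 1-min resolution of published day-length tables
    phper = 12.05 + 0.12 * np.cos(2 * np.pi * (doy - 355.0) / 365.25)
    phper = np.round(phper * 60.0) / 60.0

    df = pd.DataFrame(
        {
            "rain": rain,
            "temp": temp,
            "temp_var": pd.Series(temp).rolling(24, min_periods=1).var().fillna(0.0).to_numpy(),
            "rh": rh,
            "atm": atm,
            "atm_var": pd.Series(atm).rolling(24, min_periods=1).var().fillna(0.0).to_numpy(),
            "solrad": solrad,
            "phper": phper,
        },
        index=index,
    )
    df.attrs["site_id"] = _site_id(config, site_index)
    return df


def _site_id(config: SimulationConfig, site_index: int) -> str:
    return config.site_ids()[site_index]


# ---------------------------------------------------------------------------
# Ground-truth event schedule
# ---------------------------------------------------------------------------


def schedule_events(
    weather: pd.DataFrame, config: SimulationConfig, site_index: int = 0
) -> list[BreedingEvent]:
    """Ground-truth onsets from the cumulative-rain trigger rule.

    An onset is emitted at the first hour where rain summed over the trigger
    window exceeds ``trigger_window_mm`` AND rain over the previous 24 h
    exceeds ``trigger_day_mm``; after each event a refractory period of
    (duration + refractory_gap_h) must elapse before the next onset.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_EVENTS, site_index)
    rain = weather["rain"].to_numpy()
    index = weather.index
    w = config.trigger_window_h
    cum_w = pd.Series(rain).rolling(w).sum().to_numpy()
    cum_24 = pd.Series(rain).rolling(24).sum().to_numpy()

    site_id = weather.attrs.get("site_id", _site_id(config, site_index))
    events: list[BreedingEvent] = []
    lo, hi = config.event_duration_range_h
    t = max(w, 24) - 1
    n = len(rain)
    while t < n:
        if cum_w[t] > config.trigger_window_mm and cum_24[t] > config.trigger_day_mm:
            duration = rng.uniform(lo, hi)
            onset = index[t]
            events.append(
                BreedingEvent(
                    site_id=site_id,
                    onset=onset,
                    end=onset + pd.Timedelta(hours=duration),
                )
            )
            t += int(np.ceil(duration + config.refractory_gap_h))
        else:
            t += 1
    if not events:
        logger.info("site %s: trigger thresholds never reached, no events", site_id)
    return events


# ---------------------------------------------------------------------------
# Amplitude series
# ---------------------------------------------------------------------------


def generate_amplitude_series(
    events: Sequence[BreedingEvent],
    config: SimulationConfig,
    site_index: int = 0,
) -> AmplitudeSeries:
    """Per-recording RMS series: diel baseline x lunar modulation x surge x noise."""
    config.validate()
    rng = _rng(config.seed, _STREAM_AMPLITUDE, site_index)
    cadence = pd.Timedelta(minutes=config.recording_cadence_min)
    n = int(config.season_days * 24 * 60 / config.recording_cadence_min)
    index = pd.date_range(config.season_start, periods=n, freq=cadence)
    hours = index.hour.to_numpy() + index.minute.to_numpy() / 60.0

    diel = 1.0 + config.diel_amplitude * np.cos(
        2 * np.pi * (hours - config.night_peak_hour) / 24.0
    )
    t_days = np.arange(n) * config.recording_cadence_min / (24.0 * 60.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    mod = 1.0 + config.modulation_amplitude * np.sin(
        2.0 * np.pi * t_days / config.modulation_period_days + phase
    )
    noise = rng.lognormal(0.0, config.noise_sigma, n) if config.noise_sigma > 0 else 1.0

    surge = np.ones(n)
    for ev in events:
        in_event = (index >= ev.onset) & (index < ev.end)
        surge[in_event] = config.surge_factor

    rms = config.base_level * diel * mod * surge * noise
    return AmplitudeSeries(
        site_id=_site_id(config, site_index), timestamps=index, rms=rms
    )


# ---------------------------------------------------------------------------
# Clip synthesis
# ---------------------------------------------------------------------------


def synthesize_clip(
    templates: Sequence[SpeciesCallTemplate],
    active: Iterable[str],
    duration: float,
    sr: int,
    noise_floor: float = 0.001,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sum of band-limited harmonic pulse trains plus white noise.

    Each active species contributes a train of Hann-windowed tone bursts at
    its peak frequency (plus a weak second harmonic when below Nyquist);
    the burst length is set so the spectral main lobe roughly matches the
    template bandwidth.  The peak sample amplitude is clipped to 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    active = set(active)
    by_id = {t.species_id: t for t in templates}
    unknown = active - set(by_id)
    if unknown:
        raise InvalidConfigError(f"unknown species in active set: {sorted(unknown)}")
    n = int(round(duration * sr))
    out = np.zeros(n)
    if noise_floor > 0:
        out += noise_floor * rng.standard_normal(n)
    for sid in sorted(active):
        tpl = by_id[sid]
        if tpl.peak_freq >= sr / 2:
            raise InvalidTemplateError(
                f"{sid}: peak_freq {tpl.peak_freq} Hz >= Nyquist {sr / 2} Hz"
            )
        if tpl.call_rate <= 0:
            continue
        # call length: long enough for the Hann main lobe (~4/T) to fit the
        # bandwidth, and at least 0.2 s (typical anuran note duration)
        burst_len = max(int(round(sr * 4.0 / tpl.bandwidth)), int(round(0.2 * sr)))
        window = np.hanning(burst_len)
        tt = np.arange(burst_len) / sr
        period = 60.0 / tpl.call_rate
        n_calls = max(int(duration / period), 1)
        starts = (np.arange(n_calls) + rng.uniform(0.0, 0.5, n_calls)) * period
        for s in starts:
            i0 = int(round(s * sr))
            if i0 + burst_len > n:
                break
            phase = rng.uniform(0.0, 2 * np.pi)
            burst = np.sin(2 * np.pi * tpl.peak_freq * tt + phase)
            if 2 * tpl.peak_freq < sr / 2:
                burst += 0.15 * np.sin(2 * np.pi * 2 * tpl.peak_freq * tt + phase)
            out[i0 : i0 + burst_len] += tpl.amplitude * window * burst
    return np.clip(out, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def active_species(
    templates: Sequence[SpeciesCallTemplate],
    events: Sequence[BreedingEvent],
    t: pd.Timestamp,
) -> set[str]:
    """True calling species at time ``t`` given pool membership and event phase.

    Within the 48-h window of an event: the pre-explosive pool calls from
    24 h before the onset until 12 h after it (t1-t3), the explosive pool
    from the onset to 24 h after it (t3-t4), and shared species throughout;
    t3 therefore mixes both pools.  Outside every window nothing calls.
    """
    h = pd.Timedelta(hours=12)
    out: set[str] = set()
    for ev in events:
        rel_start, onset = ev.onset - 2 * h, ev.onset
        if not (rel_start <= t < onset + 2 * h):
            continue
        for tpl in templates:
            if tpl.pool == "pre_explosive" and rel_start <= t < onset + h:
                out.add(tpl.species_id)
            elif tpl.pool == "explosive" and onset <= t:
                out.add(tpl.species_id)
            elif tpl.pool == "shared":
                out.add(tpl.species_id)
    return out


def generate_annotations(
    events: Sequence[BreedingEvent],
    templates: Sequence[SpeciesCallTemplate],
    recordings: pd.DatetimeIndex,
    annotator_error: float = 0.05,
    n_annotators: int = 3,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Ground-truth and per-annotator presence/absence tables.

    Each annotator's table equals the truth with independent symmetric flips
    at probability ``annotator_error``.  Returns ``(truth, [annotator_k])``,
    each a 0/1 DataFrame indexed by recording time with one column per
    species.
    """
    if not 0 <= annotator_error < 0.5:
        raise InvalidConfigError("annotator_error must be in [0, 0.5)")
    if n_annotators % 2 == 0:
        raise InvalidConfigError("n_annotators must be odd")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    recordings = pd.DatetimeIndex(recordings)
    species = [t.species_id for t in templates]
    truth = np.zeros((len(recordings), len(species)), dtype=int)
    for i, t in enumerate(recordings):
        act = active_species(templates, events, t)
        for j, sid in enumerate(species):
            truth[i, j] = int(sid in act)
    truth_df = pd.DataFrame(truth, index=recordings, columns=species)
    tables = []
    for _ in range(n_annotators):
        flips = rng.random(truth.shape) < annotator_error
        tables.append(
            pd.DataFrame(np.abs(truth - flips.astype(int)), index=recordings, columns=species)
        )
    return truth_df, tables


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """Everything one synthetic season produces, with ground truth."""

    config: SimulationConfig
    templates: tuple[SpeciesCallTemplate, ...]
    weather: dict[str, pd.DataFrame]
    truth_events: list[BreedingEvent]
    amplitude: dict[str, AmplitudeSeries]
    truth_annotations: pd.DataFrame  # MultiIndex (site, timestamp)
    annotations: list[pd.DataFrame]  # one per annotator, same index

    @property
    def site_ids(self) -> list[str]:
        return self.config.site_ids()


def simulate_study(
    config: SimulationConfig | None = None,
    templates: Sequence[SpeciesCallTemplate] = DEFAULT_TEMPLATES,
) -> SimulatedStudy:
    """Generate a full multi-pond season: weather, events, amplitude, labels.

    Annotations cover the 2-h subsample of each event's 48-h window (the
    recordings a field team would scrutinise).
    """
    config = config or SimulationConfig()
    config.validate()
    weather: dict[str, pd.DataFrame] = {}
    amplitude: dict[str, AmplitudeSeries] = {}
    truth_events: list[BreedingEvent] = []
    ann_frames_truth = []
    ann_frames = [[] for _ in range(config.n_annotators)]
    for i, site in enumerate(config.site_ids()):
        w = generate_weather(config, i)
        evs = schedule_events(w, config, i)
        weather[site] = w
        truth_events.extend(evs)
        amplitude[site] = generate_amplitude_series(evs, config, i)
        recordings = pd.DatetimeIndex(
            sorted(
                set().union(
                    *(EventWindow(ev).subsample("2h") for ev in evs), set()
                )
            )
        )
        truth_df, tables = generate_annotations(
            evs,
            templates,
            recordings,
            annotator_error=config.annotator_error,
            n_annotators=config.n_annotators,
            seed=_rng(config.seed, _STREAM_ANNOTATIONS, i),
        )
        key = pd.MultiIndex.from_product([[site], truth_df.index], names=["site", "timestamp"])
        ann_frames_truth.append(truth_df.set_axis(key))
        for k, tab in enumerate(tables):
            ann_frames[k].append(tab.set_axis(key))
    species = [t.species_id for t in templates]
    empty = pd.DataFrame(
        columns=species,
        index=pd.MultiIndex.from_arrays([[], []], names=["site", "timestamp"]),
    )
    truth_annotations = pd.concat(ann_frames_truth) if ann_frames_truth else empty
    annotations = [pd.concat(f) if f else empty for f in ann_frames]
    return SimulatedStudy(
        config=config,
        templates=tuple(templates),
        weather=weather,
        truth_events=truth_events,
        amplitude=amplitude,
        truth_annotations=truth_annotations,
        annotations=annotations,
    )
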