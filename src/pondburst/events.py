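"""Detection of explosive breeding events in pond amplitude time series.

The detection chain mirrors standard long-duration soundscape practice:
per-recording RMS levels form a regular time series, a 24-h running median
removes the diel cycle and isolated spikes, values above the Tukey fence
``Q3 + 1.5 x IQR`` of the smoothed series are flagged as outliers, and
maximal outlier runs become candidate breeding events.  A 48-h analysis
window around each onset is discretised into four 12-h periods (t1..t4)
for the downstream community analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

PERIODS = ("t1", "t2", "t3", "t4")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AmplitudeSeries:
    """Regular per-recording RMS level series for one pond.

    Parameters
    ----------
    site_id : str
        Pond identifier.
    timestamps : pandas.DatetimeIndex
        Recording start times; strictly increasing on a constant cadence.
    rms : numpy.ndarray
        Per-recording root-mean-square level (linear units, >= 0).
    smoothed : numpy.ndarray, optional
        Median-filtered ``rms``; present only after :func:`median_smooth`.
    """

    site_id: str
    timestamps: pd.DatetimeIndex
    rms: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.rms = np.asarray(self.rms, dtype=float)
        if len(self.timestamps) != len(self.rms):
            raise InvalidInputError("timestamps and rms must be aligned")
        if len(self.timestamps) >= 2:
            steps = np.diff(self.timestamps.asi8)
            if steps.min() <= 0 or steps.min() != steps.max():
                raise InvalidInputError(
                    "timestamps must be strictly increasing on a constant step"
                )
        if np.any(self.rms < 0):
            raise InvalidInputError("rms levels must be nonnegative")

    @property
    def cadence(self) -> pd.Timedelta:
        if len(self.timestamps) < 2:
            raise InvalidInputError("cadence undefined for fewer than 2 samples")
        return pd.Timedelta(self.timestamps[1] - self.timestamps[0])

    def __len__(self) -> int:
        return len(self.rms)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"site": self.site_id, "timestamp": self.timestamps, "rms": self.rms}
        )
        if self.smoothed is not None:
            out["smoothed"] = self.smoothed
        return out


@dataclass(frozen=True)
class BreedingEvent:
    """A detected (or ground-truth) amplitude outbreak at one pond."""

    site_id: str
    onset: pd.Timestamp
    end: pd.Timestamp
    peak_level: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.onset:
            raise InvalidInputError("event end must be after onset")

    @property
    def duration_h(self) -> float:
        return (self.end - self.onset) / pd.Timedelta(hours=1)


@dataclass(frozen=True)
class EventWindow:
    """The 48-h window around an event onset, split into four 12-h periods.

    Periods are half-open, relative to the onset:
    t1 = [-24, -12) h, t2 = [-12, 0) h, t3 = [0, 12) h, t4 = [12, 24) h.
    """

    event: BreedingEvent
    event_label: str = ""

    @property
    def start(self) -> pd.Timestamp:
        return self.event.onset - pd.Timedelta(hours=24)

    @property
    def end(self) -> pd.Timestamp:
        return self.event.onset + pd.Timedelta(hours=24)

    def period_bounds(self) -> dict[str, tuple[pd.Timestamp, pd.Timestamp]]:
        onset = self.event.onset
        h = pd.Timedelta(hours=12)
        return {
            "t1": (onset - 2 * h, onset - h),
            "t2": (onset - h, onset),
            "t3": (onset, onset + h),
            "t4": (onset + h, onset + 2 * h),
        }

    def period_of(self, t: pd.Timestamp) -> str | None:
        """Period containing ``t`` under the half-open convention, else None."""
        for name, (lo, hi) in self.period_bounds().items():
            if lo <= t < hi:
                return name
        return None

    def subsample(self, step: str | pd.Timedelta = "2h") -> pd.DatetimeIndex:
        """Regular subsample of the window, anchored at its start (half-open)."""
        step = pd.Timedelta(step)
        return pd.date_range(self.start, self.end - step, freq=step)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_rms(clip: np.ndarray) -> float:
    """Root-mean-square of a waveform: sqrt(mean(x^2)) over all samples."""
    clip = np.asarray(clip, dtype=float)
    if clip.size == 0:
        raise InvalidInputError("cannot compute RMS of an empty waveform")
    return float(np.sqrt(np.mean(np.square(clip))))


def median_smooth(
    series: AmplitudeSeries, window: str | pd.Timedelta = "24h"
) -> AmplitudeSeries:
    """Running median of the RMS series over a centred window.

    The window length in samples is ``round(window / cadence)``, forced odd
    by adding one; edges are handled by reflection, so the output has the
    same length as the input.
    """
    window = pd.Timedelta(window)
    cadence = series.cadence
    if window < 3 * cadence:
        raise InvalidInputError("median window must span at least 3 cadence steps")
    size = int(round(window / cadence))
    if size % 2 == 0:
        size += 1
    if len(series) < size:
        raise InvalidInputError(
            f"series of {len(series)} samples is shorter than the {size}-sample window"
        )
    smoothed = median_filter(series.rms, size=size, mode="reflect")
    return replace(series, smoothed=smoothed)


def detect_outliers(values: Sequence[float], multiplier: float = 1.5) -> np.ndarray:
    """Boolean mask of values strictly above ``Q3 + multiplier * IQR``.

    Quartiles are computed over the whole series with the linear-interpolation
    quantile rule (the ubiquitous "type 7").
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise InvalidInputError("need at least 4 values to estimate quartiles")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    fence = q3 + multiplier * (q3 - q1)
    return x > fence


def segment_events(
    mask: np.ndarray,
    timestamps: pd.DatetimeIndex,
    merge_gap: str | pd.Timedelta = "6h",
    min_duration: str | pd.Timedelta = "12h",
    site_id: str = "",
    levels: np.ndarray | None = None,
) -> list[BreedingEvent]:
    """Turn an outlier mask into events.

    Maximal runs of True are extracted; runs separated by a gap shorter than
    ``merge_gap`` are merged; merged runs shorter than ``min_duration`` are
    dropped.  An event's onset is the first flagged sample and its end is one
    cadence step past the last flagged sample (half-open), so a run of n
    samples has duration ``n * cadence``.
    """
    mask = np.asarray(mask, dtype=bool)
    timestamps = pd.DatetimeIndex(timestamps)
    if len(mask) != len(timestamps):
        raise InvalidInputError("mask and timestamps must be aligned")
    merge_gap = pd.Timedelta(merge_gap)
    min_duration = pd.Timedelta(min_duration)
    if not mask.any():
        return []
    cadence = timestamps[1] - timestamps[0] if len(timestamps) > 1 else pd.Timedelta(0)

    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]  # runs are [start, stop)

    merged: list[list[int]] = [[int(starts[0]), int(stops[0])]]
    for s, e in zip(starts[1:], stops[1:]):
        gap = (s - merged[-1][1]) * cadence
        if gap < merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    events = []
    for s, e in merged:
        duration = (e - s) * cadence
        if duration < min_duration:
            continue
        peak = float(np.max(levels[s:e])) if levels is not None else None
        events.append(
            BreedingEvent(
                site_id=site_id,
                onset=timestamps[s],
                end=timestamps[e - 1] + cadence,
                peak_level=peak,
            )
        )
    return events


def detect_events(
    series: AmplitudeSeries,
    window: str | pd.Timedelta = "24h",
    multiplier: float = 1.5,
    merge_gap: str | pd.Timedelta = "6h",
    min_duration: str | pd.Timedelta = "12h",
) -> list[BreedingEvent]:
    """Full detection chain: median smoothing, IQR outliers, run segmentation."""
    smoothed = median_smooth(series, window=window)
    mask = detect_outliers(smoothed.smoothed, multiplier=multiplier)
    events = segment_events(
        mask,
        smoothed.timestamps,
        merge_gap=merge_gap,
        min_duration=min_duration,
        site_id=series.site_id,
        levels=smoothed.smoothed,
    )
    logger.info("site %s: %d event(s) detected", series.site_id, len(events))
    return events


def make_windows(
    events: Iterable[BreedingEvent], series: AmplitudeSeries
) -> list[EventWindow]:
    """One 48-h window per event; events whose window exceeds the series are dropped."""
    windows = []
    t0 = series.timestamps[0]
    t1 = series.timestamps[-1] + series.cadence
    counter: dict[str, int] = {}
    for ev in events:
        counter[ev.site_id] = counter.get(ev.site_id, 0) + 1
        w = EventWindow(ev, event_label=f"{ev.site_id}{counter[ev.site_id]}")
        if w.start < t0 or w.end > t1:
            logger.warning(
                "event at %s dropped: 48-h window exceeds series bounds", ev.onset
            )
            continue
        windows.append(w)
    return windows


def events_to_frame(events: Iterable[BreedingEvent]) -> pd.DataFrame:
    rows = [
        {
            "site": ev.site_id,
            "onset": ev.onset,
            "end": ev.end,
            "duration_h": ev.duration_h,
            "peak_level": ev.peak_level,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=["site", "onset", "end", "duration_h", "peak_level"])


def events_from_frame(df: pd.DataFrame) -> list[BreedingEvent]:
    return [
        BreedingEvent(
            site_id=str(r["site"]),
            onset=pd.Timestamp(r["onset"]),
            end=pd.Timestamp(r["end"]),
            peak_level=(None if pd.isna(r.get("peak_level")) else float(r["peak_level"])),
        )
        for _, r in df.iterrows()
    ]
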