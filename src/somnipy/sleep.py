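"""Actigraphy sleep-interval detection with ambient-light moderation.

The detector scores sleep from wrist motion alone, in six steps:

1. centered moving average of the motion channel (smoothing);
2. quiescence detection: maximal runs of epochs whose smoothed motion stays
   at or below a threshold, never bridging a cleaning-segment break;
3. light moderation: the ambient-light channel either vetoes candidate
   intervals whose mean light is too bright (a quiet afternoon in a lit
   room is not sleep) or gates them down to their dark core;
4. merging: candidate intervals separated by short wake gaps are combined;
5. shallow-interval exclusion: intervals shorter than 30 min are dropped;
6. depth classification: intervals longer than 3 h are labelled deep.

Both duration cutoffs are strict: an exactly-30-min interval is kept, an
exactly-180-min interval is not deep. Heart rate is carried through to the
report for display only; it never enters scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import time

import numpy as np
import pandas as pd

from .records import DayWindow, RecordError, SensorRecord, segment_days

__all__ = [
    "DetectorConfig",
    "SleepInterval",
    "SleepReport",
    "moving_average",
    "detect_quiescence",
    "apply_light_moderator",
    "merge_intervals",
    "drop_shallow",
    "classify_depth",
    "analyze_sleep",
]

_MINUTE = pd.Timedelta(minutes=1)


@dataclass
class DetectorConfig:
    """Tunable parameters of the sleep detector.

    ``motion_threshold`` and ``light_threshold`` default to ``None``,
    meaning record-relative values are derived at analysis time (10% of the
    95th percentile of smoothed motion; the 20th percentile of light plus
    10% of the 20th-to-80th percentile spread). Record-relative defaults
    tolerate device-to-device gain differences without retuning.

    ``light_mode`` selects how ambient light moderates motion-derived
    candidates: ``off`` (ignore light), ``gate`` (trim each candidate to its
    largest contiguous dark run), or ``veto`` (discard candidates whose mean
    light is above threshold). The default is ``veto``.
    """

    ma_window: int = 5
    motion_threshold: float | None = None
    light_threshold: float | None = None
    light_mode: str = "veto"
    merge_gap: float = 10.0
    min_duration: float = 30.0
    deep_duration: float = 180.0
    day_boundary: time = time(12, 0)

    def __post_init__(self) -> None:
        if self.ma_window < 1 or self.ma_window % 2 == 0:
            raise ValueError("ma_window must be an odd integer >= 1")
        for name in ("motion_threshold", "light_threshold"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if not (0 < self.min_duration < self.deep_duration):
            raise ValueError("need 0 < min_duration < deep_duration")
        if self.light_mode not in ("off", "gate", "veto"):
            raise ValueError("light_mode must be off, gate, or veto")

    def resolve(self, smoothed_motion: np.ndarray,
                light: np.ndarray | None) -> "DetectorConfig":
        """Fill record-relative thresholds with concrete values."""
        cfg = self
        if cfg.motion_threshold is None:
            thr = 0.10 * float(np.nanpercentile(smoothed_motion, 95))
            cfg = replace(cfg, motion_threshold=thr)
        if cfg.light_threshold is None and light is not None:
            p20 = float(np.nanpercentile(light, 20))
            p80 = float(np.nanpercentile(light, 80))
            cfg = replace(cfg, light_threshold=p20 + 0.10 * (p80 - p20))
        return cfg


@dataclass
class SleepInterval:
    """A detected sleep span, half-open in time."""

    start: pd.Timestamp
    end: pd.Timestamp
    depth: str = "sleep"  # "sleep" or "deep"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must be after start")

    @property
    def duration(self) -> float:
        """Duration in minutes."""
        return (self.end - self.start) / _MINUTE

    @property
    def midpoint(self) -> pd.Timestamp:
        return self.start + (self.end - self.start) / 2

    def to_dict(self) -> dict:
        return {
            "start": self.start.isoformat(),
            "end": self.end.isoformat(),
            "duration_min": self.duration,
            "depth": self.depth,
        }


@dataclass
class SleepReport:
    """Per-day-window detection results for one record."""

    windows: list[tuple[DayWindow, list[SleepInterval], float]]
    config: DetectorConfig = field(default_factory=DetectorConfig)
    device_label: str = ""

    @property
    def nightly_minutes(self) -> list[float]:
        return [total for _, _, total in self.windows]

    def to_dict(self) -> dict:
        return {
            "device_label": self.device_label,
            "windows": [
                {
                    **w.summary(),
                    "intervals": [iv.to_dict() for iv in ivs],
                    "total_sleep_min": total,
                }
                for w, ivs, total in self.windows
            ],
        }


# ---------------------------------------------------------------------------
# Pipeline steps


def moving_average(values, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the series edges.

    Near a boundary the window simply loses the samples that would fall
    outside the series, so the output has the same length as the input.
    """
    x = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window > len(x):
        raise ValueError("window longer than series")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(len(x))
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, len(x))
    return (csum[hi] - csum[lo]) / (hi - lo)


def _segment_bounds(times: pd.DatetimeIndex, period: float,
                    segments) -> np.ndarray:
    """Boolean array marking where a new contiguous segment starts."""
    new_seg = np.zeros(len(times), dtype=bool)
    new_seg[0] = True
    if segments is not None:
        starts = {pd.Timestamp(s) for s, _ in segments}
        new_seg |= np.array([t in starts for t in times])
    else:
        deltas = (times[1:] - times[:-1]) / pd.Timedelta(seconds=1)
        new_seg[1:] = deltas > 1.5 * period
    return new_seg


def detect_quiescence(
    times: pd.DatetimeIndex,
    smoothed_motion,
    motion_threshold: float,
    period: float,
    segments=None,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Maximal runs of epochs with smoothed motion <= threshold.

    Returns half-open intervals ``[first epoch start, last epoch end)``.
    Runs never bridge a cleaning-segment break.
    """
    x = np.asarray(smoothed_motion, dtype=float)
    if len(x) == 0:
        raise RecordError("empty series")
    quiet = x <= motion_threshold
    new_seg = _segment_bounds(times, period, segments)

    step = pd.Timedelta(seconds=period)
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    run_start: int | None = None
    for i in range(len(x)):
        if quiet[i] and (run_start is None or not new_seg[i]):
            if run_start is None:
                run_start = i
        elif quiet[i] and new_seg[i]:
            intervals.append((times[run_start], times[i - 1] + step))
            run_start = i
        elif run_start is not None:
            intervals.append((times[run_start], times[i - 1] + step))
            run_start = None
    if run_start is not None:
        intervals.append((times[run_start], times[-1] + step))
    return intervals


def apply_light_moderator(
    intervals,
    times: pd.DatetimeIndex,
    light,
    cfg: DetectorConfig,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Moderate motion-derived candidates with the ambient-light channel.

    ``off``: unchanged. ``gate``: each interval is trimmed to its largest
    contiguous run of epochs whose light is at or below threshold (an
    all-bright interval disappears). ``veto``: an interval whose mean epoch
    light exceeds threshold is discarded whole.
    """
    if cfg.light_mode == "off":
        return list(intervals)
    if light is None:
        raise RecordError("light channel required when light_mode != off")
    lx = np.asarray(light, dtype=float)
    thr = cfg.light_threshold
    if thr is None:
        raise RecordError("light_threshold unresolved")
    step = pd.Timedelta(seconds=_infer_period(times))

    out: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for start, end in intervals:
        sel = (times >= start) & (times < end)
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            continue
        vals = lx[idx]
        if cfg.light_mode == "veto":
            if np.nanmean(vals) <= thr:
                out.append((start, end))
            continue
        # gate: largest contiguous dark run inside the interval
        dark = vals <= thr
        best_len, best_lo = 0, -1
        lo = None
        for j, d in enumerate(np.append(dark, False)):
            if d and lo is None:
                lo = j
            elif not d and lo is not None:
                if j - lo > best_len:
                    best_len, best_lo = j - lo, lo
                lo = None
        if best_len > 0:
            a = times[idx[best_lo]]
            b = times[idx[best_lo + best_len - 1]] + step
            out.append((a, b))
    return out


def _infer_period(times: pd.DatetimeIndex) -> float:
    if len(times) < 2:
        return 30.0
    return float(np.median(np.diff(times.view("int64"))) / 1e9)


def merge_intervals(intervals, merge_gap: float) -> list:
    """Combine consecutive intervals whose separating gap is short.

    Gaps of at most ``merge_gap`` minutes are absorbed (gap included in the
    merged span), applied transitively left to right. Idempotent.
    """
    ivs = sorted(intervals, key=lambda iv: iv[0])
    for a, b in zip(ivs, ivs[1:]):
        if b[0] < a[1]:
            raise ValueError(f"overlapping intervals: {a} and {b}")
    gap = merge_gap * _MINUTE
    out: list = []
    for iv in ivs:
        if out and (iv[0] - out[-1][1]) <= gap:
            out[-1] = (out[-1][0], iv[1])
        else:
            out.append((iv[0], iv[1]))
    return out


def drop_shallow(intervals, min_duration: float = 30.0) -> list:
    """Remove intervals lasting less than ``min_duration`` minutes.

    The comparison is strict: an exactly-30-min interval is retained.
    """
    return [iv for iv in intervals
            if (iv[1] - iv[0]) / _MINUTE >= min_duration]


def classify_depth(intervals, deep_duration: float = 180.0) -> list[SleepInterval]:
    """Label intervals deep iff strictly longer than ``deep_duration`` min."""
    out = []
    for start, end in intervals:
        depth = "deep" if (end - start) / _MINUTE > deep_duration else "sleep"
        out.append(SleepInterval(start=start, end=end, depth=depth))
    return out


# ---------------------------------------------------------------------------
# End-to-end


def analyze_sleep(record: SensorRecord, cfg: DetectorConfig | None = None
                  ) -> SleepReport:
    """Run the full detector on a (cleaned) record.

    An interval crossing a day boundary is credited to the window that
    contains its midpoint. Per-window total sleep is the sum of interval
    durations credited to that window.
    """
    if cfg is None:
        cfg = DetectorConfig()
    if not record.has_channel("motion"):
        raise RecordError("record has no motion channel")

    times = record.timestamps
    motion = record.channel("motion")
    light = record.channel("light") if record.has_channel("light") else None
    if cfg.light_mode != "off" and light is None:
        raise RecordError("light channel required when light_mode != off")

    window = min(cfg.ma_window, len(motion) if len(motion) % 2 else len(motion) - 1)
    window = max(window, 1)
    smoothed = moving_average(motion, window)
    rcfg = cfg.resolve(smoothed, light)

    raw = detect_quiescence(times, smoothed, rcfg.motion_threshold,
                            record.nominal_period, record.segments)
    moderated = apply_light_moderator(raw, times, light, rcfg)
    merged = merge_intervals(moderated, rcfg.merge_gap)
    kept = drop_shallow(merged, rcfg.min_duration)
    classified = classify_depth(kept, rcfg.deep_duration)

    windows = segment_days(record, boundary=cfg.day_boundary)
    report_rows: list[tuple[DayWindow, list[SleepInterval], float]] = []
    for w in windows:
        ivs = [iv for iv in classified if w.start <= iv.midpoint < w.end]
        total = float(sum(iv.duration for iv in ivs))
        report_rows.append((w, ivs, total))
    return SleepReport(windows=report_rows, config=rcfg,
                       device_label=record.device_label)
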