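"""Photoplethysmography (PPG) waveform processing.

A reflective PPG signal is a large quasi-DC component (average blood
volume, drifting slowly with respiration) plus a small pulsatile AC
component synchronous with the cardiac cycle. Beats are found on the AC
component after moving-median baseline removal; ambient light measured
with the emitter off is subtracted from the emitter-on signal, with
overload flagged when ambient light reaches the supply level; heart-rate
samples recorded during wrist movement are masked as motion artifacts
using the concurrent accelerometer channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .records import RecordError, SensorRecord

__all__ = [
    "PPGWaveform",
    "HeartRateSeries",
    "ambient_subtract",
    "detect_beats",
    "square_wave_beats",
    "compute_hr",
    "mask_motion_artifacts",
]


@dataclass
class PPGWaveform:
    """A raw PPG trace: detector units sampled at ``fs`` Hz (default 200)."""

    values: np.ndarray
    fs: float = 200.0
    start_time: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("1970-01-01"))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite")

    @property
    def duration(self) -> float:
        """Seconds of signal."""
        return len(self.values) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from start."""
        return np.arange(len(self.values)) / self.fs


@dataclass
class HeartRateSeries:
    """Windowed heart-rate estimates with a validity mask."""

    timestamps: pd.DatetimeIndex
    bpm: np.ndarray
    mask: np.ndarray  # "valid" | "artifact" per sample

    def __post_init__(self) -> None:
        self.bpm = np.asarray(self.bpm, dtype=float)
        self.mask = np.asarray(self.mask, dtype=object)
        if not (len(self.timestamps) == len(self.bpm) == len(self.mask)):
            raise ValueError("timestamps, bpm, mask must have equal length")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        valid = self.mask == "valid"
        if np.any((self.bpm[valid] <= 20) | (self.bpm[valid] >= 300)):
            raise ValueError("valid bpm must lie in (20, 300)")

    @property
    def valid(self) -> np.ndarray:
        return self.mask == "valid"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hr": self.bpm, "mask": self.mask},
            index=pd.DatetimeIndex(self.timestamps, name="timestamp"),
        )


def ambient_subtract(on_signal, off_signal, supply_level: float):
    """Subtract the emitter-off (ambient) reading from the emitter-on one.

    Returns ``(corrected, overload)``: ``corrected = max(on - off, 0)`` and
    ``overload`` is True wherever the ambient reading reaches the supply
    level, at which point the detector saturates and the corrected value is
    not meaningful.
    """
    on = np.asarray(on_signal, dtype=float)
    off = np.asarray(off_signal, dtype=float)
    if on.shape != off.shape:
        raise ValueError("on/off signals must have the same shape")
    if supply_level <= 0:
        raise ValueError("supply_level must be positive")
    corrected = np.maximum(on - off, 0.0)
    overload = off >= supply_level
    return corrected, overload


def detect_beats(wave: PPGWaveform, min_rr: float = 0.3) -> pd.DatetimeIndex:
    """Locate beat times on the AC component of a PPG waveform.

    The quasi-DC baseline is removed with a centered moving median over a
    1-second window; peaks are then required to exceed an adaptive
    prominence (30% of the AC inter-percentile amplitude) and to be at
    least ``min_rr`` seconds apart, guarding against counting dicrotic
    notches as beats.
    """
    x = wave.values
    if len(x) < int(2 * wave.fs):
        raise RecordError("waveform shorter than 2 s")
    win = int(round(wave.fs)) | 1  # odd, ~1 s
    baseline = (
        pd.Series(x).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    ac = x - baseline

    lo, hi = np.percentile(ac, [2, 98])
    amp = hi - lo
    if amp <= 1e-12 or amp <= 1e-9 * max(1.0, np.abs(x).max()):
        return pd.DatetimeIndex([])
    prominence = 0.3 * amp
    distance = max(1, int(round(min_rr * wave.fs)))
    idx, _ = find_peaks(ac, prominence=prominence, distance=distance)
    # no pulsatile component: residual baseline wobble (e.g. respiratory
    # drift the median filter cannot fully remove) yields "peaks" slower
    # than any heartbeat; reject trains below the 20 bpm physiological floor
    if len(idx) >= 2:
        mean_rr = float(np.mean(np.diff(idx))) / wave.fs
        if mean_rr > 60.0 / 20.0:
            return pd.DatetimeIndex([])
    elif len(idx) <= 1:
        return pd.DatetimeIndex([])
    return pd.DatetimeIndex(
        wave.start_time + pd.to_timedelta(idx / wave.fs, unit="s")
    )


def square_wave_beats(wave: PPGWaveform) -> pd.DatetimeIndex:
    """Beat times from a sensor operating in digital square-wave mode.

    Each rising edge of the (binary) output marks one beat.
    """
    x = wave.values
    if len(x) < 2:
        raise RecordError("waveform too short")
    level = 0.5 * (x.min() + x.max())
    high = x > level
    edges = np.flatnonzero(~high[:-1] & high[1:]) + 1
    return pd.DatetimeIndex(
        wave.start_time + pd.to_timedelta(edges / wave.fs, unit="s")
    )


def compute_hr(beats: pd.DatetimeIndex, window: float = 60.0) -> HeartRateSeries:
    """Windowed heart rate from an ordered sequence of beat times.

    The beat train is cut into consecutive ``window``-second bins anchored
    at the first beat; each bin with at least two beats yields
    ``bpm = 60 / mean inter-beat interval``, timestamped at the bin center.
    Bins with fewer than two beats are omitted.
    """
    beats = pd.DatetimeIndex(beats)
    if len(beats) < 2:
        raise RecordError("need at least 2 beats")
    t = (beats - beats[0]) / pd.Timedelta(seconds=1)
    t = np.asarray(t, dtype=float)
    nbins = int(t[-1] // window) + 1

    stamps, bpms = [], []
    for k in range(nbins):
        sel = (t >= k * window) & (t < (k + 1) * window)
        tb = t[sel]
        if len(tb) < 2:
            continue
        mean_rr = float(np.mean(np.diff(tb)))
        stamps.append(beats[0] + pd.Timedelta(seconds=(k + 0.5) * window))
        bpms.append(60.0 / mean_rr)
    return HeartRateSeries(
        timestamps=pd.DatetimeIndex(stamps),
        bpm=np.array(bpms, dtype=float),
        mask=np.array(["valid"] * len(bpms), dtype=object),
    )


def mask_motion_artifacts(
    hr: HeartRateSeries,
    motion: SensorRecord,
    motion_threshold: float,
) -> HeartRateSeries:
    """Flag heart-rate samples recorded during wrist movement.

    An hr sample is an artifact when the motion epoch containing its
    timestamp has motion above ``motion_threshold``. Optical pulse readings
    taken while the user moves are unreliable, so the concurrent
    accelerometer channel is the natural exclusion criterion.
    """
    times = motion.timestamps
    vals = motion.channel("motion")
    period = pd.Timedelta(seconds=motion.nominal_period)
    if len(hr.timestamps) == 0:
        return hr
    if hr.timestamps[-1] < times[0] or hr.timestamps[0] >= times[-1] + period:
        raise RecordError("hr series and motion record do not overlap in time")

    pos = np.searchsorted(times.view("int64"), hr.timestamps.view("int64"),
                          side="right") - 1
    mask = np.array(hr.mask, dtype=object)
    for i, p in enumerate(pos):
        if p < 0:
            continue
        if hr.timestamps[i] < times[p] + period and vals[p] > motion_threshold:
            mask[i] = "artifact"
    return HeartRateSeries(timestamps=hr.timestamps, bpm=hr.bpm.copy(),
                           mask=mask)
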