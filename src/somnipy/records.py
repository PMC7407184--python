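"""Sensor-record containers and plumbing shared by every pipeline stage.

A recording is a timestamped multi-channel series sampled twice per minute
by default: motion magnitude (accelerometer counts, arbitrary units),
ambient light (photodetector units) and, optionally, heart rate in bpm.
The on-disk dialect is a plain CSV with header ``timestamp,motion,light,hr``,
ISO-8601 local timestamps and empty cells for missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorRecord",
    "DayWindow",
    "CleaningReport",
    "RecordError",
    "load_record",
    "write_record",
    "clean_discontinuities",
    "segment_days",
    "to_epochs",
]

CHANNELS = ("motion", "light", "hr")

#: default timestamp-gap tolerance, in multiples of the nominal period
DEFAULT_GAP_TOLERANCE = 3.0


class RecordError(ValueError):
    """Raised for malformed, empty, or inconsistent recordings."""


@dataclass
class SensorRecord:
    """A timestamped multi-channel recording from one device.

    Parameters
    ----------
    data : pandas.DataFrame
        Indexed by a strictly increasing ``DatetimeIndex`` (1-second
        resolution is sufficient); columns ``motion`` and ``light``
        (non-negative floats) and optionally ``hr`` (bpm, NaN = missing).
    nominal_period : float
        Nominal seconds between consecutive samples (30 = twice per minute).
    device_label : str
        Free-text device identifier.
    channel_meta : dict
        Per-channel gain/saturation annotations (informational only).
    segments : list of (Timestamp, Timestamp) or None
        Contiguous spans established by :func:`clean_discontinuities`;
        ``None`` means the record has not been cleaned.
    """

    data: pd.DataFrame
    nominal_period: float = 30.0
    device_label: str = ""
    channel_meta: dict = field(default_factory=dict)
    segments: list[tuple[pd.Timestamp, pd.Timestamp]] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.nominal_period <= 0:
            raise RecordError("nominal_period must be positive")
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise RecordError("record index must be a DatetimeIndex")
        if len(df) == 0:
            raise RecordError("empty record")
        # duplicates are tolerated here (clean_discontinuities collapses
        # them); going backwards in time is never valid
        diffs = np.diff(df.index.view("int64"))
        if np.any(diffs < 0):
            i = int(np.argmax(diffs < 0))
            raise RecordError(
                "timestamps decrease at "
                f"{df.index[i]} -> {df.index[i + 1]}"
            )
        for ch in ("motion", "light"):
            if ch not in df.columns:
                raise RecordError(f"missing required channel {ch!r}")
            vals = df[ch].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise RecordError(f"negative values in channel {ch!r}")
        if "hr" in df.columns:
            hr = df["hr"].to_numpy(dtype=float)
            present = np.isfinite(hr)
            if np.any((hr[present] <= 0) | (hr[present] >= 300)):
                raise RecordError("hr values must lie in (0, 300) bpm")

    # -- convenience accessors -------------------------------------------
    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def start(self) -> pd.Timestamp:
        return self.data.index[0]

    @property
    def end(self) -> pd.Timestamp:
        """End of the record span: last timestamp + one nominal period."""
        return self.data.index[-1] + pd.Timedelta(seconds=self.nominal_period)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise RecordError(f"record has no channel {name!r}")
        return self.data[name].to_numpy(dtype=float)

    def has_channel(self, name: str) -> bool:
        return name in self.data.columns and bool(
            np.isfinite(self.data[name].to_numpy(dtype=float)).any()
        )

    def slice(self, start: pd.Timestamp, end: pd.Timestamp) -> pd.DataFrame:
        """Samples with start <= t < end."""
        idx = self.data.index
        return self.data.loc[(idx >= start) & (idx < end)]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DayWindow:
    """One boundary-to-boundary (default noon-to-noon) slice of a record.

    ``boundary`` is the nominal window start (e.g. Monday 12:00) even when
    the record only partially covers the window; ``start``/``end`` are
    clipped to the record span.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    samples: pd.DataFrame
    partial: bool = False
    boundary: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise RecordError("DayWindow end must be after start")
        if self.boundary is None:
            self.boundary = self.start

    @property
    def span_hours(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)

    def summary(self) -> dict:
        return {
            "start": self.start.isoformat(),
            "end": self.end.isoformat(),
            "n_samples": int(len(self.samples)),
            "partial": bool(self.partial),
        }


@dataclass
class CleaningReport:
    """Outcome of discontinuity cleaning."""

    n_gaps: int
    n_dropped: int
    segments: list[tuple[pd.Timestamp, pd.Timestamp]]

    def to_dict(self) -> dict:
        return {
            "n_gaps": self.n_gaps,
            "n_dropped": self.n_dropped,
            "segments": [
                {"start": s.isoformat(), "end": e.isoformat()}
                for s, e in self.segments
            ],
        }


# ---------------------------------------------------------------------------
# Reading and writing


def load_record(
    path,
    dialect: str = "somnipy-csv",
    device_label: str | None = None,
) -> SensorRecord:
    """Read a recording from the package CSV dialect.

    The dialect has a header row ``timestamp,motion,light[,hr]``, ISO-8601
    timestamps, numeric channel columns, and empty cells for missing values.
    Missing hr cells yield absent (NaN) hr, never zero.
    """
    if dialect != "somnipy-csv":
        raise RecordError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError:
        raise RecordError(f"empty record file: {path}") from None
    if len(df) == 0:
        raise RecordError(f"empty record file: {path}")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "timestamp" not in cols or "motion" not in cols or "light" not in cols:
        raise RecordError(
            f"{path}: header must contain timestamp,motion,light (got {cols})"
        )

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = ts.isna()
    if bad.any():
        line = int(np.argmax(bad.to_numpy())) + 2  # header is line 1
        raise RecordError(f"{path}: unparseable timestamp at line {line}")
    ts_ns = ts.to_numpy().astype("datetime64[ns]").astype("int64")
    nonmono = np.diff(ts_ns) <= 0
    if nonmono.any():
        i = int(np.argmax(nonmono))
        raise RecordError(
            f"{path}: non-monotone timestamps at lines {i + 2}-{i + 3} "
            f"({ts.iloc[i]} -> {ts.iloc[i + 1]})"
        )

    out = pd.DataFrame(index=pd.DatetimeIndex(ts.to_numpy(), name="timestamp"))
    for ch in CHANNELS:
        if ch in cols:
            out[ch] = pd.to_numeric(df[ch], errors="raise").to_numpy(dtype=float)
    if "hr" not in out.columns:
        out["hr"] = np.nan

    if len(out) >= 2:
        period = float(np.median(np.diff(ts_ns)) / 1e9)
    else:
        period = 30.0
    return SensorRecord(out, nominal_period=period,
                        device_label=device_label or "")


def write_record(record: SensorRecord, path) -> None:
    """Write a record in the package CSV dialect (lossless round-trip)."""
    df = record.data.copy()
    df.index = df.index.strftime("%Y-%m-%dT%H:%M:%S")
    df.index.name = "timestamp"
    df.to_csv(path, float_format="%.10g", na_rep="")


# ---------------------------------------------------------------------------
# Cleaning, segmentation, epoch aggregation


def clean_discontinuities(
    record: SensorRecord, gap_tolerance: float = DEFAULT_GAP_TOLERANCE
) -> tuple[SensorRecord, CleaningReport]:
    """Collapse duplicate timestamps and mark timing gaps as segment breaks.

    A gap is an inter-sample interval exceeding ``gap_tolerance`` nominal
    periods; the record is not resampled, but the retained contiguous spans
    are recorded so that later stages never bridge a discontinuity.
    Idempotent: cleaning a cleaned record changes nothing.
    """
    if gap_tolerance < 1:
        raise RecordError("gap_tolerance must be >= 1")
    df = record.data
    dup = df.index.duplicated(keep="first")
    n_dropped = int(dup.sum())
    df = df[~dup]
    if len(df) == 0:
        raise RecordError("empty record")

    tol = pd.Timedelta(seconds=gap_tolerance * record.nominal_period)
    period = pd.Timedelta(seconds=record.nominal_period)
    deltas = df.index[1:] - df.index[:-1]
    breaks = np.flatnonzero(deltas > tol)
    n_gaps = int(len(breaks))

    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(df) - 1]))
    segments = [(df.index[a], df.index[b] + period) for a, b in zip(starts, ends)]

    cleaned = SensorRecord(
        df,
        nominal_period=record.nominal_period,
        device_label=record.device_label,
        channel_meta=dict(record.channel_meta),
        segments=segments,
    )
    return cleaned, CleaningReport(n_gaps=n_gaps, n_dropped=n_dropped,
                                   segments=segments)


def segment_days(
    record: SensorRecord, boundary: time = time(12, 0)
) -> list[DayWindow]:
    """Tile the record span into boundary-to-boundary 24-h windows.

    The default boundary is noon, so each window runs noon-to-noon. Partial
    leading/trailing windows are retained and flagged rather than dropped,
    which keeps week-start offsets between two devices analyzable.
    """
    span_start = record.start
    span_end = record.end
    anchor = pd.Timestamp(datetime.combine(span_start.date(), boundary))
    if anchor > span_start:
        anchor -= pd.Timedelta(days=1)

    windows: list[DayWindow] = []
    w0 = anchor
    while w0 < span_end:
        w1 = w0 + pd.Timedelta(days=1)
        start = max(w0, span_start)
        end = min(w1, span_end)
        samples = record.slice(w0, w1)
        partial = (end - start) < pd.Timedelta(days=1)
        windows.append(DayWindow(start=start, end=end, samples=samples,
                                 partial=partial, boundary=w0))
        w0 = w1
    return windows


_AGGREGATORS = {"mean": np.nanmean, "sum": np.nansum, "max": np.nanmax}


def to_epochs(
    record: SensorRecord,
    epoch_len: float,
    aggregator: str | dict[str, str] = "mean",
    anchor: pd.Timestamp | None = None,
) -> SensorRecord:
    """Aggregate raw samples into fixed, half-open, left-labelled epochs.

    Each output sample at time ``t`` aggregates every input sample in
    ``[t, t + epoch_len)``; empty epochs are omitted. ``aggregator`` is one
    of mean/sum/max, either globally or per channel. ``anchor`` fixes the
    grid origin (default: the first sample), which lets two devices share an
    epoch grid.
    """
    if epoch_len < record.nominal_period:
        raise RecordError(
            f"epoch_len {epoch_len} s shorter than nominal period "
            f"{record.nominal_period} s"
        )
    if isinstance(aggregator, str):
        agg_by_channel = {ch: aggregator for ch in record.data.columns}
    else:
        agg_by_channel = {ch: aggregator.get(ch, "mean")
                          for ch in record.data.columns}
    for name in agg_by_channel.values():
        if name not in _AGGREGATORS:
            raise RecordError(f"unknown aggregator {name!r}")

    origin = record.start if anchor is None else pd.Timestamp(anchor)
    df = record.data
    if anchor is not None:
        df = df[df.index >= origin]
        if len(df) == 0:
            raise RecordError("no samples at or after the anchor")
    step = pd.Timedelta(seconds=epoch_len)
    bins = ((df.index - origin) // step).astype(int)

    grouped = df.groupby(bins)
    pieces = {}
    for ch in df.columns:
        fn = _AGGREGATORS[agg_by_channel[ch]]
        with np.errstate(invalid="ignore"):
            pieces[ch] = grouped[ch].agg(
                lambda s, fn=fn: fn(s.to_numpy(dtype=float))
                if np.isfinite(s.to_numpy(dtype=float)).any()
                else np.nan
            )
    out = pd.DataFrame(pieces)
    out.index = pd.DatetimeIndex(origin + out.index * step, name="timestamp")
    return SensorRecord(
        out,
        nominal_period=float(epoch_len),
        device_label=record.device_label,
        channel_meta=dict(record.channel_meta),
        segments=record.segments,
    )
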