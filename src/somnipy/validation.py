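"""Two-device agreement statistics.

To validate one wearable against a reference device worn on the same
wrist, both recordings are epoch-aggregated onto a shared grid over their
overlapping span, channel agreement is summarized by the Pearson
correlation and an ordinary-least-squares calibration line ``y = m x + b``
(reference device on x), and the two sleep analyses are compared night by
night as percent duration differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import RecordError, SensorRecord, clean_discontinuities, to_epochs
from .sleep import DetectorConfig, SleepReport, analyze_sleep

__all__ = [
    "AlignedPair",
    "ComparisonResult",
    "align",
    "pearson_r",
    "linear_fit",
    "duration_diffs",
    "compare_devices",
]


@dataclass
class AlignedPair:
    """Paired per-channel epoch series from two devices on a common grid."""

    timestamps: pd.DatetimeIndex
    a_values: pd.DataFrame
    b_values: pd.DataFrame

    def __post_init__(self) -> None:
        if not (len(self.timestamps) == len(self.a_values) == len(self.b_values)):
            raise ValueError("aligned series must have equal lengths")

    def channel(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        return (self.a_values[name].to_numpy(dtype=float),
                self.b_values[name].to_numpy(dtype=float))


@dataclass
class ComparisonResult:
    """Agreement summary between a reference device A and a test device B."""

    r: dict[str, float] = field(default_factory=dict)
    slope: dict[str, float] = field(default_factory=dict)
    intercept: dict[str, float] = field(default_factory=dict)
    night_diffs: list[float] = field(default_factory=list)
    max_diff: float = float("nan")
    mean_diff: float = float("nan")
    median_diff: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.r,
            "slope": self.slope,
            "intercept": self.intercept,
            "night_diffs_percent": list(self.night_diffs),
            "max_diff_percent": self.max_diff,
            "mean_diff_percent": self.mean_diff,
            "median_diff_percent": self.median_diff,
        }


def align(rec_a: SensorRecord, rec_b: SensorRecord,
          epoch_len: float = 60.0) -> AlignedPair:
    """Epoch-aggregate two records onto a shared grid over their overlap.

    The grid is anchored at the later of the two start times (devices are
    rarely switched on simultaneously); epochs missing in either record
    are dropped pairwise.
    """
    start = max(rec_a.start, rec_b.start)
    end = min(rec_a.end, rec_b.end)
    if end <= start:
        raise RecordError("records do not overlap in time")
    ea = to_epochs(rec_a, epoch_len, aggregator="mean", anchor=start)
    eb = to_epochs(rec_b, epoch_len, aggregator="mean", anchor=start)
    da = ea.data[ea.data.index < end]
    db = eb.data[eb.data.index < end]
    common = da.index.intersection(db.index)
    if len(common) == 0:
        raise RecordError("no common epochs after alignment")
    return AlignedPair(timestamps=common,
                       a_values=da.loc[common], b_values=db.loc[common])


def pearson_r(x, y) -> float:
    """Product-moment correlation of two paired series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


def linear_fit(x, y) -> tuple[float, float]:
    """Ordinary least squares line ``y = m x + b`` (vertical residuals)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("slope undefined for constant x")
    m, b = np.polyfit(x, y, 1)
    return float(m), float(b)


def duration_diffs(report_a: SleepReport, report_b: SleepReport) -> dict:
    """Per-night percent sleep-duration differences, device A as reference.

    For each shared day window, ``diff = |dur_b - dur_a| / dur_a * 100``.
    Windows where both devices report zero sleep contribute nothing; a
    window with zero reference sleep but nonzero test sleep is an error
    (the percent difference is undefined).
    """
    wa = [w for w, _, _ in report_a.windows]
    wb = [w for w, _, _ in report_b.windows]
    if len(wa) != len(wb) or any(a.boundary != b.boundary
                                 for a, b in zip(wa, wb)):
        raise ValueError("reports cover different day windows")
    diffs: list[float] = []
    for (_, _, ta), (_, _, tb) in zip(report_a.windows, report_b.windows):
        if ta == 0 and tb == 0:
            continue
        if ta == 0:
            raise ValueError("zero reference duration in a compared window")
        diffs.append(abs(tb - ta) / ta * 100.0)
    if not diffs:
        raise ValueError("no windows with sleep to compare")
    return {
        "night_diffs": diffs,
        "max_diff": float(np.max(diffs)),
        "mean_diff": float(np.mean(diffs)),
        "median_diff": float(np.median(diffs)),
    }


def compare_devices(
    rec_a: SensorRecord,
    rec_b: SensorRecord,
    cfg: DetectorConfig | None = None,
    epoch_len: float = 60.0,
    channels: tuple[str, ...] = ("motion", "light"),
) -> ComparisonResult:
    """Full agreement workflow: align, correlate, calibrate, compare sleep."""
    if cfg is None:
        cfg = DetectorConfig()
    pair = align(rec_a, rec_b, epoch_len)

    result = ComparisonResult()
    for ch in channels:
        xa, xb = pair.channel(ch)
        keep = np.isfinite(xa) & np.isfinite(xb)
        xa, xb = xa[keep], xb[keep]
        result.r[ch] = pearson_r(xa, xb)
        m, b = linear_fit(xa, xb)
        result.slope[ch] = m
        result.intercept[ch] = b

    ca, _ = clean_discontinuities(rec_a)
    cb, _ = clean_discontinuities(rec_b)
    rep_a = analyze_sleep(ca, cfg)
    rep_b = analyze_sleep(cb, cfg)
    # restrict the night comparison to windows both reports cover
    shared = {w.boundary for w, _, _ in rep_a.windows} & {
        w.boundary for w, _, _ in rep_b.windows}
    rep_a = SleepReport(
        [row for row in rep_a.windows if row[0].boundary in shared],
        config=rep_a.config, device_label=rep_a.device_label)
    rep_b = SleepReport(
        [row for row in rep_b.windows if row[0].boundary in shared],
        config=rep_b.config, device_label=rep_b.device_label)
    d = duration_diffs(rep_a, rep_b)
    result.night_diffs = d["night_diffs"]
    result.max_diff = d["max_diff"]
    result.mean_diff = d["mean_diff"]
    result.median_diff = d["median_diff"]
    return result
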