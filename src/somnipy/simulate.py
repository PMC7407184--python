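"""Ground-truthed synthetic wearable streams.

The simulator emulates the recording regime of a week-long wrist-worn
study: motion and ambient light sampled twice per minute, a nightly sleep
schedule producing quiescent dark blocks, a diurnal light profile with
linear dawn/dusk ramps, raw 200 Hz PPG, and two-device twins rendered from
one latent truth stream through per-device affine gains, noise, clipping
and start offsets. Every stream is deterministic given the seed, and the
injected schedule is returned as ground truth so parameter recovery can be
scored exactly.

Default study conditions: seven noon-to-noon days starting on a Monday,
30-s epochs, nightly sleep onsets around 23:00 with durations of
7.7, 9, 8.1, 8.3, 6.2, 7.5 and 7.6 hours.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import time

import numpy as np
import pandas as pd

from .ppg import PPGWaveform
from .records import SensorRecord

__all__ = [
    "NightSpec",
    "QuiescentBlock",
    "PPGParams",
    "DeviceParams",
    "SimConfig",
    "SimTruth",
    "simulate_week",
    "simulate_ppg",
    "simulate_two_devices",
]

_DEFAULT_ONSETS = ("23:12", "22:56", "23:30", "23:05", "00:18", "23:45", "23:20")
_DEFAULT_DURATIONS = (462.0, 540.0, 486.0, 498.0, 372.0, 450.0, 456.0)


def _parse_clock(value) -> time:
    if isinstance(value, time):
        return value
    h, m = str(value).split(":")
    return time(int(h), int(m))


@dataclass
class NightSpec:
    """One scheduled night: onset clock time on day ``day`` of the study.

    Onsets before noon belong to the small hours of the following calendar
    day (an 00:18 onset on study day 4 happens early on day 5).
    """

    day: int
    onset: str = "23:00"
    duration_min: float = 450.0


@dataclass
class QuiescentBlock:
    """An extra motionless block (e.g. an afternoon nap or a watch left on
    a table); ``dark`` controls whether the room light is off during it."""

    day: int
    start: str = "13:00"
    duration_min: float = 175.0
    dark: bool = True


@dataclass
class PPGParams:
    """Waveform-synthesis parameters for :func:`simulate_ppg`."""

    ac_amplitude: float = 1.0
    dc_level: float = 10.0
    resp_drift_freq: float = 0.25
    resp_drift_amp: float = 0.5
    noise_sd: float = 0.0


@dataclass
class DeviceParams:
    """Per-device rendering of the latent truth stream."""

    motion_gain: float = 1.0
    motion_offset: float = 0.0
    light_gain: float = 1.0
    light_offset: float = 0.0
    noise_sd: float = 0.0
    epoch_len: float | None = None
    start_delay_s: float = 0.0
    light_saturation: float | None = None
    label: str = ""


@dataclass
class SimConfig:
    """Study-condition parameters for the stream simulator."""

    days: int = 7
    epoch_len: float = 30.0
    start: str = "2020-07-06T12:00:00"  # a Monday noon
    sleep_schedule: list[NightSpec] | None = None
    extra_blocks: list[QuiescentBlock] = field(default_factory=list)
    wake_motion_mean: float = 40.0
    wake_motion_var: float = 400.0
    sleep_motion_rate: float = 0.05
    sleep_motion_mean: float = 3.0
    light_day: float = 300.0
    light_night: float = 1.0
    light_noise_sd: float = 0.3
    light_noise_frac: float = 0.03
    light_saturation: float | None = None
    dawn: str = "06:00"
    dusk: str = "19:30"
    ramp_min: float = 45.0
    include_hr: bool = True
    ppg: PPGParams = field(default_factory=PPGParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not (0 <= self.sleep_motion_rate <= 1):
            raise ValueError("sleep_motion_rate must be in [0, 1]")
        for name in ("wake_motion_mean", "wake_motion_var", "light_day",
                     "light_night", "epoch_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sleep_schedule is None:
            n = min(self.days, len(_DEFAULT_ONSETS))
            self.sleep_schedule = [
                NightSpec(day=i, onset=_DEFAULT_ONSETS[i],
                          duration_min=_DEFAULT_DURATIONS[i])
                for i in range(n)
            ]


@dataclass
class SimTruth:
    """Injected ground truth: quiescent spans and the injected HR profile."""

    true_intervals: list[dict]
    true_hr: object | None = None

    def spans(self, kind: str | None = None) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        return [
            (pd.Timestamp(iv["start"]), pd.Timestamp(iv["end"]))
            for iv in self.true_intervals
            if kind is None or iv["kind"] == kind
        ]

    def to_json(self, path) -> None:
        payload = {"true_intervals": self.true_intervals}
        if self.true_hr is not None:
            payload["true_hr"] = self.true_hr
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _schedule_spans(cfg: SimConfig) -> list[dict]:
    start = pd.Timestamp(cfg.start)
    day0 = pd.Timestamp(start.date())
    rec_end = start + pd.Timedelta(days=cfg.days)
    spans: list[dict] = []
    for night in cfg.sleep_schedule:
        onset_t = _parse_clock(night.onset)
        day = day0 + pd.Timedelta(days=night.day)
        if onset_t < time(12, 0):
            day += pd.Timedelta(days=1)
        s = day + pd.Timedelta(hours=onset_t.hour, minutes=onset_t.minute)
        e = s + pd.Timedelta(minutes=night.duration_min)
        spans.append({"start": s.isoformat(), "end": e.isoformat(),
                      "kind": "sleep", "dark": True})
    for block in cfg.extra_blocks:
        t = _parse_clock(block.start)
        day = day0 + pd.Timedelta(days=block.day)
        if t < time(12, 0):
            day += pd.Timedelta(days=1)
        s = day + pd.Timedelta(hours=t.hour, minutes=t.minute)
        e = s + pd.Timedelta(minutes=block.duration_min)
        spans.append({"start": s.isoformat(), "end": e.isoformat(),
                      "kind": "quiescent", "dark": bool(block.dark)})
    spans.sort(key=lambda d: d["start"])
    for a, b in zip(spans, spans[1:]):
        if b["start"] < a["end"]:
            raise ValueError(f"overlapping scheduled spans: {a} / {b}")
    for d in spans:
        if pd.Timestamp(d["start"]) < start or pd.Timestamp(d["end"]) > rec_end:
            raise ValueError(f"scheduled span outside simulated range: {d}")
    return spans


def _daylight_fraction(tod_min: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """0 at night, 1 in full daylight, linear ramps around dawn and dusk."""
    dawn = _parse_clock(cfg.dawn)
    dusk = _parse_clock(cfg.dusk)
    dawn_m = dawn.hour * 60 + dawn.minute
    dusk_m = dusk.hour * 60 + dusk.minute
    up = np.clip((tod_min - dawn_m) / cfg.ramp_min, 0, 1)
    down = np.clip((dusk_m + cfg.ramp_min - tod_min) / cfg.ramp_min, 0, 1)
    return np.minimum(up, down)


def simulate_week(cfg: SimConfig | None = None) -> tuple[SensorRecord, SimTruth]:
    """Simulate a multi-day motion/light/HR record plus its ground truth."""
    if cfg is None:
        cfg = SimConfig()
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start)
    n = int(round(cfg.days * 86400 / cfg.epoch_len))
    times = start + pd.to_timedelta(np.arange(n) * cfg.epoch_len, unit="s")

    spans = _schedule_spans(cfg)
    t64 = times.view("int64")
    quiescent = np.zeros(n, dtype=bool)
    lights_off = np.zeros(n, dtype=bool)
    for d in spans:
        s = pd.Timestamp(d["start"]).value
        e = pd.Timestamp(d["end"]).value
        sel = (t64 >= s) & (t64 < e)
        quiescent |= sel
        if d["dark"]:
            lights_off |= sel

    # motion: gamma bursts awake, sparse small movements while quiescent
    k = cfg.wake_motion_mean ** 2 / max(cfg.wake_motion_var, 1e-12)
    theta = cfg.wake_motion_var / max(cfg.wake_motion_mean, 1e-12)
    motion = rng.gamma(k, theta, size=n)
    moves = rng.random(n) < cfg.sleep_motion_rate
    small = rng.exponential(cfg.sleep_motion_mean, size=n)
    motion[quiescent] = np.where(moves[quiescent], small[quiescent], 0.0)

    # light: diurnal profile, forced dark during sleep / dark blocks
    tod_min = (times.hour * 60 + times.minute + times.second / 60).to_numpy()
    frac = _daylight_fraction(tod_min, cfg)
    light = cfg.light_night + (cfg.light_day - cfg.light_night) * frac
    light[lights_off] = cfg.light_night
    noise_sd = cfg.light_noise_sd + cfg.light_noise_frac * light
    light = np.maximum(light + rng.normal(0, 1, size=n) * noise_sd, 0.0)
    if cfg.light_saturation is not None:
        light = np.minimum(light, cfg.light_saturation)

    df = pd.DataFrame({"motion": motion, "light": light},
                      index=pd.DatetimeIndex(times, name="timestamp"))
    if cfg.include_hr:
        hr = np.where(quiescent, 55.0, 72.0) + rng.normal(0, 1.5, size=n)
        df["hr"] = np.clip(hr, 35.0, 180.0)
    else:
        df["hr"] = np.nan

    record = SensorRecord(df, nominal_period=cfg.epoch_len,
                          device_label="sim")
    return record, SimTruth(true_intervals=spans)


def simulate_ppg(
    hr_profile,
    duration_s: float = 60.0,
    fs: float = 200.0,
    params: PPGParams | None = None,
    seed: int = 0,
    start_time: pd.Timestamp | str = "2020-07-06T23:00:00",
) -> tuple[PPGWaveform, SimTruth]:
    """Synthesize a PPG waveform with a known instantaneous heart rate.

    ``hr_profile`` is either a constant bpm or an array of per-sample bpm
    values (length ``duration_s * fs``). The waveform is a quasi-DC level
    plus a slow sinusoidal respiratory drift plus a raised-cosine pulse per
    beat at the instantaneous rate, plus optional Gaussian noise.
    """
    if params is None:
        params = PPGParams()
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(duration_s * fs))
    bpm = np.broadcast_to(np.asarray(hr_profile, dtype=float), (n,)).copy() \
        if np.ndim(hr_profile) == 0 else np.asarray(hr_profile, dtype=float)
    if len(bpm) != n:
        raise ValueError("hr_profile length must equal duration_s * fs")
    if np.any(bpm <= 0):
        raise ValueError("hr_profile must be positive")
    if fs <= 2 * bpm.max() / 60:
        raise ValueError("fs must exceed twice the beat frequency")

    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    # cardiac phase in cycles; start mid-cycle so the first peak is interior
    phase = 0.5 + np.concatenate(([0.0], np.cumsum(bpm[:-1] / 60.0) / fs))
    frac = np.mod(phase, 1.0)
    width = 0.35  # pulse width as a fraction of the cycle
    d = np.minimum(frac, 1.0 - frac)
    pulse = np.where(d < width / 2,
                     0.5 * (1 + np.cos(2 * np.pi * d / width)), 0.0)

    values = (
        params.dc_level
        + params.resp_drift_amp * np.sin(2 * np.pi * params.resp_drift_freq * t)
        + params.ac_amplitude * pulse
    )
    if params.noise_sd > 0:
        values = values + rng.normal(0, params.noise_sd, size=n)

    wave = PPGWaveform(values=values, fs=fs,
                       start_time=pd.Timestamp(start_time))
    # true beats: integer phase crossings
    crossings = np.flatnonzero(np.floor(phase[1:]) > np.floor(phase[:-1])) + 1
    truth = SimTruth(
        true_intervals=[],
        true_hr={"bpm": bpm.tolist() if len(np.unique(bpm)) <= 64
                 else [float(bpm[0]), float(bpm[-1])],
                 "beat_times_s": (crossings / fs).tolist()},
    )
    return wave, truth


def _render_device(latent: SensorRecord, dev: DeviceParams,
                   rng: np.random.Generator) -> SensorRecord:
    from .records import to_epochs  # local import avoids cycle at module load

    df = latent.data.copy()
    if dev.start_delay_s > 0:
        cut = latent.start + pd.Timedelta(seconds=dev.start_delay_s)
        df = df[df.index >= cut]
    motion = df["motion"].to_numpy() * dev.motion_gain + dev.motion_offset
    light = df["light"].to_numpy() * dev.light_gain + dev.light_offset
    if dev.noise_sd > 0:
        motion = motion + rng.normal(0, dev.noise_sd, size=len(df))
        light = light + rng.normal(0, dev.noise_sd, size=len(df))
    df["motion"] = np.maximum(motion, 0.0)
    light = np.maximum(light, 0.0)
    if dev.light_saturation is not None:
        light = np.minimum(light, dev.light_saturation)
    df["light"] = light
    rec = SensorRecord(df, nominal_period=latent.nominal_period,
                       device_label=dev.label)
    if dev.epoch_len is not None and dev.epoch_len > latent.nominal_period:
        rec = to_epochs(rec, dev.epoch_len, aggregator="mean")
    return rec


def simulate_two_devices(
    cfg: SimConfig | None = None,
    dev_a: DeviceParams | None = None,
    dev_b: DeviceParams | None = None,
) -> tuple[SensorRecord, SensorRecord, SimTruth]:
    """Render one latent truth stream through two device transforms.

    Each device applies its own affine channel gains/offsets, independent
    Gaussian noise, optional light clipping (saturation), optional start
    delay and optional coarser epoch length — the mechanisms by which two
    wearables recording the same wrist produce different numbers.
    """
    if cfg is None:
        cfg = SimConfig()
    if dev_a is None:
        dev_a = DeviceParams(label="device_a")
    if dev_b is None:
        dev_b = DeviceParams(label="device_b")
    latent, truth = simulate_week(cfg)
    rng_a, rng_b = np.random.default_rng(cfg.seed).spawn(2)
    rec_a = _render_device(latent, dev_a, rng_a)
    rec_b = _render_device(latent, dev_b, rng_b)
    return rec_a, rec_b, truth
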