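# Methods

## Scope and model

`somnipy` treats a wrist-worn recording as a timestamped multi-channel
series — motion magnitude (arbitrary accelerometer counts), ambient light
(arbitrary photodetector units), optional heart rate in bpm or a raw
200 Hz PPG waveform — sampled nominally twice per minute for motion/light.
Sleep is modelled purely behaviourally: a sleep interval is a sustained
run of low smoothed motion, confirmed (not contradicted) by darkness.
No physiological staging is attempted; heart rate is carried through to
reports for display but never enters scoring.

## Detector parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `ma_window` | 5 | epochs (2.5 min at 30-s epochs) | long enough to suppress single-epoch twitches, short enough to keep onset/offset resolution ~1 min |
| `motion_threshold` | 10% of the 95th percentile of smoothed motion | counts | record-relative, so two devices with different gains score the same behaviour; the 95th percentile is a robust "active wake" scale |
| `light_threshold` | p20 + 0.1·(p80 − p20) of the light channel | detector units | p20 estimates the dark baseline; the 10% headroom toward the bright level (p80) keeps noisy dark epochs below threshold. A bare low percentile fails whenever ≥ 40% of epochs are dark, because a genuine night's *mean* light then straddles it |
| `light_mode` | `veto` | — | the minimal defensible use of light as a moderator: discard quiescent intervals whose mean light is bright. `gate` (trim to the largest contiguous dark run) is provided for the alternative reading; `off` disables light |
| `merge_gap` | 10 | min | brief awakenings within a night should not fragment it; 10 min is a conventional actigraphy choice |
| `min_duration` | 30 | min | shallow-interval exclusion; comparison is strict `<` (an exactly-30-min interval is kept) |
| `deep_duration` | 180 | min | deep label for intervals strictly longer than 3 h |
| `day_boundary` | 12:00 | clock time | noon-to-noon day windows place every night inside one window |

Boundary strictness follows the literal readings "less than 30 min"
(dropped) and "more than 3 h" (deep). An interval crossing noon is
credited to the window containing its midpoint; no crossing rule is
canonical, and the midpoint rule keeps per-night totals stable when an
interval barely overlaps a boundary.

## Cleaning and epochs

Cleaning collapses duplicate timestamps (first kept) and marks any
inter-sample gap exceeding `gap_tolerance` (default 3) nominal periods as
a segment break; quiescence runs never bridge a break, so a dead battery
cannot fabricate a sleep interval. Cleaning is idempotent. Epochs are
half-open `[t, t + len)` and left-labelled, which avoids double counting
at boundaries; empty epochs are omitted. Day windows tile the record span;
partial leading/trailing windows are retained and flagged, so a start-time
offset between two devices leaves the shared nights comparable (windows
are matched by their nominal boundary, not their clipped start).

## PPG processing

Ambient subtraction is `corrected = max(on − off, 0)` with an overload
flag wherever the emitter-off (ambient) reading reaches the supply level —
a saturated detector cannot be corrected, only invalidated. Beat detection
removes the quasi-DC baseline with a centered 1-s moving median (robust to
the slow respiratory drift), then takes local maxima with prominence above
30% of the AC inter-percentile (2–98%) amplitude and successive peaks at
least `min_rr` = 0.3 s apart (a 200-bpm ceiling, guarding against counting
dicrotic notches). A candidate train whose mean rate falls below 20 bpm is
rejected outright: residual baseline wobble the median filter cannot fully
remove produces slow "peaks" well outside the physiological band, and this
floor is what makes a pulseless waveform yield zero beats. Heart rate is
windowed (default 60 s): `bpm = 60 / mean RR` per window with ≥ 2 beats,
timestamped at the window center. A square-wave sensor mode is supported
by counting rising edges. Motion-artifact masking flags any hr sample
whose containing motion epoch exceeds the motion threshold.

## Validation statistics

Alignment epoch-aggregates both records (mean) onto a grid anchored at the
later start time, over the overlapping span only, dropping epochs missing
in either record pairwise (imputation would manufacture agreement).
Channel agreement is the Pearson correlation and the OLS line
`y = m x + b` with the reference device on x — the standard convention for
device-validation studies, which also fixes the percent-difference
denominator: `|dur_B − dur_A| / dur_A × 100` per night, summarized by max,
arithmetic mean, and median. Windows where both devices score zero sleep
are skipped; a zero reference with nonzero test sleep is an error rather
than an infinite percentage.

## Simulator

The simulator emulates the study conditions the pipeline is meant for:
seven noon-to-noon days at 30-s epochs starting on a Monday, nightly
onsets around 23:00 with durations 7.7, 9, 8.1, 8.3, 6.2, 7.5, 7.6 h,
diurnal light with linear dawn/dusk ramps (ambient light changes slowly
and roughly linearly), and optional extra quiescent blocks such as the
175-min dark afternoon block used to exercise the false-positive
mechanism. Wake motion is a gamma burst process (mean 40, variance 400
counts) — only its separability from sleep quiescence matters to the
detector, not its physiological realism; sleeping epochs move with
probability 0.05 at exponential magnitude (mean 3). The PPG generator is
DC level + sinusoidal respiratory drift + one raised-cosine pulse per beat
at the instantaneous rate + Gaussian noise; any unimodal pulse shape
serves, since the detector only uses peak times. Two-device twins render
one latent stream through per-device affine channel transforms,
independent Gaussian noise, optional light clipping (saturation), start
delay, and coarser epochs. All randomness derives from the config seed.

What the simulator does **not** model: postural artifacts, off-wrist
periods, nonstationary wake activity, real photodiode spectra, or PPG
morphology pathology. Passing the recovery tests therefore shows the
algorithm is internally correct and robust to gain/noise/saturation
differences — not that it matches polysomnography on real wearers.

## Numerical choices and degenerate inputs

- Moving average uses truncated windows at the series edges (same output
  length); a window longer than the series is an error, and the
  end-to-end path shrinks its window on very short records.
- Thresholds are resolved once per record before detection; resolved
  values are echoed in the report config.
- Duplicate timestamps keep the first sample; records that go backwards
  in time are rejected at construction.
- An all-quiescent record yields a single interval spanning it; an
  all-active record yields none. Constant series make the correlation
  undefined and are rejected rather than returned as NaN.
- Merging is left-to-right and transitive, so it is idempotent; the
  shallow filter and depth classifier are idempotent by construction.

## Problem sizes

The test suite and acceptance script use week-scale records (20,160
epochs), 500 randomized short records for the brute-force equivalence
check, 100 seeded weeks for schedule recovery, and 120-s PPG traces at
200 Hz — sizes at which every check runs in seconds while still covering
the week-scale regime the pipeline targets.
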