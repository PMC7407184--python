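"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately naive (explicit Python loops, repeated passes) and kept
separate from the package implementation they check.
"""

from __future__ import annotations

import math

import pandas as pd


def brute_moving_average(values, window):
    half = window // 2
    out = []
    for i in range(len(values)):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out


def brute_sleep_intervals(times, motion, period_s, *, ma_window,
                          motion_threshold, merge_gap_min, min_duration_min,
                          deep_duration_min):
    """Enumerate maximal sub-threshold runs, then merge/filter/classify.

    Returns a list of (start, end, depth) tuples. Assumes a contiguous
    record (no segment breaks) and no light moderation.
    """
    sm = brute_moving_average(list(motion), ma_window)
    step = pd.Timedelta(seconds=period_s)

    runs = []
    i = 0
    while i < len(sm):
        if sm[i] <= motion_threshold:
            j = i
            while j + 1 < len(sm) and sm[j + 1] <= motion_threshold:
                j += 1
            runs.append((times[i], times[j] + step))
            i = j + 1
        else:
            i += 1

    # merge by repeated passes until stable (transitive closure)
    gap = pd.Timedelta(minutes=merge_gap_min)
    changed = True
    while changed:
        changed = False
        out = []
        for iv in runs:
            if out and (iv[0] - out[-1][1]) <= gap:
                out[-1] = (out[-1][0], iv[1])
                changed = True
            else:
                out.append(iv)
        runs = out

    minute = pd.Timedelta(minutes=1)
    kept = [iv for iv in runs
            if (iv[1] - iv[0]) / minute >= min_duration_min]
    return [
        (s, e, "deep" if (e - s) / minute > deep_duration_min else "sleep")
        for s, e in kept
    ]


def closed_form_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def normal_equations_fit(x, y):
    """OLS slope/intercept from the 2x2 normal equations."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(a * a for a in x)
    sxy = sum(a * b for a, b in zip(x, y))
    det = n * sxx - sx * sx
    m = (n * sxy - sx * sy) / det
    b = (sy * sxx - sx * sxy) / det
    return m, b
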