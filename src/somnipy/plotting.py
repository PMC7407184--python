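"""Weekly report and agreement charts.

One panel per day window: motion in black, ambient light in yellow, heart
rate in red (right axis), detected sleep spans shaded blue. The agreement
chart is one scatter panel per channel with the fitted calibration line.
Uses the Agg backend so charts render headlessly.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .sleep import SleepReport
from .validation import AlignedPair, ComparisonResult

__all__ = ["plot_report", "plot_comparison"]


def plot_report(report: SleepReport, path) -> None:
    """Render a per-day-panel weekly sleep chart to ``path``."""
    n = max(len(report.windows), 1)
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.8 * n), sharex=False,
                             squeeze=False)
    for ax, (window, intervals, total) in zip(axes[:, 0], report.windows):
        df = window.samples
        ax.plot(df.index, df["motion"], color="black", lw=0.5, label="motion")
        ax.plot(df.index, df["light"], color="gold", lw=0.5, label="light")
        if "hr" in df.columns and np.isfinite(df["hr"].to_numpy()).any():
            ax2 = ax.twinx()
            ax2.plot(df.index, df["hr"], color="red", lw=0.5, label="hr")
            ax2.set_ylabel("bpm", fontsize=7)
        for iv in intervals:
            ax.axvspan(iv.start, iv.end, color="tab:blue", alpha=0.3)
        ax.set_xlim(window.start, window.end)
        ax.set_ylabel(window.start.strftime("%a"), fontsize=8)
        ax.set_title(f"total sleep {total / 60:.1f} h", fontsize=8, loc="right")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_comparison(pair: AlignedPair, result: ComparisonResult, path,
                    channels=("motion", "light")) -> None:
    """Scatter + calibration-line panels for the aligned channel pairs."""
    fig, axes = plt.subplots(1, len(channels), figsize=(5 * len(channels), 4),
                             squeeze=False)
    for ax, ch in zip(axes[0], channels):
        xa, xb = pair.channel(ch)
        keep = np.isfinite(xa) & np.isfinite(xb)
        xa, xb = xa[keep], xb[keep]
        ax.scatter(xa, xb, s=4, alpha=0.4, color="tab:blue")
        if ch in result.slope:
            xs = np.linspace(xa.min(), xa.max(), 50)
            ax.plot(xs, result.slope[ch] * xs + result.intercept[ch],
                    color="red", lw=1,
                    label=(f"y = {result.slope[ch]:.2f}x + "
                           f"{result.intercept[ch]:.2f}, "
                           f"r = {result.r[ch]:.2f}"))
            ax.legend(fontsize=8)
        ax.set_xlabel(f"device A {ch}")
        ax.set_ylabel(f"device B {ch}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
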