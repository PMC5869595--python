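"""Figure helpers: single-molecule kymographs, kinetic traces, sweep curves.

All functions take an ``ax`` or create one, and return the Axes; saving is
left to the caller.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def kymograph(result, motor: int = 0, ax=None):
    """Position-vs-time rendering of one motor's trajectory.

    Requires a run with ``record_trajectories > motor``.  Detached stretches
    are blank; SRS intervals are shaded.
    """
    if result.trajectories is None or result.trajectories.shape[1] <= motor:
        raise ValueError("run was executed without trajectory recording for "
                         f"motor {motor}")
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    pos = result.trajectories[:, motor].astype(float)
    pos[pos < 0] = np.nan
    ax.plot(np.arange(pos.size), pos, lw=0.8, color="tab:orange")
    for start, end, _ in result.spec.srs_intervals:
        ax.axhspan(start, end, color="tab:green", alpha=0.3, lw=0)
    ax.set_xlabel("time (MCS)")
    ax.set_ylabel("DNA coordinate (bp)")
    ax.set_ylim(0, result.spec.length_bp)
    return ax


def kinetic_traces(traces: dict, ax=None, seconds: bool = True):
    """Overlay triplex-displacement signals, one labelled trace per entry."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for label, tr in traces.items():
        x = tr.seconds if seconds else tr.mcs
        ax.plot(x, tr.signal, label=label)
    ax.set_xlabel("time (s)" if seconds else "time (MCS)")
    ax.set_ylabel("intact-triplex signal")
    ax.legend(frameon=False)
    return ax


def sweep_curve(summary, ax=None, logx: bool = True, ylabel: str = ""):
    """Mean +/- sd of a sweep statistic against the parameter grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(summary["value"], summary["mean"], yerr=summary["sd"],
                marker="s", capsize=3)
    if logx:
        ax.set_xscale("log")
    ax.set_xlabel(str(summary["parameter"].iloc[0]))
    ax.set_ylabel(ylabel or "statistic")
    return ax
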