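"""Quick-look figures: PSTHs with epoch overlays and arena trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .behavior import ArenaGeometry, Trajectory, OPEN_FIELD
from .evoked import PSTH, BaselineStats, ResponseEpoch

__all__ = ["plot_psth", "plot_trajectory"]


def plot_psth(
    psth: PSTH,
    baseline: BaselineStats | None = None,
    epochs: tuple[ResponseEpoch, ...] = (),
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Cumulative PSTH with the baseline band and detected epochs shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    n_pre = psth.n_baseline_bins
    t = (np.arange(psth.counts.size) - n_pre) * psth.bin_width_ms
    ax.bar(t, psth.counts, width=psth.bin_width_ms, align="edge", color="0.3")
    ax.axvline(0.0, color="crimson", lw=1, label="pulse")
    if baseline is not None:
        lo = baseline.mean_per_bin - 2 * baseline.sd_per_bin
        hi = baseline.mean_per_bin + 2 * baseline.sd_per_bin
        ax.axhspan(max(lo, 0), hi, color="tab:blue", alpha=0.2, label="baseline ±2 SD")
    for epoch in epochs:
        color = "tab:orange" if epoch.kind == "excitation" else "tab:purple"
        ax.axvspan(
            epoch.onset_bin * psth.bin_width_ms,
            epoch.offset_bin * psth.bin_width_ms,
            color=color,
            alpha=0.25,
            label=epoch.kind,
        )
    ax.set_xlabel("time from pulse (ms)")
    ax.set_ylabel(f"counts / {psth.bin_width_ms:g} ms bin ({psth.n_trials} trials)")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_trajectory(
    traj: Trajectory, arena: ArenaGeometry, ax: "plt.Axes | None" = None
) -> "plt.Axes":
    """Path over the arena outline (centre zone / arms drawn for context)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if arena.kind == OPEN_FIELD:
        s = arena.side_cm
        ax.plot([0, s, s, 0, 0], [0, 0, s, s, 0], color="k", lw=1)
        lo, hi = arena.center_bounds
        ax.plot([lo, hi, hi, lo, lo], [lo, lo, hi, hi, lo], color="0.6", lw=1, ls="--")
    else:
        w = arena.arm_width_cm / 2
        r = w + arena.arm_length_cm
        for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            ax.plot([sx * w, sx * r], [sy * w, sy * w], color="k", lw=1)
            ax.plot([sx * w, sx * w], [sy * w, sy * r], color="k", lw=1)
            ax.plot([sx * r, sx * r], [-w, w][:: sy], color="k", lw=1)
            ax.plot([-w, w][:: sx], [sy * r, sy * r], color="k", lw=1)
    ax.plot(traj.x_cm, traj.y_cm, lw=0.5, color="tab:blue")
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    return ax
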