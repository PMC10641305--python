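"""Small figures: environment series and posterior survival series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_environment(series_list):
    """Daily temperature and water level per stream, two stacked panels."""
    fig, (ax_t, ax_l) = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    for s in series_list:
        ax_t.plot(s.data["date"], s.data["temp_c"], lw=0.8, label=s.stream)
        ax_l.plot(s.data["date"], s.data["level_m"], lw=0.8, label=s.stream)
    ax_t.set_ylabel("mean daily temperature (°C)")
    ax_l.set_ylabel("water level (m)")
    ax_t.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_survival_series(series, level_label="95% CRI"):
    """Posterior-mean 60-day survival with credible bars, one panel per stream."""
    streams = list(dict.fromkeys(series["stream"]))
    fig, axes = plt.subplots(1, len(streams), figsize=(5 * len(streams), 4),
                             sharey=True, squeeze=False)
    for ax, stream in zip(axes[0], streams):
        sub = series[series["stream"] == stream]
        for sp, grp in sub.groupby("species", sort=False):
            ax.errorbar(grp["interval"], grp["mean"],
                        yerr=[grp["mean"] - grp["lower"],
                              grp["upper"] - grp["mean"]],
                        marker="o", ms=3, lw=1, capsize=2, label=sp)
        ax.set_title(stream)
        ax.set_xlabel("interval")
        ax.set_ylim(0, 1)
    axes[0][0].set_ylabel(f"60-day survival (mean, {level_label})")
    axes[0][-1].legend(frameon=False)
    fig.tight_layout()
    return fig
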