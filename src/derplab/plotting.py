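"""Figure rendering: electrode-grid difference-trace plots and
individual-peak scatter plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .montage import Montage  # noqa: E402

GROUP_COLORS = {"meditator": "crimson", "non_meditator": "steelblue"}


def plot_derp_grid(grand_means: dict, channels: tuple[str, ...],
                   times_ms: np.ndarray, montage: Montage,
                   experiment: str, out_file: str | Path) -> Path:
    """One axis per electrode at its scalp position, one line per group."""
    fig = plt.figure(figsize=(14, 12))
    for ci, label in enumerate(channels):
        x, y = montage.positions[label]
        ax = fig.add_axes([(x + 1.3) / 2.9, (y + 1.25) / 2.8, 0.11, 0.08])
        for (group, exp), trace in grand_means.items():
            if exp != experiment:
                continue
            ax.plot(times_ms, trace[ci],
                    color=GROUP_COLORS.get(group, "gray"), lw=0.9,
                    label=group)
        ax.axhline(0, color="k", lw=0.4)
        ax.axvline(0, color="k", lw=0.4)
        ax.set_title(label, fontsize=7)
        ax.tick_params(labelsize=5)
    fig.suptitle(f"grand-mean difference traces ({experiment})")
    out_file = Path(out_file)
    fig.savefig(out_file, dpi=120)
    plt.close(fig)
    return out_file


def plot_peak_scatter(peaks: dict[str, pd.DataFrame],
                      out_file: str | Path) -> Path:
    """Per component: individual subject peak amplitudes (dots) with
    group means +- SEM, experiments averaged."""
    names = list(peaks)
    fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 4),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, name in zip(axes, names):
        table = peaks[name]
        per_subject = (table.groupby(["group", "subject"])["amplitude_uv"]
                       .mean().reset_index())
        for gi, (group, sub) in enumerate(per_subject.groupby("group")):
            x = gi + 0.1 * np.random.default_rng(0).standard_normal(len(sub))
            ax.plot(x, sub["amplitude_uv"], "o", ms=4, alpha=0.7,
                    color=GROUP_COLORS.get(group, "gray"))
            mean = sub["amplitude_uv"].mean()
            sem = sub["amplitude_uv"].sem()
            ax.errorbar([gi + 0.35], [mean], yerr=[sem], fmt="o", ms=7,
                        mfc="none", color=GROUP_COLORS.get(group, "gray"))
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(name)
        ax.set_xticks(range(per_subject["group"].nunique()))
        ax.set_xticklabels(sorted(per_subject["group"].unique()),
                           rotation=30, fontsize=7)
    axes[0].set_ylabel("peak amplitude (µV)")
    fig.tight_layout()
    out_file = Path(out_file)
    fig.savefig(out_file, dpi=120)
    plt.close(fig)
    return out_file
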