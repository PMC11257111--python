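"""Bar-chart reports, generated from result TSVs so plots are reproducible
post hoc from files alone."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_timepoint_comparison(
    comparison_tsv: Path | str, out_path: Path | str, title: str = ""
) -> None:
    """Paired D1/D7 bars per node with significance stars."""
    df = pd.read_csv(comparison_tsv, sep="\t", comment="#")
    x = range(len(df))
    w = 0.38
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.bar([i - w / 2 for i in x], df["d1_mean"], w, label="D1", color="#4472c4")
    ax.bar([i + w / 2 for i in x], df["d7_mean"], w, label="D7", color="#c0504d")
    top = max(df["d1_mean"].max(), df["d7_mean"].max())
    for i, sig in enumerate(df["significant"]):
        if sig:
            ax.text(i, top * 1.05, "*", ha="center", fontsize=14)
    ax.set_xticks(list(x), df["node"])
    ax.set_ylabel("Fisher-z similarity")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_severity_table(severity_tsv: Path | str, out_path: Path | str) -> None:
    """Per-network grouped bars: sham-vs-mild plus the severe noise ladder."""
    df = pd.read_csv(severity_tsv, sep="\t", comment="#")
    nets = sorted(df["network"].unique())
    fig, axes = plt.subplots(1, len(nets), figsize=(3.2 * len(nets), 3.2), sharey=True)
    if len(nets) == 1:
        axes = [axes]
    for ax, net in zip(axes, nets):
        sub = df[df["network"] == net]
        mild = sub[sub["comparison"] == "sham_vs_mild"]
        severe = sub[sub["comparison"] == "sham_vs_severe"].sort_values("sd_level")
        labels = [f"mild\n(sd {mild['sd_level'].iloc[0]:g})"] + [
            f"sd {s:g}" for s in severe["sd_level"]
        ]
        means = [mild["mean_z"].iloc[0], *severe["mean_z"]]
        errs = [mild["stderr"].iloc[0], *severe["stderr"]]
        colors = ["0.6"] + ["0.15"] * len(severe)
        ax.bar(range(len(means)), means, yerr=errs, color=colors)
        for i, sig in enumerate([False, *severe["significant"]]):
            if sig:
                ax.text(i, means[i] * 1.06, "*", ha="center", fontsize=13)
        ax.set_xticks(range(len(labels)), labels, fontsize=7)
        ax.set_title(net)
    axes[0].set_ylabel("Fisher-z similarity")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
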