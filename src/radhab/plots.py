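"""Optional figure rendering. Figures are side effects, never pipeline inputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def survival_bars(table: pd.DataFrame, path: str | Path) -> None:
    """Grouped log-scale bar chart of survival times per scenario."""
    organisms = list(dict.fromkeys(table["organism"]))
    scenarios = list(dict.fromkeys(table["scenario"]))
    width = 0.8 / max(len(organisms), 1)
    fig, ax = plt.subplots(figsize=(1.8 * len(scenarios) + 2, 4))
    x = np.arange(len(scenarios))
    for i, org in enumerate(organisms):
        sub = table[table["organism"] == org].set_index("scenario")
        years = [sub.loc[s, "years"] for s in scenarios]
        ax.bar(x + i * width, years, width=width, label=org)
    ax.set_yscale("log")
    ax.set_xticks(x + width * (len(organisms) - 1) / 2)
    ax.set_xticklabels(scenarios, rotation=30, ha="right")
    ax.set_ylabel("time to inactivation (yr)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def presence_heatmap(presence: pd.DataFrame, path: str | Path) -> None:
    """Black/white presence-absence heatmap of a boolean matrix."""
    fig, ax = plt.subplots(
        figsize=(0.25 * presence.shape[1] + 2, 0.12 * presence.shape[0] + 2)
    )
    ax.imshow(presence.to_numpy(dtype=float), cmap="Greys", aspect="auto", vmin=0, vmax=1)
    ax.set_xticks(range(presence.shape[1]))
    ax.set_xticklabels(presence.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(presence.shape[0]))
    ax.set_yticklabels(presence.index, fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
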