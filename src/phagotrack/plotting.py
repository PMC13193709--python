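"""Minimal plots for contact quantification results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_contact_summary(groups: dict[str, dict], path=None):
    """Violin plots of total contact time and contact enrichment by group.

    ``groups`` maps group name to ``{"contact_time_min": [...],
    "enrichment": [...]}``.  Returns the matplotlib figure; saves to
    ``path`` when given.
    """
    names = list(groups)
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2))
    for ax, key, title in zip(
        axes,
        ("contact_time_min", "enrichment"),
        ("Total contact time (min)", "Contact enrichment"),
    ):
        data = [groups[n][key] for n in names]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(names) + 1), names)
        ax.set_ylabel(title)
    if "enrichment" in groups.get(names[0], {}):
        axes[1].axhline(1.0, color="grey", lw=0.8, ls="--")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
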