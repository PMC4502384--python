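"""Plotting conveniences: screen correlation bars and site-strength
histograms.  Layout is not bit-specified; these are quick-look figures."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_screen(screen: pd.DataFrame, path, r_high: float = 0.19) -> None:
    """Paired bar chart of per-motif correlations with both factors."""
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(screen)), 4))
    x = np.arange(len(screen))
    ax.bar(x - 0.2, screen["r_A"], width=0.4, label="factor A")
    ax.bar(x + 0.2, screen["r_B"], width=0.4, label="factor B")
    ax.axhline(r_high, color="darkorange", ls="--", lw=1,
               label=f"high (r > {r_high})")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xticks(x)
    ax.set_xticklabels(screen["motif_id"], rotation=90, fontsize=7)
    ax.set_ylabel("Pearson r (occupancy vs. enrichment)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_strength_histograms(strength_cobound: Sequence[float],
                             strength_single: Sequence[float], path,
                             motif_id: Optional[str] = None) -> None:
    """Overlaid histograms of −log10 site p-values for the two groups."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    bins = np.histogram_bin_edges(
        np.concatenate([strength_cobound, strength_single]), bins=20)
    ax.hist(strength_cobound, bins=bins, alpha=0.6, label="co-bound",
            density=True)
    ax.hist(strength_single, bins=bins, alpha=0.6, label="single-factor",
            density=True)
    ax.set_xlabel("site strength, −log10 p")
    ax.set_ylabel("density")
    if motif_id:
        ax.set_title(motif_id)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
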