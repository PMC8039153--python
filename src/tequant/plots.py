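"""Quick-look figures for the main outputs (optional, matplotlib)."""

from __future__ import annotations

import numpy as np

from .integrate import MetaProfile


def plot_methylation_density(joint, conditions=("WT", "mutant"), bins=10,
                             ax=None):
    """Histogram-style density of per-CpG percents per condition."""
    import matplotlib.pyplot as plt

    from .methylome import methylation_density

    if ax is None:
        _, ax = plt.subplots()
    for cond in conditions:
        edges, mass, mean = methylation_density(joint, cond, bins=bins)
        centers = (edges[:-1] + edges[1:]) / 2
        ax.plot(centers, mass, marker="o",
                label=f"{cond} (mean {mean:.1f}%)")
    ax.set_xlabel("CpG methylation (%)")
    ax.set_ylabel("fraction of CpGs")
    ax.legend()
    return ax


def plot_tss_metaplot(profile: MetaProfile, ax=None):
    """Mean methylation around the TSS, one line per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cond, means in profile.mean_percent.items():
        label = cond[len("percent_"):] if cond.startswith("percent_") else cond
        ax.plot(profile.bin_centers, means, label=label)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("mean CpG methylation (%)")
    ax.set_ylim(0, 100)
    ax.legend()
    return ax


def plot_ma(results, ax=None, alpha=0.05):
    """MA plot of a differential-expression result table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sig = results["padj"] < alpha
    ax.scatter(np.log10(results.loc[~sig, "base_mean"] + 1),
               results.loc[~sig, "l2fc"], s=8, c="grey", label="ns")
    ax.scatter(np.log10(results.loc[sig, "base_mean"] + 1),
               results.loc[sig, "l2fc"], s=8, c="crimson",
               label=f"padj < {alpha}")
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("log10 base mean + 1")
    ax.set_ylabel("log2 fold change")
    ax.legend()
    return ax
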