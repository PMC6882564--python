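"""Optional figures: enhancement histograms and per-chain posterior densities."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bayes import PosteriorDraws
from .enhancement import EnhancementSample

__all__ = ["plot_enhancement_histograms", "plot_posterior_chains"]


def plot_enhancement_histograms(
    enhancements_by_arm: dict[int, list[EnhancementSample]],
    path: str | Path,
    thresholds: dict[str, float] | None = None,
) -> None:
    """Side-by-side histograms of aortic and hepatic enhancement per arm,
    with the diagnostic thresholds marked."""
    thresholds = thresholds or {"aorta": 280.0, "liver": 50.0}
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, site in zip(axes, ("aorta", "liver")):
        for kvp, samples in sorted(enhancements_by_arm.items()):
            values = [s.value(site) for s in samples]
            ax.hist(values, bins=20, alpha=0.55, label=f"{kvp} kVp")
        ax.axvline(thresholds[site], color="k", linestyle="--", linewidth=1)
        ax.set_xlabel(f"{site} enhancement (HU)")
        ax.set_ylabel("patients")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_posterior_chains(draws: PosteriorDraws, path: str | Path, title: str = "") -> None:
    """Per-chain kernel density estimates of the posterior of the mean
    and SD of the required contrast volume."""
    from scipy.stats import gaussian_kde

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, param, label in zip(axes, ("mu", "sigma"), ("mean (mL/kg)", "SD (mL/kg)")):
        chains = getattr(draws, param)
        for c in range(chains.shape[0]):
            x = chains[c]
            grid = np.linspace(x.min(), x.max(), 200)
            ax.plot(grid, gaussian_kde(x)(grid), label=f"chain {c + 1}", linewidth=1)
        ax.set_xlabel(label)
        ax.set_ylabel("posterior density")
        ax.legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
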