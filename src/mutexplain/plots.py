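"""Density plots contrasting disease mutations with polymorphisms.

One figure with three panels — pathogenicity score, FoldX ddG and relative
solvent accessibility — with dashed lines at the published decision cutoffs
(0.611, 1 kcal/mol, 20%).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from scipy.stats import gaussian_kde  # noqa: E402

PANELS = (
    ("pathogenicity", "Pathogenicity score", 0.611),
    ("ddg", "FoldX ddG (kcal/mol)", 1.0),
    ("rsa", "Relative solvent accessibility (%)", 20.0),
)


def _density(ax, values: np.ndarray, label: str, color: str) -> None:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 3 or np.ptp(values) == 0:
        ax.hist(values, bins=10, density=True, alpha=0.4, label=label,
                color=color)
        return
    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 200)
    ax.plot(grid, kde(grid), label=label, color=color)
    ax.fill_between(grid, kde(grid), alpha=0.2, color=color)


def plot_cohort_distributions(disease: dict[str, np.ndarray],
                              polymorphism: dict[str, np.ndarray],
                              path: str | Path) -> Path:
    """Write the three-panel contrast figure; returns the output path."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, (key, title, cutoff) in zip(axes, PANELS):
        _density(ax, disease.get(key, np.array([])), "disease", "tab:blue")
        _density(ax, polymorphism.get(key, np.array([])), "polymorphism",
                 "tab:red")
        ax.axvline(cutoff, ls="--", color="gray", lw=1)
        ax.set_xlabel(title)
        ax.set_ylabel("density")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
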