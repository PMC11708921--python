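"""Plotting helpers for sweep results and profiles (matplotlib, Agg)."""

from __future__ import annotations

from typing import Dict, Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .model_space import ModelSpaceResult, ParameterLandscape  # noqa: E402
from .thermo import ExpressionProfile  # noqa: E402


def plot_rmse_aic(result: ModelSpaceResult, path) -> None:
    """RMSE and AIC versus number of included sites, one dot per model."""
    n_sites = [len(f.subset) for f in result.fits]
    rmses = [f.rmse for f in result.fits]
    aics = [f.aic for f in result.fits]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].scatter(n_sites, rmses, s=8, alpha=0.5)
    axes[0].set_xlabel("# binding sites")
    axes[0].set_ylabel("min RMSE")
    finite = np.isfinite(aics)
    axes[1].scatter(np.asarray(n_sites)[finite], np.asarray(aics)[finite],
                    s=8, alpha=0.5)
    axes[1].set_xlabel("# binding sites")
    axes[1].set_ylabel("AIC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_threshold_histogram(hist: Dict[int, int], path,
                             title: str = "HB switching threshold") -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    if hist:
        nuclei = sorted(hist)
        ax.bar(nuclei, [hist[n] for n in nuclei], width=0.9)
    ax.set_xlabel("threshold nucleus")
    ax.set_ylabel("# models")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_k_heatmap(landscape: ParameterLandscape, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 6))
    mat = landscape.matrix.to_numpy()
    im = ax.imshow(np.log1p(mat), aspect="auto", cmap="viridis")
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels(landscape.matrix.columns, rotation=90, fontsize=7)
    ax.set_ylabel("model (clustered order)")
    fig.colorbar(im, ax=ax, label="ln(1 + K)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fit(observed: ExpressionProfile,
             predicted: ExpressionProfile, path,
             title: Optional[str] = None) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(observed.ap_grid, observed.mean, "k.", label="observed")
    if observed.se is not None:
        ax.fill_between(observed.ap_grid, observed.mean - observed.se,
                        observed.mean + observed.se, color="0.8")
    ax.plot(predicted.ap_grid, predicted.mean, "r-", label="model")
    ax.set_xlabel("% AP")
    ax.set_ylabel("normalized expression")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
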