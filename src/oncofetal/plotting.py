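"""Plotting conveniences: CNV heatmap and Kaplan-Meier curves."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cnv import CnvProfile  # noqa: E402
from .cohort import KMResult  # noqa: E402


def cnv_heatmap(profile: CnvProfile, clusters: pd.Series | np.ndarray,
                path: str, vmax: float | None = None) -> None:
    """Cells (ordered by cluster) × genes (genome order) residual heatmap."""
    clusters = np.asarray(clusters)
    order = np.argsort(clusters, kind="stable")
    data = profile.residuals[order]
    vmax = vmax or float(np.percentile(np.abs(data), 99) or 1.0)
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
              interpolation="nearest")
    ax.set_xlabel("genes (genome order)")
    ax.set_ylabel("cells (by cluster)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_plot(result: KMResult, path: str) -> None:
    """Step-function survival curves for the two groups."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in result.curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=label)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"log-rank p = {result.p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
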