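"""Optional figures: correlation heat maps and simulated-intake
histograms.  Import is deferred-friendly: matplotlib is only touched
when a plot is requested."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix
from .mc import McResult

__all__ = ["correlation_heatmap", "intake_histogram", "histogram_frame"]


def correlation_heatmap(cm: CorrelationMatrix, path: str | Path | None = None):
    """Heat map of a site's rank-correlation matrix; significant cells
    are outlined."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(cm.rho.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(cm.metals)), cm.metals, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm.metals)), cm.metals, fontsize=7)
    sig = cm.significant.to_numpy()
    for i in range(len(cm.metals)):
        for j in range(len(cm.metals)):
            if sig[i, j]:
                ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1,
                                           fill=False, lw=1.2, ec="black"))
    ax.set_title(f"Spearman rho, {cm.site} (n={cm.n}, "
                 f"alpha={cm.alpha})")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def histogram_frame(result: McResult, metal: str,
                    bins: int = 50) -> pd.DataFrame:
    """Histogram of simulated EDI draws for one metal as a plain table
    (bin_left, bin_right, count), suitable for CSV emission."""
    draws = result.edi[metal].to_numpy()
    counts, edges = np.histogram(draws, bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


def intake_histogram(result: McResult, metal: str,
                     path: str | Path | None = None, bins: int = 50):
    """Histogram of simulated daily intake with the limit marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    draws = result.edi[metal].to_numpy()
    limit = float(result.config.limits[metal])
    fig, ax = plt.subplots()
    ax.hist(draws, bins=bins, color="steelblue", edgecolor="white")
    ax.axvline(limit, color="firebrick", ls="--", label=f"limit {limit:g}")
    p = float(result.exceedance_prob[metal])
    ax.set_xlabel(f"{metal} intake (µg/kg bw/day)")
    ax.set_ylabel("count")
    ax.set_title(f"{metal}: P(exceed) = {100 * p:.1f} %")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
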