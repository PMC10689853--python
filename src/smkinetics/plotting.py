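"""Optional matplotlib views: TDP heatmap and population-histogram fit.

Imported lazily so the analysis stack works without a plotting backend.
"""

from __future__ import annotations

import numpy as np

from .histogram import GaussianPeakFit, PopulationHistogram, _multipeak
from .tdp import TdpDensity

__all__ = ["plot_tdp", "plot_histogram_fit"]


def plot_tdp(tdp: TdpDensity, ax=None, cmap: str = "viridis"):
    """Heatmap of the transition density with the event count annotated."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    extent = (tdp.grid[0], tdp.grid[-1], tdp.grid[0], tdp.grid[-1])
    im = ax.imshow(tdp.density.T, origin="lower", extent=extent, cmap=cmap,
                   aspect="equal")
    ax.set_xlabel("initial intensity (normalized)")
    ax.set_ylabel("final intensity (normalized)")
    ax.annotate(f"n = {tdp.n_transitions}", xy=(0.03, 0.95),
                xycoords="axes fraction", color="w", fontsize=9, va="top")
    ax.figure.colorbar(im, ax=ax, label="transition density")
    return ax


def plot_histogram_fit(hist: PopulationHistogram, fit: GaussianPeakFit | None = None,
                       ax=None):
    """Histogram bars with SE error bars; dashed per-peak curves and the
    solid composite fit when a fit is supplied."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(hist.centers, hist.counts, width=hist.bin_width, color="0.8",
           edgecolor="0.5", yerr=hist.se, error_kw={"lw": 0.5})
    if fit is not None:
        x = np.linspace(hist.edges[0], hist.edges[-1], 400)
        for A, mu, sig in zip(fit.amplitudes, fit.centers, fit.widths):
            ax.plot(x, fit.y0 + A * np.exp(-(((x - mu) / sig) ** 2)), "--",
                    lw=1)
        ax.plot(x, _multipeak(x, fit.y0, *np.ravel(np.column_stack(
            [fit.amplitudes, fit.centers, fit.widths]))), "k-", lw=1.5)
    ax.set_xlabel("normalized intensity")
    ax.set_ylabel("frames")
    return ax
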