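"""Display helpers: log-time dwell histograms and amplitude histograms."""

from __future__ import annotations

import numpy as np

from .dwells import DwellHistogram, ExpMixtureFit


def plot_dwell_histogram(hist: DwellHistogram, fit: ExpMixtureFit | None = None,
                         ax=None):
    """Square-root-ordinate dwell histogram on a log time axis.

    Overlays the fitted exponential mixture (scaled to event counts) and its
    individual components (dashed) when a fit is given.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = np.sqrt(hist.bin_edges[:-1] * hist.bin_edges[1:])
    widths = np.diff(hist.bin_edges)
    ax.bar(centers, np.sqrt(hist.counts), width=widths, align="center",
           color="0.8", edgecolor="0.5")
    if fit is not None:
        n = fit.n
        t = np.geomspace(hist.bin_edges[0], hist.bin_edges[-1], 400)
        w = np.interp(t, centers, widths)
        total = np.zeros_like(t)
        for area, tau in fit.components:
            comp = n * w * area / tau * np.exp(-t / tau)
            ax.plot(t, np.sqrt(comp), "--", lw=1)
            total += comp
        ax.plot(t, np.sqrt(total), "k-", lw=1.5)
    ax.set_xscale("log")
    ax.set_xlabel("duration (s)")
    ax.set_ylabel("sqrt(count)")
    if hist.conductance:
        ax.set_title(f"{hist.conductance} dwell durations")
    return ax


def plot_ebah(edges: np.ndarray, fractions: np.ndarray, ax=None):
    """Event-based amplitude histogram (one entry per burst)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (edges[:-1] + edges[1:])
    ax.bar(centers, fractions, width=np.diff(edges), align="center",
           color="0.7", edgecolor="0.4")
    ax.set_xlabel("burst amplitude (pA)")
    ax.set_ylabel("fraction of bursts")
    return ax
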