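"""Scatter-plus-boundary plots in the style of boundary line studies."""

from __future__ import annotations

import numpy as np

from .model_core import BoundaryParams, eval_boundary


def plot_boundary_fit(x, y, boundary: BoundaryParams | None = None, ax=None,
                      log_scale: bool = True, xlabel: str | None = None):
    """Yield vs (log) nutrient concentration with the fitted boundary line.

    ``x`` is on the natural-log scale; with ``log_scale=False`` the abscissa
    is back-transformed to mg/L (boundary drawn as a curve).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs = np.linspace(x.min(), x.max(), 400)
    if log_scale:
        ax.plot(x, y, ".", ms=3, alpha=0.4, color="grey")
        if boundary is not None:
            ax.plot(xs, eval_boundary(boundary, xs), "r-", lw=2)
        ax.set_xlabel(xlabel or "log concentration")
    else:
        ax.plot(np.exp(x), y, ".", ms=3, alpha=0.4, color="grey")
        if boundary is not None:
            ax.plot(np.exp(xs), eval_boundary(boundary, xs), "r-", lw=2)
        ax.set_xlabel(xlabel or "concentration / mg L$^{-1}$")
    ax.set_ylabel("yield / t ha$^{-1}$")
    return ax
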