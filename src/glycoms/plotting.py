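"""Convenience figure rendering for the pipeline's plot-ready tables.

The contractual outputs are the CSV tables (scores, volcano rows, heat-map
ratios/bins); these helpers draw them with matplotlib for quick looks.
"""

from __future__ import annotations

import numpy as np

from .diffstats import HeatmapMatrix
from .multivariate import Ellipse


def _ellipse_xy(ell: Ellipse, n: int = 200):
    th = np.linspace(0, 2 * np.pi, n)
    a, b = ell.semi_axes
    x = a * np.cos(th)
    y = b * np.sin(th)
    c, s = np.cos(ell.angle), np.sin(ell.angle)
    return (ell.center[0] + c * x - s * y, ell.center[1] + s * x + c * y)


def score_plot(scores, classes, ellipse: Ellipse | None = None, ax=None,
               xlabel="t (predictive)", ylabel="t_o (orthogonal)"):
    """2-D score scatter colored by class with an optional T2 ellipse."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    S = np.asarray(scores, dtype=float)
    classes = np.asarray(classes)
    for cls, color in zip(np.unique(classes), ("tab:green", "tab:blue", "tab:red")):
        m = classes == cls
        ax.scatter(S[m, 0], S[m, 1], s=18, label=str(cls), color=color, alpha=0.8)
    if ellipse is not None:
        ax.plot(*_ellipse_xy(ellipse), "k--", lw=1)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    return ax


def volcano_plot(volcano_rows, ax=None, alpha=0.05):
    """Signed log2 fold vs -log10 p with the significance gate highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    df = volcano_rows
    sig = df["significant"].to_numpy(dtype=bool)
    ax.scatter(df.loc[~sig, "log2fc"], df.loc[~sig, "minus_log10_p"],
               s=6, color="0.6", alpha=0.6)
    ax.scatter(df.loc[sig, "log2fc"], df.loc[sig, "minus_log10_p"],
               s=8, color="tab:red", alpha=0.8)
    ax.axhline(-np.log10(alpha), ls="--", color="k", lw=0.8)
    ax.set_xlabel("log2 mean fold change")
    ax.set_ylabel("-log10 p")
    return ax


def heatmap_plot(matrix: HeatmapMatrix, ax=None):
    """Green-to-red binned ratio heat map (rows = features, cols = samples)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    cmap = LinearSegmentedColormap.from_list("ratio", ["#00c000", "#101010", "#ff2020"])
    img = matrix.bins.to_numpy(dtype=float)
    img[img < 0] = np.nan
    ax.imshow(img, aspect="auto", cmap=cmap, vmin=0, vmax=10, interpolation="nearest")
    ax.set_xlabel("samples (control | case)")
    ax.set_ylabel("features (by ascending p)")
    return ax
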