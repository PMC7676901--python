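"""Optional rendering: scalp topographies of component scores, scree plots,
DFA fluctuation plots.  Thin matplotlib helpers; nothing here feeds back
into the analysis."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .montage import positions_2d  # noqa: E402


def topomap(values: dict, path=None, *, title: str = "", cmap: str = "RdBu_r",
            grid_n: int = 120, ax=None):
    """2-D scalp map of per-channel values (vertex view, nose up, left ear
    left), interpolated on a disc.  ``values`` maps channel label -> score.

    Returns the matplotlib Axes; writes an image when ``path`` is given.
    """
    if len(values) < 32:
        raise ValueError("need >= 32 mapped channels for a topography")
    pos = positions_2d()
    unknown = set(values) - set(pos)
    if unknown:
        raise ValueError(f"unknown channel positions: {sorted(unknown)}")
    xy = np.array([pos[lab] for lab in values])
    v = np.array([values[lab] for lab in values], dtype=float)

    from scipy.interpolate import griddata

    gx, gy = np.meshgrid(np.linspace(-1.25, 1.25, grid_n),
                         np.linspace(-1.25, 1.25, grid_n))
    gz = griddata(xy, v, (gx, gy), method="cubic")
    gz_near = griddata(xy, v, (gx, gy), method="nearest")
    gz = np.where(np.isnan(gz), gz_near, gz)
    mask = gx ** 2 + gy ** 2 > 1.25 ** 2
    gz = np.ma.masked_where(mask, gz)

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(3.2, 3.2))
    vmax = float(np.max(np.abs(v))) or 1.0
    ax.pcolormesh(gx, gy, gz, cmap=cmap, vmin=-vmax, vmax=vmax,
                  shading="auto")
    ax.add_patch(plt.Circle((0, 0), 1.25, fill=False, lw=1.5))
    ax.plot([-0.12, 0, 0.12], [1.24, 1.38, 1.24], "k-", lw=1.5)  # nose up
    ax.scatter(xy[:, 0], xy[:, 1], s=4, c="k")
    ax.set_xlim(-1.5, 1.5)
    ax.set_ylim(-1.5, 1.55)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title, fontsize=9)
    if path is not None and own_fig:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax


def scree_plot(explained_var, path=None, k: int = 10):
    """Explained-variance-per-component bar plot with the cumulative curve."""
    ev = np.asarray(explained_var)[:k] * 100
    fig, ax = plt.subplots(figsize=(4.5, 3))
    xs = np.arange(1, ev.size + 1)
    ax.bar(xs, ev, color="steelblue")
    ax.plot(xs, np.cumsum(ev), "o-", color="darkorange", label="cumulative")
    ax.set_xlabel("principal component")
    ax.set_ylabel("explained variance (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax


def dfa_plot(result, path=None):
    """Log-log fluctuation function with the fitted scaling line."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.loglog(result.window_sizes_s, result.fluctuation, "o", ms=3)
    lo, hi = result.config.fit_range_s
    sel = ((result.window_sizes_s >= lo) & (result.window_sizes_s <= hi))
    x = result.window_sizes_s[sel]
    c = result.fluctuation[sel][0] / x[0] ** result.SEV
    ax.loglog(x, c * x ** result.SEV, "r-",
              label=f"SEV = {result.SEV:.2f}")
    ax.set_xlabel("window size (s)")
    ax.set_ylabel("fluctuation")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax
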