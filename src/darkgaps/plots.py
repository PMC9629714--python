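"""Static map and diagnostic plots (matplotlib, headless-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .grid import Raster  # noqa: E402


def plot_raster(raster: Raster, path: str | Path, title: str | None = None,
                cmap: str = "viridis", log_scale: bool = False) -> Path:
    """Map of one raster layer (missing cells transparent)."""
    spec = raster.spec
    vals = raster.values
    if log_scale:
        vals = np.log10(np.where(vals > 0, vals, np.nan))
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(vals, origin="lower", cmap=cmap,
                   extent=[spec.west, spec.east, spec.south, spec.north],
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, label=raster.units or raster.layer)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(title or raster.layer)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_importance(importance: pd.Series, path: str | Path,
                    title: str = "Relative importance of drivers") -> Path:
    """Horizontal bar chart of per-driver relative importance (%)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    imp = importance.sort_values()
    ax.barh(imp.index, imp.values, color="steelblue")
    ax.set_xlabel("relative importance (%)")
    ax.set_title(title)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_partial_dependence(pdp: pd.DataFrame, path: str | Path) -> Path:
    """Grid of partial-dependence curves, one panel per driver."""
    drivers = pdp["driver"].unique()
    ncols = 4
    nrows = int(np.ceil(len(drivers) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False)
    for ax, name in zip(axes.ravel(), drivers):
        sub = pdp[pdp["driver"] == name]
        ax.plot(sub["x"], sub["response"], color="darkorange")
        ax.set_title(name, fontsize=9)
    for ax in axes.ravel()[len(drivers):]:
        ax.axis("off")
    fig.supylabel("marginal fitted response (logit)")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
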