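"""Quantitative visual outputs: stacked histograms, timepoint plots, flag
plots, glass-brain projections, and animations.

Every figure is a pure function of a tidy table that is returned alongside
it, so results can be re-rendered or consumed downstream without re-running
the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import imageio.v2 as imageio
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .synthetic import CANONICAL_ICS, UNCLASSIFIED

__all__ = [
    "IC_PALETTE",
    "DisplayNormalization",
    "stacked_histogram",
    "timepoint_plot",
    "flag_plot",
    "glass_brain",
    "render_animation",
    "figure_to_array",
]

#: Resting-state network palette (DMN sky blue ... VN violet, unclassified gray).
IC_PALETTE: Mapping[str, str] = {
    "DMN": "skyblue",
    "SN": "red",
    "DAN": "orange",
    "CEN": "gold",
    "SMN": "green",
    "AN": "blue",
    "VN": "violet",
    "L_Cbl": "tan",
    "R_Cbl": "peru",
    "Vermis": "olive",
    UNCLASSIFIED: "gray",
}


@dataclass(frozen=True)
class DisplayNormalization:
    """Per-subject joint scaling of afferent and efferent capacities.

    The divisor is the maximum over all voxels and windows of both
    capacities jointly, so scaled values lie in [0, 1], at least one value
    equals 1, and the ranking of voxels is untouched.
    """

    max_value: float

    @classmethod
    def fit(cls, afferent: np.ndarray, efferent: np.ndarray) -> "DisplayNormalization":
        m = float(np.nanmax([np.nanmax(afferent), np.nanmax(efferent)]))
        if not np.isfinite(m) or m <= 0:
            raise ValueError("cannot normalise all-zero or undefined capacities")
        return cls(max_value=m)

    def scale(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) / self.max_value


def _ic_order(ic_labels: np.ndarray) -> list[str]:
    present = set(np.asarray(ic_labels, dtype=object).tolist())
    ordered = [ic for ic in CANONICAL_ICS if ic in present]
    ordered += sorted(present - set(CANONICAL_ICS))
    return ordered


def stacked_histogram(
    composition: pd.DataFrame, ax: plt.Axes | None = None
) -> tuple[pd.DataFrame, plt.Figure]:
    """Stacked window x IC bar chart of k_max_core membership counts.

    ``composition`` holds one row per window and one column per IC (counts).
    Empty windows appear as zero-height bars.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(9, 3))
    else:
        fig = ax.figure
    bottom = np.zeros(len(composition))
    x = composition.index.to_numpy()
    for ic in composition.columns:
        vals = composition[ic].to_numpy(dtype=float)
        ax.bar(x, vals, bottom=bottom, width=1.0,
               color=IC_PALETTE.get(ic, "black"), label=ic)
        bottom += vals
    ax.set_xlabel("window")
    ax.set_ylabel("k_max_core voxels")
    ax.legend(fontsize=6, ncol=2, loc="upper right")
    return composition, fig


def timepoint_plot(
    values: np.ndarray,
    ic_labels: np.ndarray,
    mode: str = "kcore_edge_scaled",
) -> tuple[pd.DataFrame, plt.Figure]:
    """Per-IC voxel-trajectory panels plus a tidy long-format table.

    ``values`` is (n_windows, n_voxels); each panel draws one polyline per
    voxel of that IC.  Missing windows (NaN) render as gaps.
    """
    values = np.asarray(values, dtype=float)
    n_w, n_v = values.shape
    labels = np.asarray(ic_labels, dtype=object)
    if len(labels) != n_v:
        raise ValueError("one label per voxel required")
    order = _ic_order(labels)

    tidy = pd.DataFrame({
        "window_id": np.repeat(np.arange(n_w), n_v),
        "voxel_id": np.tile(np.arange(n_v), n_w),
        "ic": np.tile(labels, n_w),
        "mode": mode,
        "value": values.ravel(),
    })

    ncols = min(4, len(order))
    nrows = -(-len(order) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2 * nrows),
                             squeeze=False, sharex=True)
    for k, ic in enumerate(order):
        ax = axes[k // ncols][k % ncols]
        for v in np.flatnonzero(labels == ic):
            ax.plot(values[:, v], lw=0.4, color=IC_PALETTE.get(ic, "black"),
                    alpha=0.6)
        ax.set_title(ic, fontsize=8)
    for k in range(len(order), nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    fig.suptitle(mode, fontsize=9)
    fig.supxlabel("window")
    return tidy, fig


def flag_plot(
    values: np.ndarray, ic_labels: np.ndarray
) -> tuple[pd.DataFrame, plt.Figure]:
    """Voxel x window heatmap, rows grouped by IC then by descending mean.

    The heatmap twin of the timepoint plot; the voxel ordering is the
    package's choice (IC block, then mean value) and is recorded in the
    returned table's row order.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(ic_labels, dtype=object)
    order = []
    for ic in _ic_order(labels):
        members = np.flatnonzero(labels == ic)
        means = np.nan_to_num(np.nanmean(values[:, members], axis=0))
        order.extend(members[np.argsort(-means)].tolist())
    order = np.asarray(order, dtype=int)

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(values[:, order].T, aspect="auto", interpolation="nearest",
              cmap="viridis")
    ax.set_xlabel("window")
    ax.set_ylabel("voxel (IC-blocked)")
    table = pd.DataFrame({"row": np.arange(len(order)), "voxel_id": order,
                          "ic": labels[order]})
    return table, fig


def glass_brain(
    values: np.ndarray, coords: np.ndarray
) -> tuple[dict[str, np.ndarray], plt.Figure]:
    """Sagittal and axial maximum-intensity projections of voxel values."""
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=int)
    shape = coords.max(axis=0) + 1
    vol = np.zeros(shape)
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = values
    sagittal = vol.max(axis=0)          # project along x: (y, z)
    axial = vol.max(axis=2)             # project along z: (x, y)

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(6, 3))
    ax1.imshow(sagittal.T, origin="lower", cmap="hot")
    ax1.set_title("sagittal MIP", fontsize=8)
    ax2.imshow(axial.T, origin="lower", cmap="hot")
    ax2.set_title("axial MIP", fontsize=8)
    for ax in (ax1, ax2):
        ax.set_xticks([])
        ax.set_yticks([])
    return {"sagittal": sagittal, "axial": axial}, fig


def figure_to_array(fig: plt.Figure) -> np.ndarray:
    """Rasterise a figure to an RGB uint8 array (for animation frames)."""
    fig.canvas.draw()
    buf = np.asarray(fig.canvas.buffer_rgba())
    return buf[:, :, :3].copy()


def render_animation(
    frames: Sequence[np.ndarray], path: str | Path,
    fps: float = 5.0, container: str = "gif",
) -> Path:
    """Concatenate pre-rendered frames into a movie (GIF default, AVI optional).

    All frames must share one shape.  If the AVI codec is unavailable the
    writer falls back to GIF with a warning.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("animation needs at least one frame")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all animation frames must have the same shape")
    path = Path(path)
    if container == "gif" or path.suffix.lower() == ".gif":
        imageio.mimsave(path, frames, duration=1.0 / fps)
        return path
    try:
        imageio.mimsave(path, frames, fps=fps)
        return path
    except Exception:  # codec unavailable -> GIF fallback
        import warnings

        fallback = path.with_suffix(".gif")
        warnings.warn(f"codec for {path.suffix} unavailable; writing {fallback}")
        imageio.mimsave(fallback, frames, duration=1.0 / fps)
        return fallback
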