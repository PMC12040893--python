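"""Sliding-window correlation graphs: positive and unsigned-negative channels.

A voxel time series is cut into fixed-length windows advanced by a fixed
shift; each window yields one Pearson correlation matrix, which is split into
a positive channel (r above a threshold) and an unsigned-negative channel
(|r| above a threshold, r negative).  The two channels are edge-disjoint and
are analysed separately downstream.  Diagnostics record the giant-component
fraction and a log-log degree-distribution fit; both are advisory and never
gate the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .synthetic import VoxelTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "WindowGraph",
    "WindowedGraphSet",
    "GraphDiagnostics",
    "make_windows",
    "window_correlation",
    "split_and_threshold",
    "build_windowed_graphs",
    "degree_diagnostics",
    "candidate_pair_count",
]

#: Default edge thresholds (strictly greater than).
THETA_POS = 0.65
THETA_NEG = 0.50


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.  Defaults give 1-min windows at TR 0.72 s
    (84 volumes = 60.48 s) shifted by 4 volumes (2.88 s)."""

    window_frames: int = 84
    shift_frames: int = 4
    tr_seconds: float = 0.72

    def __post_init__(self) -> None:
        if self.window_frames < 2:
            raise ValueError("window_frames must be >= 2")
        if self.shift_frames < 1:
            raise ValueError("shift_frames must be >= 1")

    @property
    def window_seconds(self) -> float:
        return self.window_frames * self.tr_seconds

    @property
    def shift_seconds(self) -> float:
        return self.shift_frames * self.tr_seconds

    def n_windows(self, n_frames: int) -> int:
        if self.window_frames > n_frames:
            raise ValueError(
                f"window ({self.window_frames}) exceeds series length ({n_frames})"
            )
        return (n_frames - self.window_frames) // self.shift_frames + 1


def make_windows(n_frames: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open 0-based frame intervals [start, end) for every window."""
    n = spec.n_windows(n_frames)
    return [(i * spec.shift_frames, i * spec.shift_frames + spec.window_frames)
            for i in range(n)]


def window_correlation(
    ts: VoxelTimeSeries | np.ndarray, interval: tuple[int, int]
) -> np.ndarray:
    """Pearson correlation of every voxel pair over one window.

    The diagonal is set to 0 (self-edges are meaningless downstream).  A voxel
    with zero variance in the window gets all-zero correlations and a logged
    warning rather than NaNs.
    """
    data = ts.data if isinstance(ts, VoxelTimeSeries) else np.asarray(ts, dtype=float)
    start, end = interval
    if not (0 <= start < end <= data.shape[1]):
        raise ValueError(f"interval {interval} outside series of {data.shape[1]} frames")
    seg = data[:, start:end]
    sd = seg.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "window [%d,%d): %d zero-variance voxel(s); their correlations set to 0",
            start, end, int(flat.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(seg)
    r = np.atleast_2d(r)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    return r


@dataclass
class WindowGraph:
    """One window's correlation matrix split into thresholded channels."""

    r: np.ndarray               # symmetric, zero diagonal
    pos_adj: np.ndarray         # bool, r > theta_pos
    neg_adj: np.ndarray         # bool, -r > theta_neg
    theta_pos: float
    theta_neg: float

    def adjacency(self, channel: str) -> np.ndarray:
        return {"positive": self.pos_adj, "negative": self.neg_adj}[channel]

    def weights(self, channel: str) -> np.ndarray:
        """Channel edge weights (positive r, or |r| for the negative channel)."""
        adj = self.adjacency(channel)
        return np.where(adj, np.abs(self.r), 0.0)

    def edge_count(self, channel: str) -> int:
        return int(self.adjacency(channel).sum()) // 2

    def surviving_voxels(self, channel: str) -> int:
        return int(self.adjacency(channel).any(axis=0).sum())


def split_and_threshold(
    r: np.ndarray, theta_pos: float = THETA_POS, theta_neg: float = THETA_NEG
) -> WindowGraph:
    """Binary positive / unsigned-negative adjacency with strict thresholds.

    An edge exists in the positive channel iff r > theta_pos and in the
    negative channel iff -r > theta_neg; ties are excluded, and no pair can
    appear in both channels.
    """
    if not (0.0 < theta_pos < 1.0 and 0.0 < theta_neg < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    pos = r > theta_pos
    neg = -r > theta_neg
    np.fill_diagonal(pos, False)
    np.fill_diagonal(neg, False)
    return WindowGraph(r=r, pos_adj=pos, neg_adj=neg,
                       theta_pos=theta_pos, theta_neg=theta_neg)


@dataclass
class WindowedGraphSet:
    """All windows of one run: intervals, per-window graphs, spec."""

    spec: WindowSpec
    intervals: list[tuple[int, int]]
    graphs: list[WindowGraph]

    @property
    def n_windows(self) -> int:
        return len(self.graphs)

    def window_times(self) -> np.ndarray:
        """Window timestamps: start frame x TR, in seconds."""
        return np.array([s for s, _ in self.intervals]) * self.spec.tr_seconds

    def edge_table(self, channel: str) -> pd.DataFrame:
        """Tidy per-window edge list (window_id, voxel_i, voxel_j, weight)."""
        rows = []
        for w, g in enumerate(self.graphs):
            i, j = np.nonzero(np.triu(g.adjacency(channel), k=1))
            rows.append(pd.DataFrame({
                "window_id": w, "voxel_i": i, "voxel_j": j,
                "weight": np.abs(g.r[i, j]), "channel": channel,
            }))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["window_id", "voxel_i", "voxel_j", "weight", "channel"])


def build_windowed_graphs(
    ts: VoxelTimeSeries | np.ndarray,
    spec: WindowSpec = WindowSpec(),
    theta_pos: float = THETA_POS,
    theta_neg: float = THETA_NEG,
) -> WindowedGraphSet:
    data = ts.data if isinstance(ts, VoxelTimeSeries) else np.asarray(ts, dtype=float)
    intervals = make_windows(data.shape[1], spec)
    graphs = [split_and_threshold(window_correlation(data, iv), theta_pos, theta_neg)
              for iv in intervals]
    return WindowedGraphSet(spec=spec, intervals=intervals, graphs=graphs)


def candidate_pair_count(n_voxels: int) -> int:
    """Unordered voxel pairs entering thresholding: n(n-1)/2."""
    return n_voxels * (n_voxels - 1) // 2


@dataclass(frozen=True)
class GraphDiagnostics:
    """Advisory per-window graph health: giant component and scale-freedom."""

    giant_fraction: float
    slope: float | None         # log-log degree-distribution slope
    r_squared: float | None
    n_degree_bins: int
    small_giant: bool           # giant component below 85% of voxels
    fit_undefined: bool         # fewer than 5 occupied degree bins

    GIANT_FRACTION_FLOOR = 0.85


def degree_diagnostics(adjacency: np.ndarray, min_bins: int = 5) -> GraphDiagnostics:
    """Giant-component fraction and a log-binned log-log degree fit.

    The fit uses geometrically spaced degree bins (degree >= 1), normalised
    per bin width; the slope is reported only when at least ``min_bins`` bins
    are occupied.  Both quantities are recorded, never enforced: threshold
    choice is an operator decision.
    """
    adj = np.asarray(adjacency)
    n = adj.shape[0]
    deg = adj.sum(axis=0).astype(int)
    if n == 0 or deg.sum() == 0:
        return GraphDiagnostics(0.0, None, None, 0, True, True)

    _, labels = connected_components(csr_matrix(adj), directed=False)
    giant = np.bincount(labels).max() / n

    pos = deg[deg >= 1]
    edges = np.unique(np.geomspace(1, pos.max() + 1, num=16).astype(int))
    counts, _ = np.histogram(pos, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * (edges[1:] - 1).clip(min=1))
    occupied = counts > 0
    n_bins = int(occupied.sum())
    if n_bins < min_bins:
        return GraphDiagnostics(float(giant), None, None, n_bins,
                                giant < GraphDiagnostics.GIANT_FRACTION_FLOOR, True)
    x = np.log10(centers[occupied])
    y = np.log10(counts[occupied] / widths[occupied])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
    return GraphDiagnostics(
        float(giant), float(slope), float(r2), n_bins,
        giant < GraphDiagnostics.GIANT_FRACTION_FLOOR, False,
    )


def diagnostics_table(graphset: WindowedGraphSet, channel: str) -> pd.DataFrame:
    rows = []
    for w, g in enumerate(graphset.graphs):
        d = degree_diagnostics(g.adjacency(channel))
        rows.append({
            "window_id": w, "channel": channel,
            "edges": g.edge_count(channel),
            "surviving_voxels": g.surviving_voxels(channel),
            "giant_fraction": d.giant_fraction,
            "slope": d.slope, "r_squared": d.r_squared,
            "small_giant": d.small_giant, "fit_undefined": d.fit_undefined,
        })
    return pd.DataFrame(rows)
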