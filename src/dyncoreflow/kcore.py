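"""k-core voxel hierarchy, edge-scaled coreness, and state-transition detection.

k-core percolation peels a graph layer by layer: nodes of degree < k are
removed recursively for k = 1, 2, ... until nothing survives.  A voxel's
coreness is the largest k whose k-core still contains it, and the last
surviving core (all voxels at the maximum coreness) is the k_max_core — the
hierarchical top tier of that window.  Coreness sums track the edge count, so
values are also reported edge-scaled (divided by E) to remove the edge-count
confound when comparing windows.

A brain-state transition is an abrupt replacement of the k_max_core voxel set
between consecutive windows; the detector declares one where the Jaccard
overlap of consecutive k_max_core sets collapses between two stable runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix, issparse

from .synthetic import CANONICAL_ICS, UNCLASSIFIED
from .windows import WindowedGraphSet

logger = logging.getLogger(__name__)

__all__ = [
    "kcore_decompose",
    "kmaxcore",
    "edge_scale",
    "ic_composition",
    "detect_state_transitions",
    "centrality_panel",
    "CorenessTimecourse",
    "StateSegmentation",
    "compute_coreness_timecourse",
]


def _to_csr(adjacency) -> csr_matrix:
    if issparse(adjacency):
        a = adjacency.tocsr().astype(np.int8)
    else:
        a = csr_matrix(np.asarray(adjacency, dtype=bool).astype(np.int8))
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return a


def kcore_decompose(adjacency) -> np.ndarray:
    """Coreness of every node by bucket peeling (Batagelj-Zaversnik).

    Nodes are processed in nondecreasing degree order; when a node is peeled
    its coreness is fixed at its current degree (clipped to be nondecreasing)
    and its unpeeled neighbours' degrees drop.  Isolated nodes get coreness 0.
    Runs in O(E) and is fully deterministic.
    """
    a = _to_csr(adjacency)
    n = a.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    deg = np.asarray(a.sum(axis=1)).ravel().astype(int)
    indptr, indices = a.indptr, a.indices

    max_deg = int(deg.max(initial=0))
    # bucket sort nodes by degree
    bin_start = np.zeros(max_deg + 2, dtype=int)
    np.cumsum(np.bincount(deg, minlength=max_deg + 1), out=bin_start[1:])
    pos = np.empty(n, dtype=int)          # node -> index in vert
    vert = np.empty(n, dtype=int)         # peeling order
    fill = bin_start[:-1].copy()
    for v in range(n):
        pos[v] = fill[deg[v]]
        vert[pos[v]] = v
        fill[deg[v]] += 1

    bin_ptr = bin_start[:-1].copy()       # first unpeeled index per degree
    core = deg.copy()
    for i in range(n):
        v = vert[i]
        for u in indices[indptr[v]:indptr[v + 1]]:
            if core[u] > core[v]:
                du = core[u]
                pu, pw = pos[u], bin_ptr[du]
                w = vert[pw]
                if u != w:                # swap u to the front of its bucket
                    vert[pu], vert[pw] = w, u
                    pos[u], pos[w] = pw, pu
                bin_ptr[du] += 1
                core[u] -= 1
    return core


def kmaxcore(coreness: np.ndarray) -> tuple[int, np.ndarray]:
    """Maximum coreness and the voxels attaining it (the last surviving core).

    An empty graph (all-zero coreness) yields k_max = 0 and an empty set.
    """
    coreness = np.asarray(coreness)
    if coreness.size == 0:
        return 0, np.array([], dtype=int)
    k_max = int(coreness.max())
    if k_max == 0:
        return 0, np.array([], dtype=int)
    return k_max, np.flatnonzero(coreness == k_max)


def edge_scale(coreness: np.ndarray, n_edges: int) -> np.ndarray:
    """Coreness divided by the window's total edge count (NaN when E = 0)."""
    coreness = np.asarray(coreness, dtype=float)
    if n_edges < 1:
        return np.full_like(coreness, np.nan)
    return coreness / n_edges


def ic_composition(
    voxel_set: Iterable[int] | np.ndarray,
    ic_labels: Sequence[str] | np.ndarray,
    ics: Sequence[str] | None = None,
) -> pd.Series:
    """Fraction of a voxel set falling in each IC (fractions sum to 1).

    An empty set yields all-zero fractions (callers flag those windows).
    Unknown voxel ids raise.
    """
    labels = np.asarray(ic_labels, dtype=object)
    if ics is None:
        extra = [ic for ic in pd.unique(labels) if ic not in CANONICAL_ICS]
        ics = [ic for ic in CANONICAL_ICS if ic in set(labels)] + extra
        if UNCLASSIFIED not in ics:
            ics = list(ics) + [UNCLASSIFIED]
    idx = np.asarray(list(voxel_set), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= len(labels)):
        raise ValueError("voxel id outside the labelled range")
    counts = pd.Series(0, index=list(ics), dtype=float)
    if idx.size:
        vc = pd.Series(labels[idx]).value_counts()
        counts.loc[vc.index] = vc.values
        counts /= idx.size
    return counts


@dataclass
class CorenessTimecourse:
    """Per-window coreness vectors and k_max_core membership for one channel."""

    channel: str
    coreness: np.ndarray            # (n_windows, n_voxels) int
    k_max: np.ndarray               # (n_windows,) int
    kmax_sets: list[np.ndarray]     # voxel indices per window
    edge_counts: np.ndarray         # (n_windows,) int
    edge_scaled: np.ndarray         # (n_windows, n_voxels) float, NaN if E=0

    @property
    def n_windows(self) -> int:
        return self.coreness.shape[0]

    def coreness_edge_ratio(self) -> np.ndarray:
        """Report-only per-window ratio sum(coreness)/E (NaN for empty windows)."""
        total = self.coreness.sum(axis=1).astype(float)
        return np.divide(total, self.edge_counts,
                         out=np.full(self.n_windows, np.nan),
                         where=self.edge_counts > 0)

    def to_frame(self) -> pd.DataFrame:
        n_w, n_v = self.coreness.shape
        return pd.DataFrame({
            "window_id": np.repeat(np.arange(n_w), n_v),
            "voxel_id": np.tile(np.arange(n_v), n_w),
            "coreness": self.coreness.ravel(),
            "edge_scaled": self.edge_scaled.ravel(),
        })


def compute_coreness_timecourse(
    graphset: WindowedGraphSet, channel: str
) -> CorenessTimecourse:
    coreness, kmaxes, sets, edges = [], [], [], []
    for g in graphset.graphs:
        adj = g.adjacency(channel)
        core = kcore_decompose(adj)
        k, s = kmaxcore(core)
        coreness.append(core)
        kmaxes.append(k)
        sets.append(s)
        edges.append(g.edge_count(channel))
    coreness = np.asarray(coreness, dtype=int)
    edge_counts = np.asarray(edges, dtype=int)
    scaled = np.vstack([edge_scale(c, e) for c, e in zip(coreness, edge_counts)])
    ratio = np.nanmean(
        np.divide(coreness.sum(axis=1), edge_counts,
                  out=np.full(len(edges), np.nan), where=edge_counts > 0)
    ) if edge_counts.any() else np.nan
    logger.info("channel %s: %d windows, mean sum(coreness)/E = %.3f",
                channel, len(edges), ratio)
    return CorenessTimecourse(
        channel=channel, coreness=coreness, k_max=np.asarray(kmaxes),
        kmax_sets=sets, edge_counts=edge_counts, edge_scaled=scaled,
    )


@dataclass
class StateSegmentation:
    """Detected transitions, segments, and the consecutive-overlap trace."""

    transitions: list[int]              # first window of each new segment
    segments: list[tuple[int, int]]     # half-open window intervals covering all
    similarity: np.ndarray              # (n_windows - 1,) Jaccard trace
    empty_windows: np.ndarray           # bool flag per window
    tau: float
    min_run: int


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    if a.size == 0 or b.size == 0:
        return 0.0
    sa, sb = set(a.tolist()), set(b.tolist())
    return len(sa & sb) / len(sa | sb)


def detect_state_transitions(
    kmax_sets: Sequence[np.ndarray],
    tau: float = 0.2,
    min_run: int = 5,
) -> StateSegmentation:
    """Declare a transition where the k_max_core set is abruptly replaced.

    The reported similarity trace is the consecutive-window Jaccard overlap
    s(t) = Jaccard(set_t, set_{t+1}).  Detection itself compares each window
    against the *established reference* of the current segment (the union of
    the ``min_run`` coherent windows that opened it), because consecutive
    windows share almost all their frames and the lag-1 trace can stay
    smooth through a genuine turnover.  A transition is declared when

    * the current window's overlap with the segment reference falls below
      ``tau``, and
    * from some later window a new regime appears: ``min_run`` consecutive
      non-empty windows, mutually coherent (consecutive Jaccard >= tau) and
      all fully detached from the old reference (overlap < tau), and
    * the old segment itself had persisted >= ``min_run`` windows.

    The transition index is the first window whose overlap with the new
    regime's reference exceeds its overlap with the old one — the point
    where the incoming state takes the majority.  Windows with empty
    k_max_core are flagged, contribute similarity 0, and can never open or
    extend a regime, so noise-dominated channels (negative graphs) yield no
    transitions.
    """
    n = len(kmax_sets)
    if n < 2:
        raise ValueError("need at least 2 windows to detect transitions")
    sets = [np.asarray(s, dtype=int) for s in kmax_sets]
    empty = np.array([len(s) == 0 for s in sets])
    if empty.any():
        logger.warning("%d window(s) with empty k_max_core (similarity forced to 0)",
                       int(empty.sum()))
    sim = np.array([_jaccard(sets[t], sets[t + 1]) for t in range(n - 1)])

    def coherent_run(u: int) -> bool:
        """S_u .. S_{u+min_run-1} non-empty and consecutively similar."""
        if u + min_run > n:
            return False
        if empty[u : u + min_run].any():
            return False
        return all(_jaccard(sets[v], sets[v + 1]) >= tau
                   for v in range(u, u + min_run - 1))

    def run_union(u: int) -> np.ndarray:
        return np.unique(np.concatenate(sets[u : u + min_run]))

    transitions: list[int] = []
    # establish the initial segment reference
    start = next((u for u in range(n) if coherent_run(u)), None)
    if start is None:
        return StateSegmentation(
            transitions=[], segments=[(0, n)], similarity=sim,
            empty_windows=empty, tau=tau, min_run=min_run,
        )
    ref = run_union(start)
    seg_start = start
    t = start + min_run
    while t < n:
        if not empty[t] and _jaccard(sets[t], ref) >= tau:
            t += 1
            continue
        # candidate turnover: search for a detached, persistent new regime
        u = t
        while u < n:
            if not empty[u] and _jaccard(sets[u], ref) >= tau:
                t = u + 1          # segment resumes: flicker, not a transition
                break
            if (coherent_run(u)
                    and all(_jaccard(sets[v], ref) < tau
                            for v in range(u, u + min_run))
                    and t - seg_start >= min_run):
                new_ref = run_union(u)
                loc = next(
                    (v for v in range(seg_start, u + min_run)
                     if not empty[v]
                     and _jaccard(sets[v], new_ref) > _jaccard(sets[v], ref)),
                    u,
                )
                transitions.append(int(loc))
                ref = new_ref
                seg_start = u
                t = u + min_run
                break
            u += 1
        else:
            t = n

    cuts = [0] + transitions + [n]
    segments = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    return StateSegmentation(
        transitions=transitions, segments=segments, similarity=sim,
        empty_windows=empty, tau=tau, min_run=min_run,
    )


def composition_table(
    kmax_sets: Sequence[np.ndarray], ic_labels: np.ndarray
) -> pd.DataFrame:
    """Window x IC counts of k_max_core members (stacked-histogram twin)."""
    rows = []
    for w, s in enumerate(kmax_sets):
        frac = ic_composition(s, ic_labels)
        rows.append(frac * len(s))
    df = pd.DataFrame(rows)
    df.index.name = "window_id"
    return df


def centrality_panel(
    adjacency, kmax_set: np.ndarray
) -> dict[str, dict[str, object]]:
    """Classical centrality top sets matched in size to the k_max_core.

    For degree, eigenvector, betweenness centrality and clustering
    coefficient, the "max voxels" are the top-q fraction where
    q = |k_max_core| / n (all ties at the cut included); each measure reports
    its set and the Jaccard overlap with the k_max_core.  Eigenvector
    centrality is computed on the giant component when disconnected.
    """
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    if n == 0 or not adj.any():
        raise ValueError("centrality panel needs a nonempty graph")
    g = nx.from_numpy_array(adj.astype(int))
    measures: dict[str, np.ndarray] = {}
    measures["degree"] = np.array([d for _, d in sorted(g.degree())], dtype=float)

    giant = max(nx.connected_components(g), key=len)
    ev = nx.eigenvector_centrality_numpy(g.subgraph(giant))
    vec = np.zeros(n)
    for v, val in ev.items():
        vec[v] = val
    measures["eigenvector"] = vec

    bt = nx.betweenness_centrality(g)
    measures["betweenness"] = np.array([bt[v] for v in range(n)])
    cl = nx.clustering(g)
    measures["clustering"] = np.array([cl[v] for v in range(n)])

    k = max(len(kmax_set), 1)
    out: dict[str, dict[str, object]] = {}
    for name, vals in measures.items():
        cut = np.sort(vals)[::-1][k - 1]
        top = np.flatnonzero(vals >= cut)     # ties included
        out[name] = {
            "values": vals,
            "top_set": top,
            "overlap_with_kmaxcore": _jaccard(top, np.asarray(kmax_set)),
        }
    return out
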