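"""Shared fixtures: small synthetic runs and benchmark graphs.

Everything is generated programmatically at test time; the default desk-scale
recovery conditions (300 voxels x 600 frames) are only used where a test
genuinely needs them, smaller configurations elsewhere.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from dyncoreflow import (SyntheticConfig, build_windowed_graphs,
                         generate_voxel_timeseries)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Two states, one boundary, 60 voxels x 300 frames: fast unit-scale run."""
    return SyntheticConfig(
        n_voxels=60,
        n_frames=300,
        ic_spec=(("DMN", 20), ("VN", 18), ("SMN", 12)),
        n_states=2,
        state_boundaries=(150,),
        state_coupling=({"DMN": 1.0}, {"VN": 1.0, "SMN": 1.0}),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_cfg):
    ts, truth = generate_voxel_timeseries(small_cfg)
    return ts, truth


@pytest.fixture(scope="session")
def small_graphs(small_run):
    ts, _ = small_run
    return build_windowed_graphs(ts)


@pytest.fixture(scope="session")
def default_run():
    """One realization of the default recovery conditions (300 x 600)."""
    cfg = SyntheticConfig(seed=3)
    ts, truth = generate_voxel_timeseries(cfg)
    return cfg, ts, truth


def unit_length_metric_graph(g: nx.Graph, scale: float = 1.0):
    """MetricGraph of a networkx graph with all edge lengths = scale."""
    from dyncoreflow import MetricGraph, to_metric_graph

    adj = nx.to_numpy_array(g) > 0
    mg = to_metric_graph(adj)
    return MetricGraph(mg.nodes, mg.edges, np.full(mg.n_edges, scale),
                       mg.weights, mg.component_fraction)


@pytest.fixture
def lollipop_graph() -> nx.Graph:
    """K4 with a 3-edge pendant path: the canonical afferent != efferent fixture."""
    g = nx.complete_graph(4)
    g.add_edges_from([(3, 4), (4, 5), (5, 6)])
    return g
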