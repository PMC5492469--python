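"""Shared fixtures: toy networks and one fully analyzed planted community.

The planted-community analysis (threshold scan, network, modules, null
distribution) is expensive enough to share session-wide; individual tests
assert different properties of the same deterministic run.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pytest

import bloomnet as bn
from bloomnet.rmt import EcologicalNetwork


def make_network(edges, signs=None) -> EcologicalNetwork:
    """Build a network from (u, v) pairs or (u, v, r) triples."""
    g = nx.Graph()
    for e in edges:
        if len(e) == 3:
            u, v, r = e
        else:
            (u, v), r = e, 1.0
        g.add_edge(u, v, correlation=float(r),
                   sign="positive" if r > 0 else "negative")
    return EcologicalNetwork(g)


@pytest.fixture
def two_triangles_joined():
    return make_network([("a", "b"), ("b", "c"), ("a", "c"),
                         ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")])


@pytest.fixture
def two_triangles_apart():
    return make_network([("a", "b"), ("b", "c"), ("a", "c"),
                         ("d", "e"), ("e", "f"), ("d", "f")])


@dataclass
class PlantedAnalysis:
    community: bn.PlantedCommunity
    filtered: bn.OtuTable
    corr: bn.CorrelationMatrix
    scan: bn.ThresholdScanResult
    network: EcologicalNetwork
    partition: dict[str, int]
    modularity: float


@pytest.fixture(scope="session")
def planted_analysis() -> PlantedAnalysis:
    """The default planted community analyzed end to end (deterministic)."""
    community = bn.generate_planted_community()
    from bloomnet.pipeline import PipelineConfig, run_network_stage

    config = PipelineConfig()
    filtered, corr, scan, threshold, net = run_network_stage(community.counts, config)
    assert threshold is not None, "RMT scan found no threshold on the default community"
    partition, q = bn.fast_greedy_partition(net)
    net.partition = partition
    return PlantedAnalysis(community, filtered, corr, scan, net, partition, q)
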