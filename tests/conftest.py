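"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from netpotential import AnnotatedNetwork, make_planted_scenario, total_potential
from netpotential.cocktails import RepressionModel


def annotated(graph: nx.Graph, conc: dict[str, float], sample_id: str = "s") -> AnnotatedNetwork:
    return AnnotatedNetwork(network=graph, sample_id=sample_id, concentration=conc)


def uniform_annotated(graph: nx.Graph, c: float = 1.0) -> AnnotatedNetwork:
    return annotated(graph, {n: c for n in graph.nodes})


def brute_force_delta_g(net: AnnotatedNetwork, gene: str) -> float:
    """Rebuild-and-recompute oracle: zero the gene, recompute every node's
    potential from scratch, and sum the per-node differences.

    Independent of the incremental path: it never exploits locality. Summing
    per-node differences (untouched nodes cancel exactly in floating point)
    keeps the comparison free of global-sum cancellation noise.
    """
    before = total_potential(net)
    conc = dict(net.concentration)
    conc[gene] = 0.0
    after = total_potential(AnnotatedNetwork(net.network, net.sample_id, conc))
    return math.fsum(
        after.node_potential[n] - before.node_potential[n] for n in net.network.nodes
    )


def random_annotated_network(rng: np.random.Generator, max_n: int = 200) -> AnnotatedNetwork:
    """A random sparse graph with log-normal, partly-zero concentrations."""
    n = int(rng.integers(12, max_n + 1))
    graph = nx.gnm_random_graph(n, int(rng.integers(n, 3 * n)), seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(graph, {i: f"G{i:04d}" for i in graph.nodes})
    conc = rng.lognormal(1.0, 1.0, size=n)
    conc[rng.random(n) < 0.15] = 0.0
    return annotated(graph, dict(zip(sorted(graph.nodes), conc)))


def brute_force_loss(mirnas, tmap, sets, model: RepressionModel = RepressionModel()) -> float:
    """Direct re-evaluation of the cocktail loss from its definition."""

    def a(c: int) -> float:
        if c <= model.min_multiplicity - 1:
            return 0.0
        return min(model.saturation, model.r * c)

    loss = 0.0
    for gene in sets.housekeeping:
        c = sum(gene in tmap.targets(m) for m in mirnas)
        loss += a(c) * abs(sets.signed_delta_g[gene])
    for gene in sets.targets:
        c = sum(gene in tmap.targets(m) for m in mirnas)
        loss -= a(c) * abs(sets.signed_delta_g[gene])
    return loss


def enumerate_cocktails_brute(candidates, k, tmap, sets, model=RepressionModel()):
    """Exhaustive enumeration oracle: (loss, sorted ids) for every combo."""
    return sorted(
        (brute_force_loss(set(combo), tmap, sets, model), tuple(sorted(combo)))
        for combo in itertools.combinations(candidates, k)
    )


@pytest.fixture(scope="session")
def planted():
    return make_planted_scenario(seed=0)


@pytest.fixture
def star4() -> AnnotatedNetwork:
    """Star with centre N0 and three leaves, all concentrations 1."""
    graph = nx.relabel_nodes(nx.star_graph(3), {i: f"N{i}" for i in range(4)})
    return uniform_annotated(graph)
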