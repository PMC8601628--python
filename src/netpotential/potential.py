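"""Network potential: a Gibbs-like node statistic on expression-weighted graphs.

The potential of node *i* with concentration :math:`C_i` and neighbours *j* is

.. math:: G_i = C_i \\ln \\frac{C_i}{\\sum_j C_j + C_i},

always <= 0 because the log argument is a fraction in (0, 1]. The total
potential :math:`G = \\sum_i G_i` summarises one sample's network state; the
repression disruption :math:`\\Delta G` of a gene is the (always >= 0) rise in
total potential after computationally zeroing that gene's concentration —
the statistic by which therapeutic targets are ranked.

Conventions at the boundary of the formula's domain, chosen as the continuous
limits: :math:`G_i = 0` when :math:`C_i = 0` (the :math:`x \\ln x \\to 0`
limit), and :math:`G_i = 0` when the neighbour sum is 0, including isolated
nodes (the ratio is exactly 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import UnknownGeneError
from .graph_io import AnnotatedNetwork


@dataclass
class PotentialResult:
    """Per-node potentials G_i and their total G for one sample (unitless)."""

    sample_id: str
    node_potential: dict[str, float]
    total: float


@dataclass
class RepressionOutcome:
    """Disruption from zeroing one gene: ΔG >= 0 and the locality footprint."""

    gene: str
    delta_g: float
    touched_nodes: int


def node_potential(c_i: float, neighbor_sum: float) -> float:
    """Potential of a single node given its concentration and neighbour sum."""
    if not (c_i >= 0.0 and neighbor_sum >= 0.0):
        raise ValueError(f"concentrations must be >= 0, got c_i={c_i}, neighbor_sum={neighbor_sum}")
    if not (math.isfinite(c_i) and math.isfinite(neighbor_sum)):
        raise ValueError("concentrations must be finite")
    if c_i == 0.0 or neighbor_sum == 0.0:
        return 0.0
    return c_i * math.log(c_i / (neighbor_sum + c_i))


def _neighbor_sums(net: AnnotatedNetwork) -> dict[str, float]:
    conc = net.concentration
    return {
        node: math.fsum(conc[nbr] for nbr in net.network.neighbors(node))
        for node in net.network.nodes
    }


def total_potential(net: AnnotatedNetwork) -> PotentialResult:
    """Compute G_i for every node and their sum G (isolated nodes contribute 0)."""
    conc = net.concentration
    sums = _neighbor_sums(net)
    node_pot = {node: node_potential(conc[node], sums[node]) for node in net.network.nodes}
    return PotentialResult(
        sample_id=net.sample_id,
        node_potential=node_pot,
        total=math.fsum(node_pot.values()),
    )


def repress_delta_g(
    net: AnnotatedNetwork, gene: str, baseline: PotentialResult | None = None
) -> RepressionOutcome:
    """ΔG from zeroing ``gene``, re-evaluating only the gene and its neighbours.

    Zeroing C_g sends G_g to 0 and lowers each neighbour's denominator, so only
    deg(g)+1 potentials can change; everything else is untouched. Each local
    term is mathematically >= 0 and is clamped at 0 against rounding so the
    sign invariant holds exactly. The input network is not mutated.
    """
    graph = net.network
    if gene not in graph:
        raise UnknownGeneError(f"gene {gene!r} is not a node of the network")
    conc = net.concentration
    c_g = conc[gene]

    if baseline is not None:
        old_g = baseline.node_potential[gene]
    else:
        old_g = node_potential(c_g, math.fsum(conc[n] for n in graph.neighbors(gene)))

    terms = [-old_g]
    touched = 1 if old_g != 0.0 else 0
    for nbr in graph.neighbors(gene):
        s_old = math.fsum(conc[n] for n in graph.neighbors(nbr))
        if baseline is not None:
            old = baseline.node_potential[nbr]
        else:
            old = node_potential(conc[nbr], s_old)
        new = node_potential(conc[nbr], max(0.0, s_old - c_g))
        if new != old:
            touched += 1
        terms.append(max(0.0, new - old))
    return RepressionOutcome(gene=gene, delta_g=max(0.0, math.fsum(terms)), touched_nodes=touched)


def batch_delta_g(net: AnnotatedNetwork) -> dict[str, float]:
    """ΔG for every node, each against the same unrepressed baseline.

    Repressions are independent, not cumulative: each gene is scored by its own
    one-at-a-time disruption. Neighbour sums are precomputed once, giving
    O(|E|) total work.
    """
    graph = net.network
    conc = net.concentration
    sums = _neighbor_sums(net)
    result: dict[str, float] = {}
    for gene in graph.nodes:
        c_g = conc[gene]
        terms = [-node_potential(c_g, sums[gene])]
        if c_g > 0.0:
            for nbr in graph.neighbors(gene):
                old = node_potential(conc[nbr], sums[nbr])
                new = node_potential(conc[nbr], max(0.0, sums[nbr] - c_g))
                terms.append(max(0.0, new - old))
        result[gene] = max(0.0, math.fsum(terms))
    return result
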