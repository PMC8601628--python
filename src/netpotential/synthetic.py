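"""Synthetic networks, expression profiles and target maps for testing.

Real inputs to this pipeline are a sparse, hub-heavy protein-interaction
graph, a non-negative expression matrix that is roughly log-normal with a
spike of unexpressed (zero) transcripts, a promiscuous miRNA → gene bipartite
mapping with a heavy-tailed out-degree, and a housekeeping list biased toward
highly expressed genes. The generators here emulate that statistical shape —
never any particular dataset's values — so every pipeline stage can be
exercised without downloads. All generators are pure functions of their
spec/seed: identical inputs give bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .graph_io import write_edge_list
from .mirna import TargetMap, build_target_map, write_target_map
from .potential import batch_delta_g
from .graph_io import AnnotatedNetwork
from .ranking import rank_targets

TOY_MODELS = ("star", "cycle", "complete", "two-hub")
GRAPH_MODELS = ("preferential-attachment", "powerlaw-configuration") + TOY_MODELS


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic input bundle.

    Expression is log-normal on the natural-log scale (``log_mean``,
    ``log_sd``) with a ``zero_inflation`` fraction of genes silenced in every
    sample; replicates are small log-normal perturbations (``replicate_sd``)
    of a shared per-gene mean, mimicking low between-replicate variance.
    miRNA target counts follow a heavy-tailed (log-normal) promiscuity model,
    optionally degree-biased toward hubs.
    """

    n_genes: int = 100
    graph_model: str = "preferential-attachment"
    attachment_m: int = 2
    log_mean: float = 2.0
    log_sd: float = 0.8
    zero_inflation: float = 0.15
    replicate_sd: float = 0.05
    n_samples: int = 3
    n_mirnas: int = 30
    mean_targets: float = 8.0
    promiscuity_sd: float = 0.8
    hub_bias: bool = False
    housekeeping_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_mirnas < 0 or self.n_samples < 1:
            raise ValueError("counts must be positive")
        for frac in (self.zero_inflation, self.housekeeping_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.graph_model not in GRAPH_MODELS:
            raise ValueError(f"unknown graph model {self.graph_model!r}; choose from {GRAPH_MODELS}")


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def make_network(spec: FixtureSpec) -> nx.Graph:
    """Generate the interaction graph named by ``spec.graph_model``."""
    n = spec.n_genes
    if spec.graph_model == "preferential-attachment":
        base = nx.barabasi_albert_graph(n, min(spec.attachment_m, n - 1), seed=spec.seed)
    elif spec.graph_model == "powerlaw-configuration":
        rng = np.random.default_rng(spec.seed)
        degrees = np.minimum(rng.zipf(2.3, size=n) + spec.attachment_m - 1, n - 1)
        if degrees.sum() % 2:
            degrees[int(np.argmax(degrees))] += 1
        multi = nx.configuration_model(degrees.tolist(), seed=spec.seed)
        base = nx.Graph(multi)
        base.remove_edges_from(nx.selfloop_edges(base))
    elif spec.graph_model == "star":
        base = nx.star_graph(n - 1)
    elif spec.graph_model == "cycle":
        base = nx.cycle_graph(n)
    elif spec.graph_model == "complete":
        base = nx.complete_graph(n)
    elif spec.graph_model == "two-hub":
        base = nx.Graph()
        leaves = range(2, n)
        for leaf in leaves:
            base.add_edge(0 if leaf % 2 else 1, leaf)
        base.add_edge(0, 1)
    else:  # pragma: no cover - guarded by FixtureSpec validation
        raise ValueError(spec.graph_model)
    return nx.relabel_nodes(base, {i: _gene_name(i) for i in base.nodes})


def make_expression(spec: FixtureSpec, network: nx.Graph) -> pd.DataFrame:
    """Draw a genes x samples matrix of zero-inflated log-normal expression."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    genes = sorted(network.nodes)
    base = rng.lognormal(spec.log_mean, spec.log_sd, size=len(genes))
    silenced = rng.random(len(genes)) < spec.zero_inflation
    base[silenced] = 0.0
    noise = rng.lognormal(0.0, spec.replicate_sd, size=(len(genes), spec.n_samples))
    values = base[:, None] * noise
    samples = [f"S{i + 1}" for i in range(spec.n_samples)]
    return pd.DataFrame(values, index=genes, columns=samples)


def make_target_map(spec: FixtureSpec, network: nx.Graph) -> TargetMap:
    """Draw a promiscuity-heavy miRNA → gene map with 1-5 supporting sources.

    With ``hub_bias`` on, target picks are degree-weighted so promiscuous
    miRNAs preferentially hit hub genes, as homology-based predictions tend to.
    Source counts span 1-5 so downstream minimum-source filtering is
    exercised; pairs are built with ``min_sources=1`` (no filtering here).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    genes = sorted(network.nodes)
    degrees = np.array([network.degree[g] for g in genes], dtype=float)
    probs = None
    if spec.hub_bias and degrees.sum() > 0:
        probs = degrees + 1.0
        probs /= probs.sum()
    triples = []
    for i in range(spec.n_mirnas):
        count = int(
            np.clip(round(rng.lognormal(math.log(spec.mean_targets), spec.promiscuity_sd)),
                    1, len(genes))
        )
        picks = rng.choice(len(genes), size=count, replace=False, p=probs)
        for gi in picks:
            triples.append((f"MIR-{i:03d}", genes[gi], int(rng.integers(1, 6))))
    return build_target_map(triples, min_sources=1)


def housekeeping_list(spec: FixtureSpec, expression: pd.DataFrame) -> list[str]:
    """Pick the housekeeping fraction, biased toward high mean expression."""
    n_hk = max(1, int(round(spec.housekeeping_fraction * len(expression))))
    mean = expression.mean(axis=1).sort_values(ascending=False, kind="stable")
    return sorted(mean.index[:n_hk])


@dataclass
class PlantedScenario:
    """End-to-end fixture with known qualitative outcomes.

    ``expected`` records what the construction guarantees: the planted hub is
    the rank-1 target; the selective miRNA (dense coverage of the strongest
    targets, zero housekeeping) belongs to the best cocktail; the promiscuous
    miRNA (heavy housekeeping coverage, weak-target hits only) belongs to the
    worst.
    """

    network: nx.Graph
    expression: pd.DataFrame
    target_map: TargetMap
    housekeeping: list[str]
    expected: dict[str, Any]
    seed: int = 0


def make_planted_scenario(seed: int = 0, n_genes: int = 60) -> PlantedScenario:
    """Construct the planted end-to-end scenario.

    A preferential-attachment graph gets one planted hub wired to half the
    nodes and given 10x the largest other concentration, making it the
    dominant ΔG gene. The miRNA panel is wired against the *realized* ΔG
    ranking: one selective miRNA covering ranks 1-3 with no housekeeping
    targets; one promiscuous miRNA covering ranks 9-10 plus most of the
    housekeeping set; four filler miRNAs with pairwise-disjoint target pairs
    and housekeeping picks drawn from the promiscuous miRNA's pool, so
    cooperative housekeeping repression occurs only alongside it. A decoy
    miRNA carried by a single source database checks the min-source filter.
    """
    spec = FixtureSpec(n_genes=n_genes, seed=seed, n_samples=2, zero_inflation=0.0,
                       log_mean=2.0, log_sd=0.5)
    network = make_network(spec)
    genes = sorted(network.nodes)
    hub = genes[0]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    others = [g for g in genes if g != hub]
    for g in rng.choice(others, size=n_genes // 2, replace=False):
        network.add_edge(hub, g)

    expression = make_expression(spec, network)
    hub_conc = 10.0 * float(expression.drop(index=hub).values.max())
    expression.loc[hub] = hub_conc

    tables = {
        sid: batch_delta_g(
            AnnotatedNetwork(network=network, sample_id=sid,
                             concentration=expression[sid].to_dict())
        )
        for sid in expression.columns
    }
    ranked = rank_targets(tables)
    by_rank = ranked.top(30)
    top10 = by_rank[:10]
    hk_pool = by_rank[10:25]  # promiscuous miRNA's housekeeping coverage
    housekeeping = sorted(by_rank[10:30])

    triples: list[tuple[str, str, int]] = []

    def add(mirna: str, targets: list[str], n_sources: int = 3) -> None:
        triples.extend((mirna, g, n_sources) for g in targets)

    add("MIR-SELECT", top10[:3])
    add("MIR-PROMISC", top10[8:10] + hk_pool)
    filler_pairs = [(0, 3), (1, 4), (2, 5), (6, 7)]  # pairwise disjoint top-10 ranks
    for fi, (a, b) in enumerate(filler_pairs, start=1):
        add(f"MIR-F{fi}", [top10[a], top10[b]] + hk_pool[2 * fi - 2: 2 * fi])
    add("MIR-DECOY", top10[:2], n_sources=1)  # dropped at min_sources=2

    target_map = build_target_map(triples, min_sources=1)
    expected = {
        "hub": hub,
        "rank_1": hub,
        "selective": "MIR-SELECT",
        "promiscuous": "MIR-PROMISC",
        "decoy": "MIR-DECOY",
        "top_targets": top10,
    }
    return PlantedScenario(
        network=network, expression=expression, target_map=target_map,
        housekeeping=housekeeping, expected=expected, seed=seed,
    )


def write_bundle(scenario: PlantedScenario, outdir: str | Path) -> dict[str, str]:
    """Write a complete input bundle (edge list, expression, target map,
    housekeeping list, manifest with expected outcomes) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": str(outdir / "network.tsv"),
        "expression": str(outdir / "expression.tsv"),
        "target_map": str(outdir / "target_map.tsv"),
        "housekeeping": str(outdir / "housekeeping.txt"),
        "manifest": str(outdir / "scenario.yaml"),
    }
    write_edge_list(scenario.network, paths["network"])
    scenario.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
    write_target_map(scenario.target_map, paths["target_map"])
    with open(paths["housekeeping"], "w") as fh:
        fh.write("\n".join(scenario.housekeeping) + "\n")
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump({"seed": scenario.seed, "expected": scenario.expected}, fh)
    return paths
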