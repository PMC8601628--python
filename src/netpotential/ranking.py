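"""Rank genes by mean repression disruption and test them against a
degree-preserving rewiring null.

The null model randomizes topology while keeping every node's degree and the
sample's expression fixed: repeated double-edge swaps (pick two edges u–v and
x–y, rewire to u–x and v–y, rejecting self-loops and duplicates) produce a
random simple graph with the original degree sequence. Observed ΔG values are
compared to the per-gene null mean ± z·sd with a Bonferroni-adjusted normal
quantile.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import RewireExhaustedError, UnknownGeneError
from .graph_io import AnnotatedNetwork, attach_expression
from .potential import batch_delta_g, repress_delta_g

logger = logging.getLogger(__name__)


@dataclass
class DeltaGTable:
    """Gene x sample ΔG matrix with mean-based descending ranks.

    Rank 1 is the gene with the largest mean ΔG; ties break lexicographically
    by symbol so rankings are deterministic.
    """

    delta_g: pd.DataFrame  # genes x samples
    mean_delta_g: pd.Series
    rank: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.delta_g.index)

    @property
    def samples(self) -> list[str]:
        return list(self.delta_g.columns)

    def top(self, k: int) -> list[str]:
        """The k highest-ranked genes, in rank order."""
        return list(self.rank.sort_values().index[:k])

    def frame(self) -> pd.DataFrame:
        """Flat table (rank, gene, mean_delta_g, per-sample columns), rank order."""
        out = self.delta_g.copy()
        out.insert(0, "mean_delta_g", self.mean_delta_g)
        out.insert(0, "rank", self.rank)
        return out.sort_values("rank")


@dataclass
class NullSummary:
    """Normal-approximation summary of one gene's rewiring null distribution."""

    gene: str
    mean_null: float
    sd_null: float
    ci_low: float
    ci_high: float
    n_iterations: int
    alpha_nominal: float
    n_tests: int


def rank_targets(tables: dict[str, dict[str, float]]) -> DeltaGTable:
    """Aggregate per-sample ΔG maps into a mean-ranked table.

    Only genes present in every sample are ranked (the intersection; dropped
    genes are logged). The mean is unweighted across samples.
    """
    if not tables:
        raise ValueError("no samples provided")
    gene_sets = [set(t) for t in tables.values()]
    shared = set.intersection(*gene_sets)
    if not shared:
        raise ValueError("no genes shared by all samples")
    union = set.union(*gene_sets)
    if union - shared:
        logger.info("rank_targets: dropped %d genes absent from some samples", len(union - shared))
    genes = sorted(shared)
    df = pd.DataFrame({sid: [t[g] for g in genes] for sid, t in tables.items()}, index=genes)
    mean = df.mean(axis=1)
    order = sorted(genes, key=lambda g: (-mean[g], g))
    rank = pd.Series({g: i + 1 for i, g in enumerate(order)}, name="rank")
    return DeltaGTable(delta_g=df, mean_delta_g=mean, rank=rank.loc[genes])


def subset_ranking(table: DeltaGTable, allow_list: set[str]) -> DeltaGTable:
    """Restrict a ranking to an allow-list (e.g. cancer-implicated genes)."""
    if not allow_list:
        raise ValueError("allow_list is empty")
    allowed = {g.upper() for g in allow_list}
    keep = [g for g in table.genes if g in allowed]
    if not keep:
        raise ValueError("allow_list has no overlap with the ranked genes")
    df = table.delta_g.loc[keep]
    mean = table.mean_delta_g.loc[keep]
    order = sorted(keep, key=lambda g: (-mean[g], g))
    rank = pd.Series({g: i + 1 for i, g in enumerate(order)})
    return DeltaGTable(delta_g=df, mean_delta_g=mean, rank=rank.loc[keep])


def rewire_preserving_degrees(
    network: nx.Graph,
    n_swaps: int,
    seed: int | _random.Random,
    max_tries: int | None = None,
    strict: bool = False,
) -> nx.Graph:
    """Randomize topology by ``n_swaps`` accepted double-edge swaps.

    Only successful swaps count toward ``n_swaps`` (so the amount of
    randomization is independent of the rejection rate); proposals creating a
    self-loop or duplicate edge are rejected and retried within ``max_tries``
    total proposals (default 100 x n_swaps). On a swap-degenerate graph (e.g. a
    triangle, where no proposal can succeed) the budget runs out: by default
    the graph randomized so far is returned with a warning, with degrees intact
    either way; ``strict=True`` raises instead. Same seed, same output.
    """
    if network.number_of_edges() < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = seed if isinstance(seed, _random.Random) else _random.Random(seed)
    if max_tries is None:
        max_tries = max(100 * n_swaps, 100)

    graph = nx.Graph()
    graph.add_nodes_from(network.nodes)
    graph.add_edges_from(network.edges)
    edges = [tuple(e) for e in graph.edges]

    accepted = tries = 0
    n_edges = len(edges)
    while accepted < n_swaps:
        if tries >= max_tries:
            msg = f"rewiring accepted {accepted}/{n_swaps} swaps in {max_tries} proposals"
            if strict:
                raise RewireExhaustedError(msg)
            logger.warning("rewire_preserving_degrees: %s; returning as-is", msg)
            break
        tries += 1
        i = rng.randrange(n_edges)
        j = rng.randrange(n_edges)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        # propose u-x, v-y
        if u == x or v == y:
            continue
        if graph.has_edge(u, x) or graph.has_edge(v, y):
            continue
        graph.remove_edge(u, v)
        graph.remove_edge(x, y)
        graph.add_edge(u, x)
        graph.add_edge(v, y)
        edges[i] = (u, x)
        edges[j] = (v, y)
        accepted += 1
    return graph


def null_distribution(
    network: nx.Graph,
    expression: pd.DataFrame,
    sample_id: str,
    genes: list[str],
    n_iterations: int = 1000,
    swap_multiplier: int = 100,
    alpha: float = 1e-4,
    n_tests: int | None = None,
    seed: int = 0,
    method: str = "normal",
) -> list[NullSummary]:
    """Per-gene null distribution of ΔG over degree-preserving rewirings.

    Each iteration rewires the network with ``n_nodes * swap_multiplier``
    accepted swaps, keeps the sample's expression unchanged, and recomputes ΔG
    for the listed genes. The summary is the per-gene mean and sd over
    iterations with a two-sided CI at level ``1 - alpha/n_tests`` (Bonferroni;
    ``n_tests`` defaults to the number of genes scored). ``method="normal"``
    (default) uses mean ± z·sd; ``method="percentile"`` uses empirical
    quantiles, which cannot resolve extreme tails at moderate iteration
    counts. Per-iteration seeds derive from the master seed, so identical
    seeds give bitwise-identical summaries.
    """
    if n_iterations < 2:
        raise ValueError("n_iterations must be >= 2 (sd undefined otherwise)")
    missing = [g for g in genes if g not in network]
    if missing:
        raise UnknownGeneError(f"genes not in network: {missing[:5]}")
    if n_tests is None:
        n_tests = len(genes)

    n_swaps = network.number_of_nodes() * swap_multiplier
    child_seeds = np.random.SeedSequence(seed).generate_state(n_iterations) % (2**31)
    draws = np.empty((n_iterations, len(genes)))
    for it in range(n_iterations):
        rewired = rewire_preserving_degrees(network, n_swaps, int(child_seeds[it]))
        annotated = attach_expression(rewired, expression, sample_id)
        for gi, gene in enumerate(genes):
            draws[it, gi] = repress_delta_g(annotated, gene).delta_g

    adjusted = alpha / n_tests
    z = float(norm.ppf(1.0 - adjusted / 2.0))
    summaries = []
    for gi, gene in enumerate(genes):
        col = draws[:, gi]
        mean = float(col.mean())
        sd = float(col.std(ddof=1))
        if method == "normal":
            lo, hi = mean - z * sd, mean + z * sd
        elif method == "percentile":
            lo = float(np.quantile(col, adjusted / 2.0))
            hi = float(np.quantile(col, 1.0 - adjusted / 2.0))
        else:
            raise ValueError(f"unknown CI method {method!r}")
        summaries.append(
            NullSummary(
                gene=gene, mean_null=mean, sd_null=sd, ci_low=lo, ci_high=hi,
                n_iterations=n_iterations, alpha_nominal=alpha, n_tests=n_tests,
            )
        )
    return summaries


def flag_within_null(observed: DeltaGTable, nulls: list[NullSummary]) -> pd.DataFrame:
    """Flag genes whose mean ΔG lies inside the (closed) null CI.

    Genes inside the interval are indistinguishable from a topology-random
    network: their disruption reflects degree and expression alone.
    """
    rows = []
    for summary in nulls:
        gene = summary.gene
        if gene not in observed.mean_delta_g.index:
            raise UnknownGeneError(f"gene {gene!r} has no observed ΔG")
        mean = float(observed.mean_delta_g[gene])
        rows.append(
            {
                "gene": gene,
                "mean_delta_g": mean,
                "mean_null": summary.mean_null,
                "sd_null": summary.sd_null,
                "ci_low": summary.ci_low,
                "ci_high": summary.ci_high,
                "inside_ci": summary.ci_low <= mean <= summary.ci_high,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
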