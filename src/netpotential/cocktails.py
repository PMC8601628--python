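"""Enumerate and rank k-miRNA cocktails by a cooperative-repression loss.

Giving several miRNAs together at low dose means only transcripts hit by
multiple cocktail members are meaningfully repressed. The repression fraction
of a gene hit by ``c`` distinct cocktail miRNAs is

    A(c) = 0            for c <= min_multiplicity - 1   (default: c <= 1)
    A(c) = min(1, r*c)  otherwise                       (default r = 0.2)

so, at the defaults, two hits repress 40% of expression, three hits 60%, and
six or more saturate at 100%. A cocktail μ is scored by the loss

    L(μ) = Σ_{i ∈ I} A(c_i)·ΔG_i  −  Σ_{j ∈ J} A(c_j)·ΔG_j

over the housekeeping set I (whose repression is the toxicity proxy, pushing
the loss up) and the target set J (the top-k genes by mean ΔG, pushing it
down). More negative losses are better. A(c)·ΔG scales the full-repression
disruption linearly; an exact mode re-evaluating the potential at fractionally
reduced concentration is available for comparison but is not the default
(see ``exact_gene_effect``).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .mirna import TargetMap
from .potential import AnnotatedNetwork, repress_delta_g, total_potential
from .ranking import DeltaGTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepressionModel:
    """Multiplicity → repression-fraction model A(c).

    ``r``: per-miRNA repression fraction added per hit (default 0.2);
    ``min_multiplicity``: smallest number of cocktail miRNAs that represses at
    all (default 2: a gene hit once counts as unrepressed);
    ``saturation``: cap on the repressed fraction (1 = complete repression).
    """

    r: float = 0.2
    min_multiplicity: int = 2
    saturation: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.r <= 1.0:
            raise ValueError(f"r must be in (0, 1], got {self.r}")
        if self.min_multiplicity < 1:
            raise ValueError("min_multiplicity must be >= 1")


@dataclass
class GeneSets:
    """Target set J, housekeeping set I, and the signed disruption per gene.

    Targets carry −ΔG (repressing them improves the loss) and housekeeping
    genes +ΔG (repressing them worsens it). A gene in both sets counts as a
    target only.
    """

    targets: list[str]
    housekeeping: set[str]
    signed_delta_g: dict[str, float]


@dataclass
class CocktailScore:
    mirnas: frozenset[str]
    loss: float
    multiplicity: dict[str, int] = field(repr=False)
    n_targets_hit: int = 0
    n_housekeeping_hit: int = 0
    rank: int = 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.mirnas))


def repression_fraction(c: int, model: RepressionModel = RepressionModel()) -> float:
    """Fraction of a gene's expression repressed when hit by c cocktail miRNAs."""
    if c < 0:
        raise ValueError(f"multiplicity must be >= 0, got {c}")
    if c <= model.min_multiplicity - 1:
        return 0.0
    return min(model.saturation, model.r * c)


def build_gene_sets(
    ranked: DeltaGTable, housekeeping: list[str] | set[str], top_k: int = 10
) -> GeneSets:
    """Pick the top-k targets and resolve them against the housekeeping list.

    Housekeeping genes that rank inside the top-k are treated as targets
    (precedence to efficacy); housekeeping genes without a ΔG value are
    dropped with a logged tally.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not housekeeping:
        raise ValueError("housekeeping list is empty")
    if top_k > len(ranked.genes):
        raise ValueError(f"top_k={top_k} exceeds the {len(ranked.genes)}-gene universe")
    targets = ranked.top(top_k)
    hk_all = {g.upper() for g in housekeeping}
    unmeasured = {g for g in hk_all if g not in ranked.mean_delta_g.index}
    if unmeasured:
        logger.info("build_gene_sets: %d housekeeping genes lack ΔG values, dropped", len(unmeasured))
    hk = (hk_all - set(targets)) - unmeasured
    signed = {g: -float(ranked.mean_delta_g[g]) for g in targets}
    signed.update({g: float(ranked.mean_delta_g[g]) for g in hk})
    return GeneSets(targets=targets, housekeeping=hk, signed_delta_g=signed)


def candidate_mirnas(tmap: TargetMap, targets: list[str], min_hits: int = 2) -> list[str]:
    """miRNAs predicted to hit at least ``min_hits`` of the target genes."""
    target_set = set(targets)
    out = sorted(m for m, genes in tmap.pairs.items() if len(genes & target_set) >= min_hits)
    if not out:
        logger.warning("candidate_mirnas: no miRNA hits >= %d of %d targets", min_hits, len(targets))
    return out


def cocktail_loss(
    mirnas: frozenset[str] | set[str],
    tmap: TargetMap,
    sets: GeneSets,
    model: RepressionModel = RepressionModel(),
    k: int | None = None,
) -> CocktailScore:
    """Score one cocktail: multiplicity per gene, then L(μ).

    ``c(g)`` counts distinct cocktail miRNAs predicted to target g; genes
    outside I ∪ J contribute nothing. Hits are counted per gene with
    A(c) > 0.
    """
    mirnas = frozenset(mirnas)
    if k is not None and len(mirnas) != k:
        raise ValueError(f"expected a cocktail of {k} miRNAs, got {len(mirnas)}")
    scored_genes = sets.signed_delta_g
    multiplicity = {g: 0 for g in scored_genes}
    for m in mirnas:
        for g in tmap.targets(m):
            if g in multiplicity:
                multiplicity[g] += 1
    loss = 0.0
    n_t = n_h = 0
    target_set = set(sets.targets)
    for g, c in multiplicity.items():
        a = repression_fraction(c, model)
        if a == 0.0:
            continue
        loss += a * scored_genes[g]
        if g in target_set:
            n_t += 1
        else:
            n_h += 1
    return CocktailScore(
        mirnas=mirnas, loss=loss, multiplicity=multiplicity,
        n_targets_hit=n_t, n_housekeeping_hit=n_h,
    )


def rank_cocktails(
    candidates: list[str],
    k: int,
    tmap: TargetMap,
    sets: GeneSets,
    model: RepressionModel = RepressionModel(),
) -> list[CocktailScore]:
    """Exhaustively score all C(|candidates|, k) cocktails, best (most
    negative loss) first; ties break on the sorted miRNA id tuple."""
    if len(candidates) < k:
        raise ValueError(f"need at least k={k} candidates, have {len(candidates)}")
    scores = [
        cocktail_loss(frozenset(combo), tmap, sets, model)
        for combo in itertools.combinations(sorted(candidates), k)
    ]
    scores.sort(key=lambda s: (s.loss, s.ids))
    for i, s in enumerate(scores):
        s.rank = i + 1
    return scores


@dataclass
class SensitivityGrid:
    """Per-(r, top_k) cocktail rankings plus the cross-cell stability report."""

    cells: dict[tuple[float, int], list[CocktailScore]]
    stable_top: list[tuple[str, ...]]  # cocktails in the best n_head of every cell


def sensitivity_grid(
    ranked: DeltaGTable,
    housekeeping: list[str] | set[str],
    tmap: TargetMap,
    r_values: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    top_k_values: tuple[int, ...] = (5, 10, 15),
    k: int = 3,
    min_hits: int = 2,
    n_head: int = 10,
) -> SensitivityGrid:
    """Re-rank cocktails across a grid of repression slopes and target-set
    sizes to check how stable the best cocktails are to those assumptions."""
    cells: dict[tuple[float, int], list[CocktailScore]] = {}
    head_sets: list[set[tuple[str, ...]]] = []
    for top_k in top_k_values:
        sets = build_gene_sets(ranked, housekeeping, top_k=top_k)
        candidates = candidate_mirnas(tmap, sets.targets, min_hits=min_hits)
        for r in r_values:
            model = RepressionModel(r=r)
            if len(candidates) < k:
                cells[(r, top_k)] = []
                head_sets.append(set())
                continue
            ranking = rank_cocktails(candidates, k, tmap, sets, model)
            cells[(r, top_k)] = ranking
            head_sets.append({s.ids for s in ranking[:n_head]})
    stable = sorted(set.intersection(*head_sets)) if head_sets else []
    return SensitivityGrid(cells=cells, stable_top=stable)


def mirna_frequency_summary(
    rankings: list[CocktailScore], n_head: int = 10
) -> pd.DataFrame:
    """Count how often each miRNA appears in the best and worst n_head cocktails.

    miRNAs dominating the worst cocktails are the promiscuous,
    housekeeping-heavy ones; miRNAs dominating the best are the selective ones.
    """
    best = rankings[:n_head]
    worst = rankings[-n_head:] if len(rankings) >= n_head else rankings
    all_mirnas = sorted({m for s in rankings for m in s.mirnas})
    rows = [
        {
            "mirna": m,
            "n_best": sum(m in s.mirnas for s in best),
            "n_worst": sum(m in s.mirnas for s in worst),
        }
        for m in all_mirnas
    ]
    return pd.DataFrame(rows).set_index("mirna")


def exact_gene_effect(
    net: AnnotatedNetwork, gene: str, fraction: float
) -> float:
    """Potential change from reducing one gene's concentration by ``fraction``,
    re-evaluating the potential exactly rather than scaling ΔG linearly.

    Provided for comparison with the default linear A(c)·ΔG scaling; at
    fraction 1 it equals the full-repression ΔG.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 1.0:
        return repress_delta_g(net, gene).delta_g
    before = total_potential(net)
    reduced = dict(net.concentration)
    reduced[gene] = (1.0 - fraction) * reduced[gene]
    after = total_potential(
        AnnotatedNetwork(network=net.network, sample_id=net.sample_id, concentration=reduced)
    )
    return sum(
        after.node_potential[n] - before.node_potential[n] for n in net.network.nodes
    )
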