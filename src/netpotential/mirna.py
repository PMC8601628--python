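"""miRNA → target mappings and single-miRNA disruption scores.

A single miRNA represses every transcript it is predicted to bind, so its
maximum achievable network disruption is the sum of the ΔG values of its
predicted targets. Mappings come from a precomputed table aggregated across
prediction databases; a pair is trusted only when supported by at least
``min_sources`` databases (default 2), and a miRNA's target set is the union
of its retained pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError


@dataclass
class TargetMap:
    """miRNA → predicted target genes, with per-pair source-database counts."""

    pairs: dict[str, set[str]]
    source_count: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.pairs)

    def targets(self, mirna: str) -> set[str]:
        return self.pairs.get(mirna, set())


@dataclass
class MirnaScore:
    mirna: str
    disruption: float
    n_targets_in_universe: int
    rank: int


def read_target_map(path: str | Path, min_sources: int = 2) -> TargetMap:
    """Read a (miRNA, gene, n_sources) TSV, keeping pairs with enough support.

    Rows below ``min_sources`` are dropped; duplicate pairs keep the highest
    source count. Gene symbols are uppercased.
    """
    pairs: dict[str, set[str]] = {}
    counts: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for line_num, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: expected 3 tab-separated fields at line {line_num}")
            mirna, gene, n_sources = parts
            if line_num == 1 and not n_sources.strip().isdigit():
                continue  # header row
            try:
                n = int(n_sources)
            except ValueError:
                raise FormatError(f"{path}: non-integer source count at line {line_num}")
            if n < 1:
                raise FormatError(f"{path}: source count must be >= 1 at line {line_num}")
            if n < min_sources:
                continue
            gene = gene.strip().upper()
            mirna = mirna.strip()
            key = (mirna, gene)
            counts[key] = max(counts.get(key, 0), n)
            pairs.setdefault(mirna, set()).add(gene)
    return TargetMap(pairs=pairs, source_count=counts)


def build_target_map(
    pairs: Iterable[tuple[str, str, int]], min_sources: int = 2
) -> TargetMap:
    """Build a TargetMap from in-memory (mirna, gene, n_sources) triples."""
    out_pairs: dict[str, set[str]] = {}
    counts: dict[tuple[str, str], int] = {}
    for mirna, gene, n in pairs:
        if n < min_sources:
            continue
        gene = gene.upper()
        counts[(mirna, gene)] = max(counts.get((mirna, gene), 0), n)
        out_pairs.setdefault(mirna, set()).add(gene)
    return TargetMap(pairs=out_pairs, source_count=counts)


def write_target_map(tmap: TargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tgene\tn_sources\n")
        for mirna in tmap.mirnas:
            for gene in sorted(tmap.pairs[mirna]):
                fh.write(f"{mirna}\t{gene}\t{tmap.source_count.get((mirna, gene), 1)}\n")


def score_mirnas(tmap: TargetMap, delta_g: Mapping[str, float]) -> list[MirnaScore]:
    """Rank miRNAs by summed ΔG over their targets inside the scored universe.

    A miRNA's disruption is the network change it could achieve if introduced
    synthetically and every predicted target were fully repressed. Targets
    outside ``delta_g`` contribute 0. Ties break lexicographically by id.
    """
    if not tmap.pairs:
        raise ValueError("target map is empty")
    scored = []
    for mirna in tmap.mirnas:
        in_universe = tmap.pairs[mirna] & set(delta_g.keys())
        disruption = float(sum(delta_g[g] for g in in_universe))
        scored.append((mirna, disruption, len(in_universe)))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [
        MirnaScore(mirna=m, disruption=d, n_targets_in_universe=k, rank=i + 1)
        for i, (m, d, k) in enumerate(scored)
    ]


def scores_frame(scores: list[MirnaScore]) -> pd.DataFrame:
    """Flat (rank, mirna, disruption, n_targets_in_universe) table."""
    return pd.DataFrame(
        [
            {
                "rank": s.rank,
                "mirna": s.mirna,
                "disruption": s.disruption,
                "n_targets_in_universe": s.n_targets_in_universe,
            }
            for s in scores
        ]
    ).set_index("rank")
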