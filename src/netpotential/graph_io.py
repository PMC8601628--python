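"""Readers for interaction networks and expression matrices.

The pipeline keys everything on uppercase gene symbols: BioGRID exports,
expression tables and housekeeping lists all carry official symbols, so joins
happen on symbol strings throughout. Interaction networks are plain
:class:`networkx.Graph` objects (simple, undirected, no self-loops); per-sample
transcript concentrations live in an :class:`AnnotatedNetwork` alongside the
topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .errors import EmptyNetworkError, FormatError, UnknownSampleError

logger = logging.getLogger(__name__)

HUMAN_TAXON = 9606


@dataclass
class AnnotatedNetwork:
    """An interaction network with one sample's transcript concentrations.

    ``concentration`` maps every node to a finite value >= 0 (normalized
    expression units); nodes the expression matrix did not cover carry 0, which
    leaves every neighbour-sum term of the potential unchanged relative to
    deleting the node.
    """

    network: nx.Graph
    sample_id: str
    concentration: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        missing = [n for n in self.network.nodes if n not in self.concentration]
        if missing:
            raise ValueError(f"concentration missing for {len(missing)} nodes, e.g. {missing[:3]}")
        for gene, value in self.concentration.items():
            if not (value >= 0.0) or value != value or value == float("inf"):
                raise ValueError(f"concentration for {gene} must be finite and >= 0, got {value}")


def _empty_graph_check(graph: nx.Graph, source: str) -> nx.Graph:
    if graph.number_of_nodes() == 0:
        raise EmptyNetworkError(f"no interactions left after parsing/filtering {source}")
    return graph


def _add_pair(graph: nx.Graph, a: str, b: str) -> bool:
    """Add an undirected edge, dropping self-loops. Returns True if kept."""
    a, b = a.strip().upper(), b.strip().upper()
    if not a or not b or a == b:
        return False
    graph.add_edge(a, b)
    return True


def read_biogrid(
    path: str | Path,
    organism_filter: int | None = HUMAN_TAXON,
    physical_only: bool = False,
) -> nx.Graph:
    """Parse a BioGRID tab-delimited export into a simple undirected graph.

    Column names are matched case-insensitively: the two official-symbol
    columns are required; organism columns are used only when
    ``organism_filter`` is given (default human, taxon 9606). Self-interactions
    and duplicate pairs are collapsed; dropped-row counts are logged.

    Set ``physical_only`` to keep only rows whose experimental-system type is
    ``physical`` (BioGRID also curates genetic interactions; whether to include
    them is left to the caller).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    cols = {c.lower().replace("_", " "): c for c in df.columns}

    def find(fragment: str, which: str) -> str | None:
        for lowered, original in cols.items():
            if fragment in lowered and lowered.endswith(which):
                return original
        return None

    col_a = find("official symbol", "a")
    col_b = find("official symbol", "b")
    if col_a is None or col_b is None:
        missing = "Official Symbol Interactor A" if col_a is None else "Official Symbol Interactor B"
        raise FormatError(f"{path}: required column '{missing}' not found (have {list(df.columns)})")

    n_total = len(df)
    if organism_filter is not None:
        org_a = find("organism", "a")
        org_b = find("organism", "b")
        if org_a is not None and org_b is not None:
            keep = (df[org_a].astype(str) == str(organism_filter)) & (
                df[org_b].astype(str) == str(organism_filter)
            )
            df = df[keep]
            logger.info("read_biogrid: dropped %d/%d rows by organism filter %s",
                        n_total - len(df), n_total, organism_filter)
    if physical_only:
        type_col = find("experimental system type")
        if type_col is not None:
            before = len(df)
            df = df[df[type_col].str.lower() == "physical"]
            logger.info("read_biogrid: dropped %d genetic-interaction rows", before - len(df))

    graph = nx.Graph()
    dropped = 0
    for a, b in zip(df[col_a], df[col_b]):
        if not _add_pair(graph, str(a), str(b)):
            dropped += 1
    if dropped:
        logger.info("read_biogrid: dropped %d self-interaction/blank rows", dropped)
    return _empty_graph_check(graph, str(path))


def read_string(
    path: str | Path,
    min_score: int = 700,
    aliases: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Parse STRING protein links (``protein1 protein2 combined_score``).

    Rows with combined score >= ``min_score`` (0-1000 scale, inclusive
    threshold) are kept. ``aliases`` optionally maps raw STRING identifiers to
    gene symbols; unmapped identifiers are kept as-is, uppercased.
    """
    if not 0 <= min_score <= 1000:
        raise ValueError(f"min_score must be in [0, 1000], got {min_score}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    score_col = next((c for c in df.columns if "score" in c.lower()), None)
    id_cols = [c for c in df.columns if c != score_col]
    if score_col is None or len(id_cols) < 2:
        raise FormatError(f"{path}: need two identifier columns and a combined_score column")

    graph = nx.Graph()
    kept = 0
    for row_num, (a, b, s) in enumerate(
        zip(df[id_cols[0]], df[id_cols[1]], df[score_col]), start=2
    ):
        try:
            score = float(s)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-numeric combined score {s!r} at row {row_num}")
        if score < min_score:
            continue
        if aliases is not None:
            a = aliases.get(a, a)
            b = aliases.get(b, b)
        kept += _add_pair(graph, str(a), str(b))
    logger.info("read_string: kept %d rows with score >= %d", kept, min_score)
    return _empty_graph_check(graph, str(path))


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column tab-separated edge list (the package's own format)."""
    graph = nx.Graph()
    with open(path) as fh:
        for line_num, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: expected two tab-separated symbols at line {line_num}")
            _add_pair(graph, *parts)
    return _empty_graph_check(graph, str(path))


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write edges as sorted tab-separated symbol pairs (deterministic)."""
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV of normalized, non-negative expression.

    First column is the gene symbol (uppercased); duplicated symbols are
    resolved by keeping the row with the highest mean (logged). Negative or
    non-numeric values are format errors naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any():
        row, col = next(zip(*numeric.isna().values.nonzero()))
        raise FormatError(
            f"{path}: non-numeric value for gene {df.index[row]}, sample {df.columns[col]}"
        )
    df = numeric
    if (df.values < 0).any():
        row, col = next(zip(*(df.values < 0).nonzero()))
        raise FormatError(
            f"{path}: negative value for gene {df.index[row]}, sample {df.columns[col]}"
        )
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning("read_expression: %d duplicated gene symbols; keeping highest-mean rows", n_dup)
        df = (
            df.assign(_mean=df.mean(axis=1))
            .sort_values("_mean", ascending=False)
            .groupby(level=0, sort=True)
            .head(1)
            .drop(columns="_mean")
            .sort_index()
        )
    return df.astype(float)


def attach_expression(
    network: nx.Graph, expression: pd.DataFrame, sample_id: str
) -> AnnotatedNetwork:
    """Attach one sample's concentrations to every node of the network.

    Nodes absent from the matrix get concentration 0 (counted and logged as
    unmeasured); expression rows absent from the network are ignored (logged).
    Topology is never modified.
    """
    if sample_id not in expression.columns:
        raise UnknownSampleError(
            f"sample {sample_id!r} not in expression matrix (have {list(expression.columns)[:5]}...)"
        )
    column = expression[sample_id]
    concentration: dict[str, float] = {}
    unmeasured = 0
    for node in network.nodes:
        if node in column.index:
            concentration[node] = float(column[node])
        else:
            concentration[node] = 0.0
            unmeasured += 1
    extra = len(column.index.difference(pd.Index(network.nodes)))
    logger.info(
        "attach_expression[%s]: %d unmeasured network nodes set to 0; %d expression genes not in network",
        sample_id, unmeasured, extra,
    )
    return AnnotatedNetwork(network=network, sample_id=sample_id, concentration=concentration)
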