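"""End-to-end orchestration: config validation, staged execution, manifest.

The pipeline chains: load network → attach expression per sample → potentials
→ per-gene ΔG → target ranking → rewiring null for the top genes → single
miRNA scores → cocktail enumeration → optional sensitivity grid. All outputs
are TSVs plus a YAML manifest. Outputs are byte-identical for identical
(inputs, config, seed); for that reason wall-clock timings are logged rather
than written into the manifest.
"""

from __future__ import annotations

import difflib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, StageError
from .graph_io import attach_expression, read_biogrid, read_edge_list, read_expression, read_string
from .mirna import read_target_map, score_mirnas, scores_frame
from .potential import batch_delta_g, total_potential
from .ranking import flag_within_null, null_distribution, rank_targets, subset_ranking
from .cocktails import (
    RepressionModel,
    build_gene_sets,
    candidate_mirnas,
    mirna_frequency_summary,
    rank_cocktails,
    sensitivity_grid,
)

logger = logging.getLogger(__name__)

# Defaults mirror the published analysis conditions: 1000 null iterations of
# n*100 swaps each, 99.99% Bonferroni-corrected CIs over the top 50 genes,
# 3-miRNA cocktails against the top 10 targets with 20% per-miRNA repression,
# candidate miRNAs hitting >= 2 targets with >= 2 supporting databases, and a
# STRING combined-score cutoff of 700.
DEFAULTS: dict[str, Any] = {
    "network_format": "edge-list",  # edge-list | biogrid | string
    "min_score": 700,
    "organism": 9606,
    "samples": None,  # optional subset of expression columns
    "cancer_genes": None,  # optional allow-list for a subset ranking
    "iterations": 1000,
    "swap_multiplier": 100,
    "alpha": 1e-4,
    "n_tests": None,  # default: number of genes scored in the null
    "null_top": 50,
    "ci_method": "normal",
    "k": 3,
    "top_k": 10,
    "r": 0.2,
    "min_hits": 2,
    "min_sources": 2,
    "mirna_universe": "all",  # all | top (restrict ΔG universe to top_k)
    "cocktails": True,
    "grid": False,
    "r_values": [0.1, 0.2, 0.3, 0.4, 0.5],
    "top_k_values": [5, 10, 15],
    "seed": 0,
    "outdir": "netpotential_out",
}
REQUIRED_PATHS = ("network", "expression")
COCKTAIL_PATHS = ("target_map", "housekeeping")


@dataclass
class PipelineConfig:
    network: str
    expression: str
    target_map: str | None = None
    housekeeping: str | None = None
    options: dict[str, Any] = field(default_factory=dict)

    def __getattr__(self, key: str) -> Any:
        try:
            return self.__dict__["options"][key]
        except KeyError:
            raise AttributeError(key)


@dataclass
class RunManifest:
    """Reproducibility record: config echo, version, seeds, stage row counts,
    and the interpretation choices that were in effect."""

    config: dict[str, Any]
    version: str
    seed: int
    stage_rows: dict[str, int]
    choices: dict[str, Any]
    outputs: list[str]


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, type-check and default a YAML pipeline config.

    Unknown keys are hard errors (with a closest-match suggestion); required
    input paths must exist; numeric parameters are checked against their
    domains.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = set(DEFAULTS) | set(REQUIRED_PATHS) | set(COCKTAIL_PATHS)
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(f"{path}: unknown key {key!r}{suffix}")

    missing = [k for k in REQUIRED_PATHS if not raw.get(k)]
    if missing:
        raise ConfigError(f"{path}: missing required input path(s): {', '.join(missing)}")
    options = {**DEFAULTS, **{k: v for k, v in raw.items() if k in DEFAULTS}}

    if options["cocktails"]:
        missing = [k for k in COCKTAIL_PATHS if not raw.get(k)]
        if missing:
            raise ConfigError(
                f"{path}: cocktails enabled but missing: {', '.join(missing)}"
            )
    for key in ("network", "expression", *COCKTAIL_PATHS):
        value = raw.get(key)
        if value is not None and not Path(value).exists():
            raise ConfigError(f"{path}: {key} file not found: {value}")
    if not 0.0 < float(options["r"]) <= 1.0:
        raise ConfigError(f"{path}: r must be in (0, 1], got {options['r']}")
    if not 0.0 < float(options["alpha"]) < 1.0:
        raise ConfigError(f"{path}: alpha must be in (0, 1)")
    for key in ("iterations", "swap_multiplier", "k", "top_k", "min_hits", "min_sources"):
        if int(options[key]) < 0:
            raise ConfigError(f"{path}: {key} must be non-negative")
    if options["network_format"] not in ("edge-list", "biogrid", "string"):
        raise ConfigError(f"{path}: unknown network_format {options['network_format']!r}")
    return PipelineConfig(
        network=raw["network"],
        expression=raw["expression"],
        target_map=raw.get("target_map"),
        housekeeping=raw.get("housekeeping"),
        options=options,
    )


def _load_network(config: PipelineConfig):
    fmt = config.network_format
    if fmt == "biogrid":
        return read_biogrid(config.network, organism_filter=config.organism)
    if fmt == "string":
        return read_string(config.network, min_score=config.min_score)
    return read_edge_list(config.network)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage, writing TSVs and a manifest into ``outdir``.

    Any stage failure raises :class:`StageError` naming the stage, after
    removing the partially written outputs of this run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage_rows: dict[str, int] = {}
    stage = "load"

    def emit(frame: pd.DataFrame, name: str, **kwargs: Any) -> None:
        dest = outdir / name
        frame.to_csv(dest, sep="\t", **kwargs)
        written.append(dest)

    try:
        t0 = time.perf_counter()
        network = _load_network(config)
        expression = read_expression(config.expression)
        samples = config.samples or list(expression.columns)
        stage_rows["load"] = network.number_of_nodes()
        logger.info("load: %d nodes, %d edges, %d samples (%.1fs)",
                    network.number_of_nodes(), network.number_of_edges(),
                    len(samples), time.perf_counter() - t0)

        stage = "potential"
        totals = []
        delta_tables: dict[str, dict[str, float]] = {}
        for sid in samples:
            annotated = attach_expression(network, expression, sid)
            result = total_potential(annotated)
            totals.append({"sample_id": sid, "total_potential": result.total})
            per_node = pd.DataFrame(
                {
                    "concentration": pd.Series(annotated.concentration),
                    "node_potential": pd.Series(result.node_potential),
                }
            ).rename_axis("gene").sort_index()
            emit(per_node, f"potential_{sid}.tsv")
            delta_tables[sid] = batch_delta_g(annotated)
        emit(pd.DataFrame(totals), "total_potential.tsv", index=False)
        stage_rows["potential"] = len(samples)

        stage = "rank-targets"
        ranked = rank_targets(delta_tables)
        emit(ranked.frame().rename_axis("gene"), "ranked_targets.tsv")
        stage_rows["rank-targets"] = len(ranked.genes)
        if config.cancer_genes:
            allow = _read_gene_list(config.cancer_genes)
            restricted = subset_ranking(ranked, allow)
            emit(restricted.frame().rename_axis("gene"), "ranked_targets_cancer.tsv")

        stage = "null"
        if config.iterations >= 2:
            top_genes = ranked.top(min(config.null_top, len(ranked.genes)))
            nulls = null_distribution(
                network, expression, samples[0], top_genes,
                n_iterations=config.iterations, swap_multiplier=config.swap_multiplier,
                alpha=config.alpha, n_tests=config.n_tests, seed=config.seed,
                method=config.ci_method,
            )
            emit(flag_within_null(ranked, nulls), "null_summary.tsv")
            stage_rows["null"] = len(nulls)

        manifest_choices = {
            "mirna_universe": config.mirna_universe,
            "ci_method": config.ci_method,
            "null_sample": samples[0] if config.iterations >= 2 else None,
        }
        if config.cocktails:
            stage = "rank-mirnas"
            tmap = read_target_map(config.target_map, min_sources=config.min_sources)
            if config.mirna_universe == "top":
                universe = {g: float(ranked.mean_delta_g[g]) for g in ranked.top(config.top_k)}
            else:
                universe = {g: float(v) for g, v in ranked.mean_delta_g.items()}
            mirna_scores = score_mirnas(tmap, universe)
            emit(scores_frame(mirna_scores), "ranked_mirnas.tsv")
            stage_rows["rank-mirnas"] = len(mirna_scores)

            stage = "rank-cocktails"
            housekeeping = _read_gene_list(config.housekeeping)
            sets = build_gene_sets(ranked, housekeeping, top_k=config.top_k)
            candidates = candidate_mirnas(tmap, sets.targets, min_hits=config.min_hits)
            model = RepressionModel(r=config.r)
            ranking = rank_cocktails(candidates, config.k, tmap, sets, model)
            emit(_cocktail_frame(ranking), "cocktails.tsv", index=False)
            emit(mirna_frequency_summary(ranking), "mirna_frequency.tsv")
            stage_rows["rank-cocktails"] = len(ranking)

            if config.grid:
                stage = "sensitivity-grid"
                grid = sensitivity_grid(
                    ranked, housekeeping, tmap,
                    r_values=tuple(config.r_values),
                    top_k_values=tuple(config.top_k_values),
                    k=config.k, min_hits=config.min_hits,
                )
                for (r, top_k), cell in grid.cells.items():
                    emit(_cocktail_frame(cell), f"cocktails_r{r:g}_top{top_k}.tsv", index=False)
                stable = pd.DataFrame(
                    [{"cocktail": " + ".join(ids)} for ids in grid.stable_top]
                )
                emit(stable, "cocktail_stability.tsv", index=False)
                stage_rows["sensitivity-grid"] = len(grid.cells)

        stage = "manifest"
        manifest = RunManifest(
            config={"network": config.network, "expression": config.expression,
                    "target_map": config.target_map, "housekeeping": config.housekeeping,
                    **config.options},
            version=__version__,
            seed=config.seed,
            stage_rows=stage_rows,
            choices=manifest_choices,
            outputs=sorted(p.name for p in written),
        )
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(asdict(manifest), fh, sort_keys=True)
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc


def _read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def _cocktail_frame(ranking) -> pd.DataFrame:
    rows = []
    for score in ranking:
        row: dict[str, Any] = {"rank": score.rank}
        for i, mirna in enumerate(score.ids, start=1):
            row[f"mirna_{i}"] = mirna
        row.update(
            loss=score.loss,
            n_targets_hit=score.n_targets_hit,
            n_housekeeping_hit=score.n_housekeeping_hit,
        )
        rows.append(row)
    return pd.DataFrame(rows)
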