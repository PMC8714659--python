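"""End-to-end orchestration: simulate/load -> normalize -> DE -> seed-match
-> intersect -> cross-validate -> correlate -> network -> hubs -> enrichment.

Every stage writes its result as a plain TSV (or FASTA/SIF/GraphML) into the
output directory, so any stage can be re-run and inspected independently.
The run manifest records the effective configuration, per-stage record
counts and a SHA-256 checksum of every artifact; identical configuration
and seed reproduce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .errors import ConfigurationError
from .expression import (
    ExpressionMatrix,
    de_table,
    differential_expression,
    quantile_normalize,
    write_de_table,
    write_volcano_data,
)
from .enrichment import (
    fisher_enrichment,
    read_gmt,
    write_category_counts_tsv,
    write_enrichment_tsv,
)
from .hubs import (
    load_ppi_edges,
    rank_hubs,
    select_validation_candidates,
    write_hub_table,
)
from .network import (
    DEFAULT_CURATED,
    assemble_network,
    cross_validate,
    filter_correlation,
    intersect_pairs,
    read_curated_tsv,
    write_curated_tsv,
    write_edge_attributes,
    write_graphml,
    write_node_attributes,
    write_sif,
    write_triples_tsv,
)
from .synthetic import SimulationConfig, generate_dataset
from .targeting import (
    TranscriptSet,
    predict_targets,
    scan_all_sites,
    write_pairs_tsv,
    write_sites_bed,
)

logger = logging.getLogger(__name__)

CERNA_KINDS = ("lncRNA", "circRNA")


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs (files or a simulation block),
    the stated thresholds, stage flags, and the output directory."""

    # inputs: either file paths or a simulation block
    expression_tsv: str | None = None
    fasta: str | None = None
    curated_tsv: str | None = None
    ppi_tsv: str | None = None
    gmt: str | None = None
    simulation: SimulationConfig | None = None
    # thresholds (the study's stated cutoffs)
    fc_log2_threshold: float = 1.0
    p_threshold: float = 0.05
    r_threshold: float = 0.95
    ppi_min_score: float = 0.4
    hub_k: int = 30
    q_threshold: float = 0.05
    # flags
    direction_consistency: bool = True
    seed_types: tuple[str, ...] | None = None
    correlation_method: str = "pearson"
    # run control
    outdir: str = "cernet_out"
    rng_seed: int = 0

    def validate(self) -> None:
        if self.expression_tsv is None and self.simulation is None:
            raise ConfigurationError(
                "either expression_tsv/fasta inputs or a simulation block is required"
            )
        if self.expression_tsv is not None and self.fasta is None:
            raise ConfigurationError("expression_tsv given without fasta")
        for name, lo, hi in (
            ("p_threshold", 0.0, 1.0),
            ("q_threshold", 0.0, 1.0),
            ("ppi_min_score", 0.0, 1.0),
            ("r_threshold", -1.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigurationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.fc_log2_threshold < 0:
            raise ConfigurationError("fc_log2_threshold must be >= 0")
        if self.hub_k <= 0:
            raise ConfigurationError("hub_k must be positive")
        if self.simulation is not None:
            self.simulation.validate()

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            raw["simulation"] = SimulationConfig(**sim)
        if "seed_types" in raw and raw["seed_types"] is not None:
            raw["seed_types"] = tuple(raw["seed_types"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def echo(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        if d.get("seed_types") is not None:
            d["seed_types"] = list(d["seed_types"])
        return d


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict[str, Any]
    counts: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    triples: list[tuple[str, str, str]] = field(default_factory=list)
    validation_candidates: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = ""
    complete: bool = False

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and persist all artifacts under config.outdir."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.echo())
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    # ---- stage: inputs -------------------------------------------------
    truth = None
    if config.simulation is not None:
        logger.info("[simulate] generating synthetic dataset")
        expr, transcripts, truth = generate_dataset(config.simulation)
        expr.to_tsv(out / "expression_raw.tsv")
        transcripts.to_fasta(out / "transcripts.fasta")
        truth.to_tsv(out)
        emit(out / "expression_raw.tsv")
        emit(out / "transcripts.fasta")
        for name in ("truth_de_features.tsv", "truth_triples.tsv", "truth_sites.tsv"):
            emit(out / name)
        curated = (
            read_curated_tsv(config.curated_tsv)
            if config.curated_tsv
            else truth.curated_mirnas()
        )
    else:
        logger.info("[load] reading %s", config.expression_tsv)
        expr = ExpressionMatrix.from_tsv(config.expression_tsv)
        transcripts = TranscriptSet.from_fasta(config.fasta)
        curated = (
            read_curated_tsv(config.curated_tsv)
            if config.curated_tsv
            else list(DEFAULT_CURATED)
        )
    write_curated_tsv(curated, out / "curated_mirnas.tsv")
    emit(out / "curated_mirnas.tsv")
    manifest.counts["samples"] = len(expr.sample_ids)
    manifest.counts["features"] = len(expr.feature_ids)

    # ---- stage: normalize ----------------------------------------------
    logger.info("[normalize] quantile normalization")
    norm = quantile_normalize(expr)
    norm.to_tsv(out / "expression_normalized.tsv")
    emit(out / "expression_normalized.tsv")

    # ---- stage: differential expression --------------------------------
    logger.info("[de] fold-change + t-test screen")
    de_records = differential_expression(
        norm, config.fc_log2_threshold, config.p_threshold
    )
    write_de_table(de_records, out / "de_table.tsv")
    write_volcano_data(de_records, out / "volcano.tsv")
    emit(out / "de_table.tsv")
    emit(out / "volcano.tsv")
    de_ids = {r.feature_id for r in de_records if r.is_de}
    for kind in ("mRNA", "lncRNA", "circRNA", "miRNA"):
        manifest.counts[f"de_{kind}"] = sum(
            1 for r in de_records if r.is_de and r.kind == kind
        )

    # ---- stage: target prediction --------------------------------------
    logger.info("[targets] seed-site scan of DE transcripts")
    mirnas = transcripts.subset_kinds({"miRNA"})
    de_ce = TranscriptSet(
        t for t in transcripts if t.kind in CERNA_KINDS and t.id in de_ids
    )
    de_mrna = TranscriptSet(
        t for t in transcripts if t.kind == "mRNA" and t.id in de_ids
    )
    ce_pairs = predict_targets(mirnas, de_ce, config.seed_types)
    m_pairs = predict_targets(mirnas, de_mrna, config.seed_types)
    sites = scan_all_sites(mirnas, de_ce, config.seed_types) + scan_all_sites(
        mirnas, de_mrna, config.seed_types
    )
    write_pairs_tsv(ce_pairs, out / "pairs_cerna.tsv")
    write_pairs_tsv(m_pairs, out / "pairs_mrna.tsv")
    write_sites_bed(sites, out / "seed_sites.tsv")
    emit(out / "pairs_cerna.tsv")
    emit(out / "pairs_mrna.tsv")
    emit(out / "seed_sites.tsv")
    manifest.counts["pairs_cerna"] = len(ce_pairs)
    manifest.counts["pairs_mrna"] = len(m_pairs)

    # ---- stage: intersect / cross-validate / correlate ------------------
    candidates = intersect_pairs(ce_pairs, m_pairs)
    manifest.counts["candidates"] = len(candidates)
    validated = cross_validate(candidates, curated) if candidates else []
    manifest.counts["cross_validated"] = len(validated)
    triples = filter_correlation(
        validated,
        norm,
        de_records,
        curated,
        r_threshold=config.r_threshold,
        require_direction_consistency=config.direction_consistency,
        method=config.correlation_method,
    )
    write_triples_tsv(triples, out / "triples.tsv")
    emit(out / "triples.tsv")
    manifest.counts["triples"] = len(triples)
    manifest.triples = [t.key() for t in triples]
    # the pair/edge views of the same result, all three counts reported
    manifest.counts["cerna_mrna_pairs"] = len(
        {(t.cerna_id, t.mrna_id) for t in triples}
    )

    # ---- stage: network assembly ----------------------------------------
    logger.info("[network] assembling ceRNA network from %d triples", len(triples))
    kinds = {t.id: t.kind for t in transcripts}
    graph = assemble_network(triples, kinds, curated)
    write_sif(graph, out / "network.sif")
    write_graphml(graph, out / "network.graphml")
    write_node_attributes(graph, out / "network_nodes.tsv")
    write_edge_attributes(graph, out / "network_edges.tsv")
    for name in ("network.sif", "network.graphml", "network_nodes.tsv",
                 "network_edges.tsv"):
        emit(out / name)
    manifest.counts["network_nodes"] = graph.number_of_nodes()
    manifest.counts["network_edges"] = graph.number_of_edges()

    # ---- stage: hubs (optional) -----------------------------------------
    if config.ppi_tsv:
        logger.info("[hubs] degree ranking on %s", config.ppi_tsv)
        ppi = load_ppi_edges(config.ppi_tsv, config.ppi_min_score)
        hubs = rank_hubs(ppi, config.hub_k)
        write_hub_table(hubs, out / "hub_genes.tsv")
        emit(out / "hub_genes.tsv")
        manifest.counts["ppi_nodes"] = ppi.number_of_nodes()
        manifest.counts["ppi_edges"] = ppi.number_of_edges()
        manifest.counts["hubs"] = len(hubs.ranked)
        cands = select_validation_candidates(hubs, graph)
        (out / "validation_candidates.tsv").write_text(
            "gene\n" + "".join(f"{g}\n" for g in cands)
        )
        emit(out / "validation_candidates.tsv")
        manifest.validation_candidates = cands
        manifest.counts["validation_candidates"] = len(cands)

    # ---- stage: enrichment (optional) ------------------------------------
    if config.gmt:
        network_mrnas = {
            n for n, d in graph.nodes(data=True) if d.get("kind") == "mRNA"
        }
        if network_mrnas:
            logger.info("[enrich] %d network mRNAs vs %s", len(network_mrnas),
                        config.gmt)
            collection = read_gmt(config.gmt)
            records = fisher_enrichment(
                network_mrnas, collection, config.q_threshold
            )
            write_enrichment_tsv(records, out / "enrichment.tsv")
            write_category_counts_tsv(records, collection,
                                      out / "category_counts.tsv")
            emit(out / "enrichment.tsv")
            emit(out / "category_counts.tsv")
            manifest.counts["enriched_terms"] = sum(
                1 for r in records if r.significant
            )
        else:
            logger.info("[enrich] network has no mRNAs; skipped")

    # ---- manifest --------------------------------------------------------
    for path in written:
        manifest.checksums[path.name] = _sha256(path)
    manifest.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.complete = True
    manifest.write(out / "manifest.json")
    return manifest
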