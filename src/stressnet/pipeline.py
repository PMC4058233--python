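"""End-to-end orchestration: simulate -> homology -> transfer -> topology
-> predict -> report.

Stage boundaries are file-based (FASTA/TSV/GraphML/JSON), so any stage's
synthetic input can be replaced with real data: a reference edge list and
proteome from a PPI database, a unigene FASTA from an assembler, known
stress-gene lists from a curated database, or precomputed TBLASTN hits in
BLAST outfmt 6. All randomness flows from a single config seed through
named substreams, and identical config + seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .homology import (
    AlignerConfig,
    HomologyThresholds,
    HIT_COLUMNS,
    filter_hits,
    read_blast6,
    search_homologs,
    write_blast6,
)
from .io import read_fasta, sequence_lengths, write_fasta
from .network import (
    best_hits_per_species,
    connected_components,
    degree_distribution,
    fit_power_law,
    read_edge_list,
    read_reference_networks,
    transfer_interactions,
    write_degree_distribution,
    write_edge_list,
    write_fit,
    write_graphml,
    write_reference_networks,
    plot_degree_distribution,
)
from .predict import (
    KnownGeneMap,
    PredictionRule,
    PredictionTable,
    count_predictions,
    map_known_genes,
    predict_novel_genes,
    read_prediction_table,
    write_prediction_table,
    write_summary,
)
from .simulate import (
    SyntheticTruth,
    clone_ortholog_network,
    generate_proteome,
    generate_reference_network,
    generate_stress_gene_sets,
    generate_unigenes,
    read_category_table,
    write_category_table,
)

logger = logging.getLogger(__name__)

_STAGE_STREAMS = {
    "network": 1, "proteome": 2, "unigenes": 3, "stress_genes": 4,
    "orthologs": 5,
}


def substream_seed(seed: int, stream: str) -> int:
    """Derive an independent, reproducible child seed per named stage."""
    ss = np.random.SeedSequence([seed, _STAGE_STREAMS[stream]])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs; YAML-serialisable."""

    outdir: str = "stressnet_out"
    seed: int = 0
    # synthetic inputs
    n_nodes: int = 50
    edges_per_new_node: int = 3
    species_id: str = "spA"
    n_ortholog_species: int = 1
    ortholog_identity: float = 0.9
    min_protein_len: int = 120
    max_protein_len: int = 240
    target_identity: float = 1.0
    source_fraction: float = 1.0
    n_decoys: int = 10
    categories: tuple[str, ...] = ("cold", "drought", "salinity")
    n_known_per_category: int = 12
    n_implanted_candidates: int = 2
    support_size: int = 5
    n_negative_controls: int = 1
    n_redundant_controls: int = 1
    # homology stage
    thresholds: HomologyThresholds = field(default_factory=HomologyThresholds)
    aligner: AlignerConfig = field(default_factory=AlignerConfig)
    hits_file: str | None = None
    known_hits_file: str | None = None
    best_hit_per_species: bool = False
    # prediction / topology
    rule: PredictionRule = field(default_factory=PredictionRule)
    fit_method: str = "ols"
    make_plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (
            ("thresholds", HomologyThresholds),
            ("aligner", AlignerConfig),
            ("rule", PredictionRule),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "categories" in raw:
            raw["categories"] = tuple(raw["categories"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["categories"] = list(self.categories)
        return d


def _paths(cfg: PipelineConfig) -> dict[str, Path]:
    out = Path(cfg.outdir)
    return {
        "reference_edges": out / "reference_edges.tsv",
        "proteins": out / "reference_proteins.faa",
        "unigenes": out / "unigenes.fna",
        "known_genes": out / "known_genes.faa",
        "known_categories": out / "known_categories.tsv",
        "truth": out / "truth.json",
        "hits": out / "hits.tsv",
        "hits_blast6": out / "hits.blast6.tsv",
        "network_edges": out / "network_edges.tsv",
        "network_graphml": out / "network.graphml",
        "components": out / "components.tsv",
        "degree_distribution": out / "degree_distribution.tsv",
        "powerlaw_fit": out / "powerlaw_fit.json",
        "degree_plot": out / "degree_distribution.png",
        "predictions": out / "predictions.tsv",
        "summary": out / "summary.json",
        "provenance": out / "provenance.json",
    }


def simulate_stage(cfg: PipelineConfig) -> dict:
    """Generate all synthetic inputs and write them to the output dir."""
    p = _paths(cfg)
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    net = generate_reference_network(
        cfg.n_nodes, cfg.edges_per_new_node, cfg.species_id,
        seed=substream_seed(cfg.seed, "network"),
    )
    proteome = generate_proteome(
        net, cfg.min_protein_len, cfg.max_protein_len,
        seed=substream_seed(cfg.seed, "proteome"),
    )
    networks = [net]
    all_proteins = dict(proteome)
    ortho_seed = substream_seed(cfg.seed, "orthologs")
    for i in range(cfg.n_ortholog_species):
        sp = f"sp{chr(ord('B') + i)}"
        onet, oprot = clone_ortholog_network(
            net, proteome, sp, cfg.ortholog_identity, seed=ortho_seed + i
        )
        networks.append(onet)
        all_proteins.update(oprot)
    unis, truth = generate_unigenes(
        proteome, cfg.target_identity, cfg.source_fraction, cfg.n_decoys,
        seed=substream_seed(cfg.seed, "unigenes"),
    )
    known_seqs, cat_table, truth = generate_stress_gene_sets(
        net, proteome, cfg.categories, cfg.n_known_per_category,
        cfg.n_implanted_candidates, cfg.support_size,
        seed=substream_seed(cfg.seed, "stress_genes"),
        n_negative_controls=cfg.n_negative_controls,
        n_redundant_controls=cfg.n_redundant_controls,
        min_support=cfg.rule.min_support,
        truth=truth,
    )
    write_reference_networks(networks, p["reference_edges"])
    write_fasta(all_proteins, p["proteins"])
    write_fasta(unis, p["unigenes"])
    write_fasta(known_seqs, p["known_genes"])
    write_category_table(cat_table, p["known_categories"])
    truth.to_json(p["truth"])
    logger.info(
        "simulate: %d species, %d proteins, %d unigenes, %d known genes",
        len(networks), len(all_proteins), len(unis), len(known_seqs),
    )
    return {
        "networks": networks, "proteome": all_proteins, "unigenes": unis,
        "known_seqs": known_seqs, "category_table": cat_table,
        "truth": truth,
    }


def homology_stage(cfg: PipelineConfig) -> pd.DataFrame:
    """Compute (or ingest) and filter protein-vs-unigene hits."""
    p = _paths(cfg)
    unigenes = read_fasta(p["unigenes"])
    if cfg.hits_file:
        qlens = sequence_lengths(p["proteins"])
        slens = {k: len(v) for k, v in unigenes.items()}
        hits = read_blast6(cfg.hits_file, qlens, slens)
        hits = filter_hits(hits, cfg.thresholds)
    else:
        proteins = read_fasta(p["proteins"])
        hits = search_homologs(
            proteins, unigenes, cfg.thresholds, cfg.aligner
        )
    hits.to_csv(p["hits"], sep="\t", index=False)
    write_blast6(hits, p["hits_blast6"])
    logger.info("homology: %d qualifying hits", len(hits))
    return hits


def transfer_stage(cfg: PipelineConfig):
    """Interolog transfer from the reference networks onto unigenes."""
    p = _paths(cfg)
    networks = read_reference_networks(p["reference_edges"])
    hits = pd.read_csv(p["hits"], sep="\t")
    if cfg.best_hit_per_species:
        hits = best_hits_per_species(hits, networks)
    net = transfer_interactions(networks, hits)
    write_edge_list(net, p["network_edges"])
    write_graphml(net, p["network_graphml"])
    return net


def topology_stage(cfg: PipelineConfig) -> dict:
    """Components, giant-component degree distribution, power-law fit."""
    p = _paths(cfg)
    net = read_edge_list(p["network_edges"])
    comps = connected_components(net)
    rows = [
        (i, len(c), ";".join(sorted(c))) for i, c in enumerate(comps)
    ]
    pd.DataFrame(rows, columns=["component", "size", "members"]).to_csv(
        p["components"], sep="\t", index=False
    )
    result = {"n_components": len(comps)}
    if comps:
        giant = comps[0]
        dist = degree_distribution(net, giant)
        write_degree_distribution(dist, p["degree_distribution"])
        result["giant_size"] = len(giant)
        result["giant_edges"] = int(
            net.graph.subgraph(giant).number_of_edges()
        )
        usable = dist.entries[
            (dist.entries["k"] >= 1) & (dist.entries["p_k"] > 0)
        ]
        if len(usable) >= 2:
            fit = fit_power_law(dist, method=cfg.fit_method)
            write_fit(fit, p["powerlaw_fit"])
            result["fit"] = fit
            if cfg.make_plot:
                plot_degree_distribution(dist, fit, p["degree_plot"])
    return result


def predict_stage(cfg: PipelineConfig) -> PredictionTable:
    """Map known genes onto unigenes and apply the association rule."""
    p = _paths(cfg)
    unigenes = read_fasta(p["unigenes"])
    known_seqs = read_fasta(p["known_genes"])
    cat_table = read_category_table(p["known_categories"])
    net = read_edge_list(p["network_edges"])
    known_hits = None
    if cfg.known_hits_file:
        qlens = {k: len(v) for k, v in known_seqs.items()}
        slens = {k: len(v) for k, v in unigenes.items()}
        known_hits = filter_hits(
            read_blast6(cfg.known_hits_file, qlens, slens), cfg.thresholds
        )
    known_map = map_known_genes(
        known_seqs, cat_table, unigenes, cfg.thresholds, cfg.aligner,
        hits=known_hits,
    )
    table = predict_novel_genes(net, known_map, cfg.rule)
    write_prediction_table(table, p["predictions"])
    write_summary(table, p["summary"])
    return table


def evaluate_against_truth(
    table: PredictionTable, truth: SyntheticTruth
) -> dict:
    """Micro-averaged precision/recall of flagged unigenes vs the truth."""
    frame = table.frame
    tp = fp = fn = 0
    per_category = {}
    for cat, expected in sorted(truth.implanted_candidates.items()):
        if cat in frame.columns and len(frame):
            predicted = set(
                frame.loc[frame[cat] == "Yes", "unigene_id"]
            )
        else:
            predicted = set()
        tp_c = len(predicted & expected)
        per_category[cat] = {
            "predicted": len(predicted),
            "expected": len(expected),
            "true_positives": tp_c,
        }
        tp += tp_c
        fp += len(predicted - expected)
        fn += len(expected - predicted)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return {
        "precision": precision, "recall": recall,
        "per_category": per_category,
    }


def report_stage(cfg: PipelineConfig) -> dict:
    """Write provenance (versions, parameters, seed, input checksums)."""
    p = _paths(cfg)
    checksums = {}
    for name in (
        "reference_edges", "proteins", "unigenes", "known_genes",
        "known_categories",
    ):
        path = p[name]
        if path.exists():
            checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    provenance = {
        "stressnet_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "input_sha256": checksums,
    }
    p["provenance"].write_text(
        json.dumps(provenance, indent=2, sort_keys=True)
    )
    return provenance


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns the key in-memory results.

    When the run is synthetic (a truth file exists), the result includes
    precision/recall of the predictions against the implanted truth.
    """
    p = _paths(cfg)
    sim = simulate_stage(cfg)
    homology_stage(cfg)
    transfer_stage(cfg)
    topology = topology_stage(cfg)
    table = predict_stage(cfg)
    report_stage(cfg)
    result = {
        "paths": {k: str(v) for k, v in p.items()},
        "topology": topology,
        "predictions": table,
        "counts": count_predictions(table),
    }
    if p["truth"].exists():
        truth = SyntheticTruth.from_json(p["truth"])
        result["truth"] = truth
        result["evaluation"] = evaluate_against_truth(table, truth)
    return result
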