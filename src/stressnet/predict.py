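"""Guilt-by-association nomination of novel stress-tolerance genes.

Known resistance genes (per category: cold/freezing, drought, salinity)
are mapped onto unigenes with the same translated homology search and
thresholds used to build the network. A unigene is nominated as a novel
candidate for a category when it connects directly to homologs of more
than ``min_support`` known genes of that category that are mutually
non-homologous — operationalised by collapsing the supporting genes into
single-linkage homology clusters and counting clusters (default), or by
disqualifying any candidate whose supports contain a homologous pair
(strict mode). A unigene that is itself a homolog of one of the
category's known genes is never called novel for that category.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .homology import (
    AlignerConfig,
    HomologyThresholds,
    estimate_evalue,
    local_align,
    make_aligner,
    search_homologs,
)
from .network import TransferredNetwork

logger = logging.getLogger(__name__)

REDUNDANCY_MODES = ("cluster-count", "strict-disqualify")


@dataclass(frozen=True)
class PredictionRule:
    """Association-rule parameters.

    ``min_support`` is compared strictly: a candidate needs *more than*
    ``min_support`` supporting clusters (the default 4 encodes "over four
    known genes").
    """

    min_support: int = 4
    redundancy_mode: str = "cluster-count"

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.redundancy_mode not in REDUNDANCY_MODES:
            raise ValueError(
                f"redundancy_mode must be one of {REDUNDANCY_MODES}"
            )


@dataclass
class KnownGeneMap:
    """Per-category known-gene -> homologous-unigene sets, with the
    single-linkage homology clustering of each category's genes."""

    categories: tuple[str, ...]
    gene_to_unigenes: dict[str, dict[str, set[str]]]
    clusters: dict[str, list[set[str]]]

    def cluster_index(self, category: str) -> dict[str, int]:
        return {
            gene: i
            for i, cluster in enumerate(self.clusters[category])
            for gene in cluster
        }


@dataclass
class PredictionTable:
    """Per-unigene category flags with supporting known genes.

    ``frame`` has one row per unigene flagged in at least one category:
    columns ``unigene_id``, one Yes/No flag per category, and per
    category the distinct-cluster count and the semicolon-joined
    supporting gene ids. ``provenance`` records the rule parameters.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def cluster_known_by_homology(
    genes: Mapping[str, str],
    thresholds: HomologyThresholds | None = None,
    config: AlignerConfig | None = None,
) -> list[set[str]]:
    """Single-linkage clusters under pairwise protein-protein homology.

    Two genes are linked when their local alignment passes the E-value
    and identity thresholds (coverage is not required for redundancy
    detection). The E-value search space for a pair is the product of
    the two sequence lengths. Clusters are sorted by smallest member id.
    """
    if not genes:
        raise ValueError("need at least one gene")
    thresholds = thresholds or HomologyThresholds()
    config = config or AlignerConfig()
    aligner = make_aligner(config)
    ids = sorted(genes)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            aln = local_align(genes[a], genes[b], aligner=aligner)
            if aln is None:
                continue
            evalue = estimate_evalue(
                aln.score, len(genes[a]), len(genes[b]),
                config.lambda_, config.k,
            )
            if (
                evalue < thresholds.evalue_max
                and aln.identity_pct > thresholds.identity_min_pct
            ):
                g.add_edge(a, b)
    clusters = [set(c) for c in nx.connected_components(g)]
    clusters.sort(key=min)
    return clusters


def map_known_genes(
    known_seqs: Mapping[str, str],
    category_table: pd.DataFrame,
    unigenes: Mapping[str, str],
    thresholds: HomologyThresholds | None = None,
    config: AlignerConfig | None = None,
    hits: pd.DataFrame | None = None,
) -> KnownGeneMap:
    """Map each category's known genes onto homologous unigenes.

    Uses the same translated search and filters as the network stage.
    Precomputed hits (e.g. from a BLAST outfmt 6 file, already filtered)
    can be passed via ``hits`` to skip the built-in aligner. Genes listed
    in the category table but absent from the sequence set are an error.
    """
    thresholds = thresholds or HomologyThresholds()
    missing = sorted(set(category_table["gene_id"]) - set(known_seqs))
    if missing:
        raise ValueError(f"category table references unknown gene: {missing[0]}")
    if hits is None:
        hits = search_homologs(known_seqs, unigenes, thresholds, config)
    by_gene: dict[str, set[str]] = {
        g: set() for g in category_table["gene_id"]
    }
    for qid, sid in zip(hits["qseqid"], hits["sseqid"]):
        if qid in by_gene:
            by_gene[qid].add(sid)
    categories = tuple(dict.fromkeys(category_table["category"]))
    gene_to_unigenes: dict[str, dict[str, set[str]]] = {}
    clusters: dict[str, list[set[str]]] = {}
    for cat in categories:
        genes = sorted(
            category_table.loc[
                category_table["category"] == cat, "gene_id"
            ]
        )
        gene_to_unigenes[cat] = {g: set(by_gene[g]) for g in genes}
        clusters[cat] = cluster_known_by_homology(
            {g: known_seqs[g] for g in genes}, thresholds, config
        )
    return KnownGeneMap(categories, gene_to_unigenes, clusters)


def predict_novel_genes(
    net: TransferredNetwork,
    known_map: KnownGeneMap,
    rule: PredictionRule | None = None,
) -> PredictionTable:
    """Apply the association rule to every unigene in the network.

    For each category, a unigene u that is not itself a homolog of the
    category's known genes is examined: the supporting genes are those
    with at least one homologous unigene among u's direct neighbours.
    Under ``cluster-count`` the distinct homology clusters among supports
    are counted and u is flagged when the count strictly exceeds
    ``min_support``; under ``strict-disqualify`` any homologous pair
    among the supports disqualifies u outright.
    """
    rule = rule or PredictionRule()
    g = net.graph
    all_mapped = {
        u
        for per_gene in known_map.gene_to_unigenes.values()
        for unis in per_gene.values()
        for u in unis
    }
    if all_mapped and g.number_of_nodes() and not (all_mapped & set(g.nodes)):
        raise ValueError(
            "no mapped known-gene unigene appears in the network; "
            "network and map were likely built from different inputs"
        )
    records: dict[str, dict] = {}
    for cat in known_map.categories:
        per_gene = known_map.gene_to_unigenes[cat]
        cluster_of = known_map.cluster_index(cat)
        self_homologs = {u for unis in per_gene.values() for u in unis}
        for u in sorted(g.nodes):
            if u in self_homologs:
                continue
            nbrs = set(g[u])
            supports = sorted(
                gene for gene, unis in per_gene.items() if unis & nbrs
            )
            if not supports:
                continue
            support_clusters = {cluster_of[gene] for gene in supports}
            if rule.redundancy_mode == "cluster-count":
                flagged = len(support_clusters) > rule.min_support
            else:  # strict-disqualify
                flagged = (
                    len(support_clusters) == len(supports)
                    and len(supports) > rule.min_support
                )
            if not flagged:
                continue
            row = records.setdefault(u, {"unigene_id": u})
            row[cat] = "Yes"
            row[f"{cat}_n_clusters"] = len(support_clusters)
            row[f"{cat}_supporting_genes"] = ";".join(supports)
    columns = ["unigene_id"]
    for cat in known_map.categories:
        columns += [cat, f"{cat}_n_clusters", f"{cat}_supporting_genes"]
    frame = pd.DataFrame(
        [records[u] for u in sorted(records)], columns=columns
    )
    for cat in known_map.categories:
        if len(frame):
            frame[cat] = frame[cat].fillna("No")
            frame[f"{cat}_n_clusters"] = frame[
                f"{cat}_n_clusters"
            ].astype("Int64")
            frame[f"{cat}_supporting_genes"] = frame[
                f"{cat}_supporting_genes"
            ].fillna("")
    provenance = {
        "min_support": rule.min_support,
        "redundancy_mode": rule.redundancy_mode,
        "categories": list(known_map.categories),
    }
    logger.info(
        "prediction: %d unigenes flagged across %d categories",
        len(frame), len(known_map.categories),
    )
    return PredictionTable(frame=frame, provenance=provenance)


def count_predictions(
    table: PredictionTable | pd.DataFrame,
    categories: Sequence[str] | None = None,
) -> dict[str, int]:
    """Per-category flagged counts plus total distinct flagged unigenes."""
    frame = table.frame if isinstance(table, PredictionTable) else table
    if categories is None:
        categories = [
            c for c in frame.columns
            if c != "unigene_id" and frame[c].isin(["Yes", "No"]).all()
        ]
    counts = {}
    flagged_any = pd.Series(False, index=frame.index)
    for cat in categories:
        mask = frame[cat] == "Yes" if cat in frame else pd.Series(
            False, index=frame.index
        )
        counts[cat] = int(mask.sum())
        flagged_any |= mask
    counts["total"] = int(
        frame.loc[flagged_any, "unigene_id"].nunique()
    ) if len(frame) else 0
    return counts


def write_prediction_table(table: PredictionTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_prediction_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_summary(
    table: PredictionTable, path, extra: dict | None = None
) -> None:
    payload = {
        "counts": count_predictions(table),
        "rule": table.provenance,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
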