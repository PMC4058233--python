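"""Synthetic inputs with recorded ground truth.

Every downstream stage (translated homology search, interolog transfer,
guilt-by-association prediction) is testable without any database
download by emulating its real inputs:

* scale-free reference PPI networks grown by seeded preferential
  attachment (seed graph = a single edge; each new node attaches
  ``edges_per_new_node`` distinct, degree-weighted targets);
* random proteomes, one amino-acid sequence per network node;
* unigene libraries: nucleotide sequences back-translated from source
  proteins after point substitutions tuned to a target amino-acid
  identity (coverage stays 100% by construction), placed in varied
  reading frames including reverse-complement orientations, plus
  unrelated random decoys;
* known stress-gene sets implanted so that selected "candidate" nodes
  have more than ``min_support`` known-gene neighbours, together with
  negative controls (exactly ``support_size - 1`` known neighbours) and a
  redundant-pair control whose supports include a homologous gene pair.

The returned :class:`SyntheticTruth` records every mapping, and the
implanted-candidate sets are enumerated by applying the association rule
exhaustively to the reference graph, so accidental rule-satisfiers are
part of the truth rather than surprises downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .homology import _CODON_TO_AA
from .network import ReferenceNetwork

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TO_AA.items()):
    if _aa != "*":
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)

_FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating synthetic inputs.

    ``unigene_to_source`` maps unigene id -> (species id, protein id,
    realised amino-acid identity fraction). ``implanted_candidates`` maps
    category -> unigene ids that satisfy the association rule by
    exhaustive enumeration on the reference graph; ``negative_controls``
    are unigenes given exactly ``support_size - 1`` known neighbours and
    ``redundant_controls`` unigenes whose support exceeds the threshold
    only when homologous known genes are double-counted.
    """

    unigene_to_source: dict[str, tuple[str, str, float]] = field(
        default_factory=dict
    )
    decoy_ids: set[str] = field(default_factory=set)
    implanted_candidates: dict[str, set[str]] = field(default_factory=dict)
    implanted_known: dict[str, set[str]] = field(default_factory=dict)
    negative_controls: dict[str, set[str]] = field(default_factory=dict)
    redundant_controls: dict[str, set[str]] = field(default_factory=dict)
    known_gene_source: dict[str, str | None] = field(default_factory=dict)
    known_clusters: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        overlap = self.decoy_ids & set(self.unigene_to_source)
        if overlap:
            raise ValueError(f"decoys overlap sources: {sorted(overlap)[:3]}")
        for ident in (v[2] for v in self.unigene_to_source.values()):
            if not 0 < ident <= 1:
                raise ValueError("implanted identity outside (0, 1]")
        for cat, unis in self.implanted_candidates.items():
            missing = unis - set(self.unigene_to_source)
            if missing:
                raise ValueError(
                    f"{cat}: candidates without source: {sorted(missing)[:3]}"
                )

    def to_json(self, path) -> None:
        def enc(obj):
            if isinstance(obj, set):
                return sorted(obj)
            if isinstance(obj, tuple):
                return list(obj)
            raise TypeError(type(obj))

        payload = {
            "unigene_to_source": {
                k: list(v) for k, v in sorted(self.unigene_to_source.items())
            },
            "decoy_ids": sorted(self.decoy_ids),
            "implanted_candidates": {
                k: sorted(v) for k, v in sorted(self.implanted_candidates.items())
            },
            "implanted_known": {
                k: sorted(v) for k, v in sorted(self.implanted_known.items())
            },
            "negative_controls": {
                k: sorted(v) for k, v in sorted(self.negative_controls.items())
            },
            "redundant_controls": {
                k: sorted(v) for k, v in sorted(self.redundant_controls.items())
            },
            "known_gene_source": dict(sorted(self.known_gene_source.items())),
            "known_clusters": {
                k: dict(sorted(v.items()))
                for k, v in sorted(self.known_clusters.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=enc))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            unigene_to_source={
                k: (v[0], v[1], float(v[2]))
                for k, v in raw["unigene_to_source"].items()
            },
            decoy_ids=set(raw["decoy_ids"]),
            implanted_candidates={
                k: set(v) for k, v in raw["implanted_candidates"].items()
            },
            implanted_known={
                k: set(v) for k, v in raw["implanted_known"].items()
            },
            negative_controls={
                k: set(v) for k, v in raw["negative_controls"].items()
            },
            redundant_controls={
                k: set(v) for k, v in raw["redundant_controls"].items()
            },
            known_gene_source=dict(raw["known_gene_source"]),
            known_clusters={
                k: {g: int(c) for g, c in v.items()}
                for k, v in raw["known_clusters"].items()
            },
        )


def generate_reference_network(
    n_nodes: int,
    edges_per_new_node: int,
    species_id: str = "spA",
    seed: int = 0,
) -> ReferenceNetwork:
    """Grow a connected scale-free graph by preferential attachment.

    The seed graph is a single edge; each subsequent node attaches
    ``edges_per_new_node`` edges (fewer while the graph is smaller) to
    distinct existing nodes sampled proportionally to degree. The total
    edge count is therefore ``1 + m * (n - 2)`` for ``n > m + 1``.
    """
    m = edges_per_new_node
    if not (isinstance(n_nodes, (int, np.integer)) and n_nodes > m >= 1):
        raise ValueError("require n_nodes > edges_per_new_node >= 1")
    rng = np.random.default_rng(seed)
    name = [f"{species_id}_P{i:04d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_edge(name[0], name[1])
    # endpoint multiset: sampling uniformly from it is degree-weighted
    endpoints = [0, 1]
    for i in range(2, n_nodes):
        k = min(m, i)
        targets: set[int] = set()
        while len(targets) < k:
            targets.add(endpoints[rng.integers(len(endpoints))])
        for t in sorted(targets):
            g.add_edge(name[i], name[t])
            endpoints.extend((i, t))
    return ReferenceNetwork(species_id, g)


def generate_proteome(
    network: ReferenceNetwork,
    min_len: int = 120,
    max_len: int = 240,
    seed: int = 0,
) -> dict[str, str]:
    """One random amino-acid sequence per network node.

    Lengths are uniform on [min_len, max_len]; residues are drawn
    uniformly from the 20 standard amino acids.
    """
    if not 20 <= min_len <= max_len:
        raise ValueError("require 20 <= min_len <= max_len")
    nodes = sorted(network.graph.nodes)
    if not nodes:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AA_ALPHABET))
    proteome = {}
    for node in nodes:
        length = int(rng.integers(min_len, max_len + 1))
        proteome[node] = "".join(rng.choice(alphabet, size=length))
    return proteome


def mutate_protein(
    seq: str,
    target_identity: float,
    rng: np.random.Generator,
    protect_ends: int = 2,
) -> tuple[str, float]:
    """Point-substitute residues to reach a target identity fraction.

    The first/last ``protect_ends`` residues are never touched so local
    alignments keep full coverage. Returns (mutated sequence, realised
    identity), exact because substitutions never overlap.
    """
    length = len(seq)
    n_sub = round(length * (1.0 - target_identity))
    eligible = np.arange(protect_ends, length - protect_ends)
    if n_sub > len(eligible):
        raise ValueError(
            f"cannot place {n_sub} substitutions in {len(eligible)} positions"
        )
    positions = rng.choice(eligible, size=n_sub, replace=False)
    residues = list(seq)
    for pos in sorted(positions):
        choices = [a for a in AA_ALPHABET if a != residues[pos]]
        residues[pos] = choices[rng.integers(len(choices))]
    return "".join(residues), (length - n_sub) / length


def back_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Nucleotide coding sequence with uniform synonymous codon choice."""
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))]
        for aa in aa_seq
    )


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(NT_ALPHABET))[rng.integers(4, size=length)])


def generate_unigenes(
    proteome: Mapping[str, str],
    target_identity: float = 0.85,
    source_fraction: float = 1.0,
    n_decoys: int = 10,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Emit nucleotide unigenes derived from source proteins, plus decoys.

    Each selected source protein is point-mutated to ``target_identity``,
    back-translated, framed with small random pads (so the encoded frame
    varies) and reverse-complemented half the time. Decoys are unrelated
    random nucleotide sequences. The truth records every unigene ->
    (species, protein, realised identity) mapping.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    if not 0 <= source_fraction <= 1:
        raise ValueError("source_fraction must be in [0, 1]")
    if n_decoys < 0:
        raise ValueError("n_decoys must be non-negative")
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(seed)
    sources = sorted(proteome)
    n_chosen = round(source_fraction * len(sources))
    chosen_idx = sorted(
        rng.choice(len(sources), size=n_chosen, replace=False).tolist()
    )
    unigenes: dict[str, str] = {}
    for serial, idx in enumerate(chosen_idx):
        pid = sources[idx]
        protein = proteome[pid]
        mutated, realised = mutate_protein(protein, target_identity, rng)
        cds = back_translate(mutated, rng)
        frame = _FRAMES[rng.integers(len(_FRAMES))]
        nt = _random_nt(rng, abs(frame) - 1) + cds + _random_nt(
            rng, int(rng.integers(0, 6))
        )
        if frame < 0:
            nt = reverse_complement(nt)
        uid = f"uni{serial:04d}"
        unigenes[uid] = nt
        species = pid.split("_P")[0] if "_P" in pid else "unknown"
        truth.unigene_to_source[uid] = (species, pid, realised)
    lengths = [len(p) for p in proteome.values()]
    lo, hi = min(lengths), max(lengths)
    for i in range(n_decoys):
        uid = f"dec{i:04d}"
        unigenes[uid] = _random_nt(rng, 3 * int(rng.integers(lo, hi + 1)))
        truth.decoy_ids.add(uid)
    truth.validate()
    return unigenes, truth


def clone_ortholog_network(
    network: ReferenceNetwork,
    proteome: Mapping[str, str],
    species_id: str,
    identity: float = 0.9,
    seed: int = 0,
) -> tuple[ReferenceNetwork, dict[str, str]]:
    """Clone a reference network's topology into a second species whose
    proteins are point-mutated orthologs of the originals.

    This gives transferred edges genuine multi-species support: a unigene
    homologous to a protein is also homologous to its ortholog.
    """
    rng = np.random.default_rng(seed)
    rename = {
        node: f"{species_id}{node[len(network.species_id):]}"
        if node.startswith(network.species_id)
        else f"{species_id}_{node}"
        for node in network.graph.nodes
    }
    g = nx.relabel_nodes(network.graph, rename, copy=True)
    ortho_proteome = {}
    for node in sorted(network.graph.nodes):
        mutated, _ = mutate_protein(proteome[node], identity, rng)
        ortho_proteome[rename[node]] = mutated
    return ReferenceNetwork(species_id, g), ortho_proteome


def _enumerate_satisfiers(
    graph: nx.Graph,
    known_source: Mapping[str, str | None],
    cluster_of: Mapping[str, int],
    min_support: int,
    unigene_nodes: set[str],
) -> set[str]:
    """Nodes whose unigene the association rule would flag, by direct
    exhaustive evaluation on the reference graph."""
    source_nodes = {s for s in known_source.values() if s is not None}
    satisfiers = set()
    for node in unigene_nodes:
        if node in source_nodes:
            continue  # its unigene is itself homologous to a known gene
        neighbours = set(graph[node]) if node in graph else set()
        clusters = {
            cluster_of[g]
            for g, src in known_source.items()
            if src is not None and src in neighbours and src in unigene_nodes
        }
        if len(clusters) > min_support:
            satisfiers.add(node)
    return satisfiers


def generate_stress_gene_sets(
    network: ReferenceNetwork,
    proteome: Mapping[str, str],
    categories: Sequence[str] = ("cold", "drought", "salinity"),
    n_known_per_category: int = 12,
    n_implanted_candidates: int = 2,
    support_size: int = 5,
    seed: int = 0,
    n_negative_controls: int = 1,
    n_redundant_controls: int = 1,
    min_support: int = 4,
    redundant_identity: float = 0.9,
    truth: SyntheticTruth | None = None,
) -> tuple[dict[str, str], pd.DataFrame, SyntheticTruth]:
    """Designate known stress genes so the association rule has ground truth.

    Per category: ``n_implanted_candidates`` nodes each get
    ``support_size`` neighbours designated as known genes;
    ``n_negative_controls`` nodes get exactly ``support_size - 1``;
    ``n_redundant_controls`` nodes get ``min_support`` distinct known
    neighbours plus one extra known gene homologous to the first (so the
    raw gene count exceeds ``min_support`` but the cluster count does
    not). Remaining slots up to ``n_known_per_category`` are filled with
    unmapped random known genes (homolog-free, as many real database
    entries are). Designated known genes reuse the node's protein
    sequence; independent random sequences are mutually non-homologous.

    Returns (known-gene sequences, category table, updated truth). The
    truth's ``implanted_candidates`` are enumerated exhaustively, not
    assumed from the construction.
    """
    if support_size < 1:
        raise ValueError("support_size must be >= 1")
    if not categories:
        raise ValueError("categories must be non-empty")
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(seed)
    graph = network.graph
    degree = dict(graph.degree)
    if truth.unigene_to_source:
        unigene_of = {
            src[1]: uid for uid, src in truth.unigene_to_source.items()
        }
    else:  # no unigene stage yet: operate on protein node ids directly
        unigene_of = {node: node for node in graph.nodes}
    unigene_nodes = set(unigene_of)

    known_seqs: dict[str, str] = {}
    table_rows: list[tuple[str, str]] = []
    mean_len = int(np.mean([len(p) for p in proteome.values()]))

    for cat in categories:
        # categories are independent: the rule counts only this
        # category's known genes, so node reservations reset here and a
        # node may serve as candidate (or control) in several categories
        used: set[str] = set()
        gene_serial = 0
        known_source: dict[str, str | None] = {}
        cluster_of: dict[str, int] = {}
        gene_of_node: dict[str, str] = {}
        next_cluster = 0

        def new_gene(node: str | None, seq: str, cluster: int | None = None):
            nonlocal gene_serial, next_cluster
            gid = f"{cat}_K{gene_serial:03d}"
            gene_serial += 1
            known_seqs[gid] = seq
            table_rows.append((gid, cat))
            known_source[gid] = node
            if cluster is None:
                cluster = next_cluster
                next_cluster += 1
            cluster_of[gid] = cluster
            if node is not None:
                gene_of_node[node] = gid
            return gid

        def designate(node: str) -> str:
            if node in gene_of_node:
                return gene_of_node[node]
            return new_gene(node, proteome[node])

        nodes_sorted = sorted(unigene_nodes & set(graph.nodes))

        # Controls are placed first, while no known genes exist, so their
        # support counts are exact by construction; every later
        # designation must stay clear of control neighbourhoods.
        control_nodes: set[str] = set()

        def clear_of_controls(x: str) -> bool:
            return not any(nb in control_nodes for nb in graph[x])

        def place_control(n_wanted: int, n_support: int) -> list[str]:
            placed = []
            for node in nodes_sorted:
                if len(placed) >= n_wanted:
                    break
                if node in used or node in known_source.values():
                    continue
                if any(x in gene_of_node for x in graph[node]):
                    continue  # already supported; count would be off
                free = [
                    x for x in sorted(graph[node])
                    if x in unigene_nodes and x not in used
                    and x not in gene_of_node and clear_of_controls(x)
                ]
                if len(free) < n_support:
                    continue
                chosen = rng.choice(len(free), size=n_support, replace=False)
                for i in sorted(chosen.tolist()):
                    designate(free[i])
                    used.add(free[i])
                placed.append(node)
                used.add(node)
                control_nodes.add(node)
            return placed

        # --- redundant-pair controls: min_support distinct clusters plus
        # one extra known gene homologous to an existing support
        redundants = []
        for _ in range(n_redundant_controls):
            placed = place_control(1, min_support)
            if not placed:
                break
            node = placed[0]
            first_gene = next(
                g for g, src in known_source.items()
                if src is not None and src in graph[node]
            )
            twin_seq, _ = mutate_protein(
                known_seqs[first_gene], redundant_identity, rng
            )
            new_gene(
                known_source[first_gene], twin_seq,
                cluster=cluster_of[first_gene],
            )
            redundants.append(node)

        # --- negative controls: exactly support_size - 1 known neighbours
        negatives = (
            place_control(n_negative_controls, support_size - 1)
            if support_size >= 2 else []
        )

        # --- implanted candidates: > min_support known neighbours; a new
        # support may be any neighbour that is already a known gene, or a
        # fresh node whose designation cannot disturb a control
        def candidate_supports(n: str) -> list[str]:
            return [
                x for x in sorted(graph[n])
                if x in unigene_nodes and x not in control_nodes
                and (x in gene_of_node or clear_of_controls(x))
            ]

        eligible = [
            n for n in nodes_sorted
            if n not in used and degree[n] >= support_size
            and len(candidate_supports(n)) >= support_size
        ]
        if n_implanted_candidates > 0 and not eligible:
            raise ValueError(
                f"{cat}: no node with >= {support_size} eligible neighbours"
            )
        picks = rng.choice(
            len(eligible),
            size=min(n_implanted_candidates, len(eligible)),
            replace=False,
        )
        candidates = [eligible[i] for i in sorted(picks.tolist())]
        used.update(candidates)
        for cand in candidates:
            nbrs = [
                x for x in candidate_supports(cand) if x not in candidates
            ]
            chosen = rng.choice(
                len(nbrs), size=min(support_size, len(nbrs)), replace=False
            )
            for i in sorted(chosen.tolist()):
                designate(nbrs[i])

        # --- pad with unmapped known genes
        while gene_serial < n_known_per_category:
            new_gene(None, "".join(
                np.array(list(AA_ALPHABET))[rng.integers(20, size=mean_len)]
            ))

        satisfiers = _enumerate_satisfiers(
            graph, known_source, cluster_of, min_support, unigene_nodes
        )
        truth.implanted_candidates[cat] = {
            unigene_of[n] for n in satisfiers
        }
        truth.implanted_known[cat] = set(known_source)
        truth.negative_controls[cat] = {
            unigene_of[n] for n in negatives if n in unigene_of
        }
        truth.redundant_controls[cat] = {
            unigene_of[n] for n in redundants if n in unigene_of
        }
        truth.known_gene_source.update(known_source)
        truth.known_clusters[cat] = dict(cluster_of)

    category_table = pd.DataFrame(table_rows, columns=["gene_id", "category"])
    truth.validate()
    return known_seqs, category_table, truth


def write_category_table(table: pd.DataFrame, path) -> None:
    table.sort_values(["category", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_category_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
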