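"""Interolog transfer of reference PPI networks onto unigenes, plus
component decomposition and scale-free topology characterisation.

The transfer rule: two unigenes are joined by an edge whenever they are
homologous (via filtered translated-search hits) to the two endpoints of
an interaction in any reference species network. Every edge carries the
list of reference interactions supporting it, merged across species.

The degree distribution of a component is P(k) = N(k)/N, the fraction of
its N nodes having degree k; a scale-free component follows
P(k) = a * k^(-gamma), fitted by ordinary least squares on log-log axes
(a maximum-likelihood alternative is available).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import zeta

logger = logging.getLogger(__name__)

#: An evidence record: (species_id, protein_a, protein_b) of the
#: reference interaction supporting a transferred edge.
Evidence = tuple[str, str, str]


@dataclass
class ReferenceNetwork:
    """A species-tagged protein interaction graph (simple, undirected)."""

    species_id: str
    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"reference network has self-loops: {loops[:3]}")

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    @classmethod
    def from_edges(
        cls, species_id: str, edges: Iterable[tuple[str, str]]
    ) -> "ReferenceNetwork":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(species_id, g)


@dataclass
class TransferredNetwork:
    """Unigene-level interaction graph with per-edge provenance."""

    graph: nx.Graph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def evidence(self, u: str, v: str) -> list[Evidence]:
        return self.graph.edges[u, v]["evidence"]


@dataclass
class DegreeDistribution:
    """Empirical degree distribution P(k) = N(k)/N of a node set."""

    n_nodes: int
    entries: pd.DataFrame  # columns: k, n_k, p_k; one row per distinct k

    def __post_init__(self) -> None:
        if int(self.entries["n_k"].sum()) != self.n_nodes:
            raise ValueError("degree counts do not sum to the node count")
        if abs(float(self.entries["p_k"].sum()) - 1.0) > 1e-12:
            raise ValueError("P(k) does not sum to 1")


@dataclass
class PowerLawFit:
    """Fit of P(k) = coefficient * k^(-exponent)."""

    coefficient: float
    exponent: float
    r_squared: float
    n_points: int
    method: str = "ols"

    def to_dict(self) -> dict:
        return {
            "coefficient": self.coefficient,
            "exponent": self.exponent,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "method": self.method,
        }


def read_reference_networks(path) -> list[ReferenceNetwork]:
    """Read a species-tagged edge list TSV (species, protein_a, protein_b)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["species", "protein_a", "protein_b"], dtype=str,
    )
    nets = []
    for sp, grp in df.groupby("species", sort=True):
        nets.append(
            ReferenceNetwork.from_edges(
                sp, zip(grp["protein_a"], grp["protein_b"])
            )
        )
    return nets


def write_reference_networks(nets: Sequence[ReferenceNetwork], path) -> None:
    rows = [
        (net.species_id, *sorted((u, v)))
        for net in nets
        for u, v in net.graph.edges
    ]
    rows.sort()
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def best_hits_per_species(
    hits: pd.DataFrame, ref_networks: Sequence[ReferenceNetwork]
) -> pd.DataFrame:
    """Sensitivity-analysis mode: per (unigene, species), keep only the
    highest-bitscore protein hit (ties broken by query id)."""
    species_of = {
        p: net.species_id for net in ref_networks for p in net.graph.nodes
    }
    df = hits.copy()
    df["_species"] = df["qseqid"].map(species_of)
    df = df[df["_species"].notna()]
    df = df.sort_values(
        ["sseqid", "_species", "bitscore", "qseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    df = df.drop_duplicates(["sseqid", "_species"], keep="first")
    return df.drop(columns="_species").sort_index()


def transfer_interactions(
    ref_networks: Sequence[ReferenceNetwork],
    hits: pd.DataFrame,
) -> TransferredNetwork:
    """Build the unigene network by the interolog rule.

    An edge (u, v), u != v, exists iff some reference interaction (p, q)
    has a qualifying hit p -> u and q -> v in any species. Support from
    several species (or several reference edges) is merged into one edge
    with accumulated evidence. Hits whose query protein is absent from
    every reference network are skipped with a warning.
    """
    known = {p for net in ref_networks for p in net.graph.nodes}
    homologs: dict[str, set[str]] = {}
    n_skipped = 0
    for qid, sid in zip(hits["qseqid"], hits["sseqid"]):
        if qid not in known:
            n_skipped += 1
            continue
        homologs.setdefault(qid, set()).add(sid)
    if n_skipped:
        logger.warning(
            "skipped %d hits whose query is in no reference network",
            n_skipped,
        )
    g = nx.Graph()
    empty: set[str] = set()
    for net in ref_networks:
        for p, q in net.graph.edges:
            record = (net.species_id, *sorted((p, q)))
            for u in homologs.get(p, empty):
                for v in homologs.get(q, empty):
                    if u == v:
                        continue
                    if g.has_edge(u, v):
                        g.edges[u, v]["evidence"].add(record)
                    else:
                        g.add_edge(u, v, evidence={record})
    for u, v, data in g.edges(data=True):
        data["evidence"] = sorted(data["evidence"])
    logger.info(
        "interolog transfer: %d unigenes, %d edges from %d reference nets",
        g.number_of_nodes(), g.number_of_edges(), len(ref_networks),
    )
    return TransferredNetwork(g)


def connected_components(
    net: TransferredNetwork | nx.Graph,
) -> list[set[str]]:
    """Components sorted by size (descending), ties by smallest node id."""
    g = net.graph if isinstance(net, TransferredNetwork) else net
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def degree_distribution(
    net: TransferredNetwork | nx.Graph,
    nodes: Iterable[str] | None = None,
) -> DegreeDistribution:
    """P(k) = N(k)/N over the subgraph induced by ``nodes``.

    Degrees are counted within the induced subgraph, so a component's
    distribution is self-contained.
    """
    g = net.graph if isinstance(net, TransferredNetwork) else net
    sub = g if nodes is None else g.subgraph(set(nodes))
    n = sub.number_of_nodes()
    if n == 0:
        raise ValueError("empty node set")
    degrees = pd.Series([d for _, d in sub.degree()])
    counts = degrees.value_counts().sort_index()
    entries = pd.DataFrame(
        {
            "k": counts.index.to_numpy(dtype=int),
            "n_k": counts.to_numpy(dtype=int),
        }
    )
    entries["p_k"] = entries["n_k"] / n
    return DegreeDistribution(n_nodes=n, entries=entries)


def fit_power_law(
    dist: DegreeDistribution, method: str = "ols"
) -> PowerLawFit:
    """Fit P(k) = a * k^(-gamma) to a degree distribution.

    ``ols`` (default): unweighted least squares on (log10 k, log10 P(k))
    over entries with k >= 1 and P(k) > 0; gamma = -slope, a =
    10^intercept. ``mle``: discrete power-law maximum likelihood
    (Clauset-style continuous approximation) on the raw degrees, with the
    coefficient taken from the Hurwitz-zeta normalisation; r^2 is then
    descriptive only, computed on the same log-log axes.
    """
    usable = dist.entries[(dist.entries["k"] >= 1) & (dist.entries["p_k"] > 0)]
    if len(usable) < 2:
        raise ValueError("need at least 2 entries with k >= 1 and P(k) > 0")
    log_k = np.log10(usable["k"].to_numpy(dtype=float))
    log_p = np.log10(usable["p_k"].to_numpy(dtype=float))
    if method == "ols":
        slope, intercept = np.polyfit(log_k, log_p, 1)
        exponent = -slope
        coefficient = 10.0 ** intercept
        pred = intercept + slope * log_k
    elif method == "mle":
        k = usable["k"].to_numpy(dtype=float)
        n_k = usable["n_k"].to_numpy(dtype=float)
        k_min = k.min()
        n = n_k.sum()
        exponent = 1.0 + n / float(
            (n_k * np.log(k / (k_min - 0.5))).sum()
        )
        coefficient = 1.0 / float(zeta(exponent, k_min))
        pred = np.log10(coefficient) - exponent * log_k
    else:
        raise ValueError(f"unknown fit method: {method!r}")
    ss_res = float(((log_p - pred) ** 2).sum())
    ss_tot = float(((log_p - log_p.mean()) ** 2).sum())
    if ss_tot < 1e-30:
        r2 = 1.0 if ss_res < 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return PowerLawFit(
        coefficient=float(coefficient),
        exponent=float(exponent),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points=len(usable),
        method=method,
    )


def _evidence_str(records: list[Evidence]) -> str:
    return ";".join(f"{sp}:{a}:{b}" for sp, a, b in records)


def write_edge_list(net: TransferredNetwork, path) -> None:
    """TSV edge list: unigene_a, unigene_b, evidence (semicolon-joined
    ``species:protein_a:protein_b`` records)."""
    rows = sorted(
        (*sorted((u, v)), _evidence_str(data["evidence"]))
        for u, v, data in net.graph.edges(data=True)
    )
    pd.DataFrame(
        rows, columns=["unigene_a", "unigene_b", "evidence"]
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> TransferredNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.Graph()
    for u, v, ev in zip(df["unigene_a"], df["unigene_b"], df["evidence"]):
        records = sorted(
            tuple(item.split(":", 2)) for item in str(ev).split(";")
        )
        g.add_edge(u, v, evidence=records)
    return TransferredNetwork(g)


def write_graphml(net: TransferredNetwork, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes))
    for u, v in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges)):
        g.add_edge(u, v, evidence=_evidence_str(net.graph.edges[u, v]["evidence"]))
    nx.write_graphml(g, str(path))


def write_degree_distribution(dist: DegreeDistribution, path) -> None:
    dist.entries.to_csv(path, sep="\t", index=False)


def write_fit(fit: PowerLawFit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2, sort_keys=True))


def plot_degree_distribution(
    dist: DegreeDistribution, fit: PowerLawFit | None, path
) -> None:
    """Log-log degree distribution scatter with the fitted power law."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    usable = dist.entries[(dist.entries["k"] >= 1) & (dist.entries["p_k"] > 0)]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.loglog(usable["k"], usable["p_k"], "o", ms=4, label="P(k)")
    if fit is not None:
        k = np.linspace(usable["k"].min(), usable["k"].max(), 100)
        ax.loglog(
            k, fit.coefficient * k ** (-fit.exponent), "r-",
            label=f"{fit.coefficient:.2f} k^-{fit.exponent:.2f}",
        )
    ax.set_xlabel("degree k")
    ax.set_ylabel("P(k)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
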