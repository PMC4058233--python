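"""Independent brute-force oracles used only by the test suite.

These deliberately restate the rules from scratch — exhaustive dynamic
programming for local alignment, triple-loop enumeration for interolog
transfer, and a direct transcription of the association rule — so the
library implementations are checked against a second, independent route.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def gotoh_local_score(a: str, b: str, matrix, gap_open: float,
                      gap_extend: float) -> float:
    """Exhaustive affine-gap Smith-Waterman score.

    A gap of length L costs ``gap_open + gap_extend * L`` (BLAST
    convention). Returns 0 when no positive-scoring local alignment
    exists.
    """
    neg = float("-inf")
    n, m = len(a), len(b)
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    e = [[neg] * (m + 1) for _ in range(n + 1)]
    f = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(
                e[i][j - 1] - gap_extend,
                h[i][j - 1] - gap_open - gap_extend,
            )
            f[i][j] = max(
                f[i - 1][j] - gap_extend,
                h[i - 1][j] - gap_open - gap_extend,
            )
            h[i][j] = max(
                0.0,
                h[i - 1][j - 1] + float(matrix[a[i - 1], b[j - 1]]),
                e[i][j],
                f[i][j],
            )
            best = max(best, h[i][j])
    return best


def transfer_bruteforce(ref_networks, hits: pd.DataFrame) -> set[frozenset]:
    """Enumerate every (reference edge x hit x hit) triple directly."""
    pairs = list(zip(hits["qseqid"], hits["sseqid"]))
    edges: set[frozenset] = set()
    for net in ref_networks:
        node_set = set(net.graph.nodes)
        for p, q in net.graph.edges:
            for q1, u in pairs:
                if q1 != p or q1 not in node_set:
                    continue
                for q2, v in pairs:
                    if q2 != q or q2 not in node_set or u == v:
                        continue
                    edges.add(frozenset((u, v)))
    return edges


def predict_bruteforce(
    graph: nx.Graph,
    gene_to_unigenes: dict[str, set[str]],
    cluster_of: dict[str, int],
    min_support: int,
    redundancy_mode: str = "cluster-count",
) -> set[str]:
    """Direct evaluation of the association rule for one category."""
    self_homologs = {
        u for unis in gene_to_unigenes.values() for u in unis
    }
    flagged = set()
    for u in graph.nodes:
        if u in self_homologs:
            continue
        neighbours = set(graph[u])
        supports = [
            g for g, unis in gene_to_unigenes.items() if unis & neighbours
        ]
        clusters = {cluster_of[g] for g in supports}
        if redundancy_mode == "cluster-count":
            ok = len(clusters) > min_support
        else:
            ok = len(clusters) == len(supports) and len(supports) > min_support
        if ok:
            flagged.add(u)
    return flagged
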