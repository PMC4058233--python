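"""Synthetic-data generators: growth rule, proteomes, unigenes, truth."""

import numpy as np
import pytest

from stressnet.homology import search_homologs, translate_six_frames
from stressnet.io import write_fasta
from stressnet.simulate import (
    SyntheticTruth,
    back_translate,
    clone_ortholog_network,
    generate_proteome,
    generate_reference_network,
    generate_stress_gene_sets,
    generate_unigenes,
    mutate_protein,
)


class TestReferenceNetwork:
    def test_smallest_growth_step(self):
        net = generate_reference_network(2, 1, seed=0)
        assert net.graph.number_of_nodes() == 2
        assert net.graph.number_of_edges() == 1

    @pytest.mark.parametrize("n,m", [(100, 2), (50, 3), (10, 1)])
    def test_edge_count_follows_growth_rule(self, n, m):
        # seed edge + m edges per added node (fewer while graph is small)
        expected = 1 + sum(min(m, i) for i in range(2, n))
        net = generate_reference_network(n, m, seed=1)
        assert net.graph.number_of_nodes() == n
        assert net.graph.number_of_edges() == expected

    def test_connected_and_simple(self):
        import networkx as nx

        net = generate_reference_network(200, 2, seed=3)
        assert nx.is_connected(net.graph)
        assert nx.number_of_selfloops(net.graph) == 0

    def test_same_seed_identical_edges(self):
        a = generate_reference_network(100, 2, seed=5)
        b = generate_reference_network(100, 2, seed=5)
        assert set(a.graph.edges) == set(b.graph.edges)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_reference_network(2, 2)


class TestProteome:
    def test_one_sequence_per_node_with_length_bounds(self):
        net = generate_reference_network(100, 2, seed=1)
        prot = generate_proteome(net, 120, 180, seed=2)
        assert set(prot) == set(net.graph.nodes)
        assert all(120 <= len(s) <= 180 for s in prot.values())
        assert all(set(s) <= set("ACDEFGHIKLMNPQRSTVWY")
                   for s in prot.values())

    def test_degenerate_length_range(self):
        net = generate_reference_network(2, 1, seed=0)
        prot = generate_proteome(net, 50, 50, seed=0)
        assert all(len(s) == 50 for s in prot.values())

    def test_different_seeds_differ(self):
        net = generate_reference_network(20, 2, seed=1)
        assert generate_proteome(net, 100, 150, seed=1) != generate_proteome(
            net, 100, 150, seed=2
        )

    def test_empty_network_rejected(self):
        import networkx as nx

        from stressnet.network import ReferenceNetwork

        with pytest.raises(ValueError):
            generate_proteome(ReferenceNetwork("sp", nx.Graph()), 50, 60)


class TestMutateAndBackTranslate:
    def test_identity_realised_exactly(self):
        rng = np.random.default_rng(0)
        protein = "".join(
            np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.integers(20, size=200)]
        )
        mutated, realised = mutate_protein(protein, 0.85, rng)
        observed = sum(a == b for a, b in zip(protein, mutated)) / 200
        assert observed == realised
        assert 0.82 <= realised <= 0.88

    def test_back_translation_decodes_to_protein(self):
        rng = np.random.default_rng(1)
        protein = "MKWLVNSTACDEFGHIRQPY"
        nt = back_translate(protein, rng)
        assert translate_six_frames(nt)[1] == protein


class TestUnigenes:
    def test_full_identity_translation_matches_source(self):
        net = generate_reference_network(10, 2, seed=2)
        prot = generate_proteome(net, 100, 120, seed=3)
        unis, truth = generate_unigenes(prot, 1.0, 1.0, n_decoys=0, seed=4)
        assert len(unis) == 10
        for uid, (_, pid, ident) in truth.unigene_to_source.items():
            assert ident == 1.0
            frames = translate_six_frames(unis[uid])
            assert any(prot[pid] in aa for aa in frames.values())

    def test_frames_are_varied(self):
        net = generate_reference_network(40, 2, seed=2)
        prot = generate_proteome(net, 100, 120, seed=3)
        unis, truth = generate_unigenes(prot, 1.0, 1.0, n_decoys=0, seed=4)
        hits = search_homologs(prot, {
            uid: unis[uid] for uid in sorted(truth.unigene_to_source)[:15]
        })
        assert hits["frame"].nunique() >= 3
        assert (hits["frame"] < 0).any() and (hits["frame"] > 0).any()

    def test_all_decoy_case(self):
        net = generate_reference_network(5, 1, seed=0)
        prot = generate_proteome(net, 100, 120, seed=0)
        unis, truth = generate_unigenes(prot, 0.9, 0.0, n_decoys=5, seed=0)
        assert len(unis) == 5
        assert truth.unigene_to_source == {}
        assert len(truth.decoy_ids) == 5

    def test_negative_decoys_rejected(self):
        net = generate_reference_network(5, 1, seed=0)
        prot = generate_proteome(net, 100, 120, seed=0)
        with pytest.raises(ValueError):
            generate_unigenes(prot, 0.9, 1.0, n_decoys=-1)

    def test_byte_identical_fasta_for_same_seed(self, tmp_path):
        net = generate_reference_network(15, 2, seed=6)
        prot = generate_proteome(net, 100, 120, seed=7)
        paths = []
        for run in (1, 2):
            unis, _ = generate_unigenes(prot, 0.85, 1.0, 5, seed=8)
            p = tmp_path / f"u{run}.fna"
            write_fasta(unis, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


@pytest.fixture(scope="module")
def world():
    net = generate_reference_network(60, 3, seed=11)
    prot = generate_proteome(net, 100, 140, seed=12)
    unis, truth = generate_unigenes(prot, 1.0, 1.0, 5, seed=13)
    known, table, truth = generate_stress_gene_sets(
        net, prot, ("cold", "drought"), n_known_per_category=12,
        n_implanted_candidates=2, support_size=5, seed=14, truth=truth,
    )
    return net, prot, known, table, truth


class TestStressGeneSets:
    def test_candidates_have_enough_known_neighbours(self, world):
        net, prot, known, table, truth = world
        uni_to_node = {u: s[1] for u, s in truth.unigene_to_source.items()}
        for cat, unis in truth.implanted_candidates.items():
            assert unis  # at least one implanted candidate per category
            sources = {
                truth.known_gene_source[g]
                for g in truth.implanted_known[cat]
                if truth.known_gene_source[g] is not None
            }
            for uid in unis:
                node = uni_to_node[uid]
                known_neighbours = sources & set(net.graph[node])
                assert len(known_neighbours) >= 5

    def test_negative_controls_sit_exactly_below_threshold(self, world):
        net, prot, known, table, truth = world
        uni_to_node = {u: s[1] for u, s in truth.unigene_to_source.items()}
        for cat, unis in truth.negative_controls.items():
            assert unis
            cluster_of = truth.known_clusters[cat]
            sources = {
                g: truth.known_gene_source[g]
                for g in truth.implanted_known[cat]
            }
            for uid in unis:
                node = uni_to_node[uid]
                clusters = {
                    cluster_of[g]
                    for g, src in sources.items()
                    if src is not None and src in net.graph[node]
                }
                assert len(clusters) == 4
            assert not unis & truth.implanted_candidates[cat]

    def test_redundant_pair_shares_cluster(self, world):
        net, prot, known, table, truth = world
        for cat in ("cold", "drought"):
            cluster_of = truth.known_clusters[cat]
            by_cluster: dict[int, list] = {}
            for g, c in cluster_of.items():
                by_cluster.setdefault(c, []).append(g)
            paired = [gs for gs in by_cluster.values() if len(gs) > 1]
            assert paired  # the homologous-pair control exists
            assert not truth.redundant_controls[cat] & \
                truth.implanted_candidates[cat]

    def test_category_table_consistent(self, world):
        _, _, known, table, truth = world
        assert set(table["gene_id"]) == set(known)
        assert set(table["category"]) == {"cold", "drought"}
        assert (table.groupby("category").size() >= 12).all()

    def test_no_candidates_when_none_implanted(self):
        net = generate_reference_network(30, 2, seed=20)
        prot = generate_proteome(net, 100, 120, seed=21)
        unis, truth = generate_unigenes(prot, 1.0, 1.0, 0, seed=22)
        known, table, truth = generate_stress_gene_sets(
            net, prot, ("cold",), n_known_per_category=4,
            n_implanted_candidates=0, support_size=5, seed=23,
            n_negative_controls=0, n_redundant_controls=0, truth=truth,
        )
        assert truth.implanted_candidates["cold"] == set()

    def test_insufficient_degree_raises(self):
        net = generate_reference_network(5, 1, seed=0)  # a tree: low degree
        prot = generate_proteome(net, 100, 120, seed=0)
        with pytest.raises(ValueError, match="eligible neighbours"):
            generate_stress_gene_sets(
                net, prot, ("cold",), support_size=5,
                n_implanted_candidates=1, seed=0,
            )


class TestOrthologClone:
    def test_topology_preserved_and_sequences_mutated(self):
        net = generate_reference_network(20, 2, seed=30)
        prot = generate_proteome(net, 100, 120, seed=31)
        onet, oprot = clone_ortholog_network(net, prot, "spB", 0.9, seed=32)
        assert onet.species_id == "spB"
        assert onet.graph.number_of_edges() == net.graph.number_of_edges()
        for node in net.graph.nodes:
            twin = "spB" + node[len("spA"):]
            identical = sum(
                a == b for a, b in zip(prot[node], oprot[twin])
            ) / len(prot[node])
            assert 0.87 <= identical <= 0.93


class TestTruthSerialisation:
    def test_json_roundtrip(self, tmp_path):
        truth = SyntheticTruth(
            unigene_to_source={"u1": ("spA", "p1", 0.85)},
            decoy_ids={"d1"},
            implanted_candidates={"cold": {"u1"}},
            implanted_known={"cold": {"k1"}},
            known_gene_source={"k1": "p2", "k2": None},
            known_clusters={"cold": {"k1": 0, "k2": 1}},
        )
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back == truth

    def test_validation_rejects_decoy_source_overlap(self):
        truth = SyntheticTruth(
            unigene_to_source={"u1": ("spA", "p1", 1.0)}, decoy_ids={"u1"}
        )
        with pytest.raises(ValueError):
            truth.validate()
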