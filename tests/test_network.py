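"""Triplet assembly, tripartite networks, hubs, gene-set subnetworks."""

import numpy as np
import pytest

from cernet.coexpression import CoexpressionEdge
from cernet.errors import ValidationError
from cernet.network import (
    CeRNATriplet,
    assemble_triplets,
    build_network,
    extract_geneset_subnetwork,
    extract_hub_subnetwork,
    node_degrees,
)
from cernet.targets import DuplexSite, TargetPair

from oracles import assemble_oracle, hub_oracle


def _pair(mir, tid, cls):
    site = DuplexSite(mir, tid, cls, 1, 22, 1, 22, "A" * 22, "|" * 22, "U" * 22, 200.0, -40.0)
    return TargetPair(mir, tid, cls, site, 1)


def _edge(a, b, a_class="miRNA", b_class="mRNA", r=-0.9):
    return CoexpressionEdge(a, a_class, b, b_class, r, 1e-5, 12)


def _annot(mir, tid, cls):
    return (_pair(mir, tid, cls), _edge(mir, tid, "miRNA", cls))


def _strata(lnc_up=(), lnc_down=(), mir_up=(), mir_down=(), mrna_up=(), mrna_down=()):
    return {"lncRNA": {"up": set(lnc_up), "down": set(lnc_down)},
            "miRNA": {"up": set(mir_up), "down": set(mir_down)},
            "mRNA": {"up": set(mrna_up), "down": set(mrna_down)}}


def _triplet(lnc, mir, mrna, stratum="UP"):
    return CeRNATriplet(lnc, mir, mrna, stratum, 0.95, -0.9, -0.9)


class TestAssembleTriplets:
    def test_minimal_positive_case(self):
        strata = _strata(lnc_up=["L1"], mir_down=["M1"], mrna_up=["G1"])
        triplets = assemble_triplets(
            strata, [_annot("M1", "L1", "lncRNA")], [_annot("M1", "G1", "mRNA")],
            [_edge("L1", "G1", "lncRNA", "mRNA", 0.95)], "UP")
        assert [(t.lncrna_id, t.mirna_id, t.mrna_id) for t in triplets] == [("L1", "M1", "G1")]
        assert triplets[0].lnc_mrna_r == 0.95

    def test_missing_coexpression_edge_gives_no_triplet(self):
        strata = _strata(lnc_up=["L1"], mir_down=["M1"], mrna_up=["G1"])
        triplets = assemble_triplets(
            strata, [_annot("M1", "L1", "lncRNA")], [_annot("M1", "G1", "mRNA")], [], "UP")
        assert triplets == []

    def test_wrong_stratum_membership_gives_no_triplet(self):
        strata = _strata(lnc_down=["L1"], mir_down=["M1"], mrna_up=["G1"])
        triplets = assemble_triplets(
            strata, [_annot("M1", "L1", "lncRNA")], [_annot("M1", "G1", "mRNA")],
            [_edge("L1", "G1", "lncRNA", "mRNA", 0.95)], "UP")
        assert triplets == []

    def test_brute_force_oracle_on_random_instances(self, rng):
        """Assembly equals a triple loop applying the predicate, on random
        instances with up to 50 features per class."""
        for trial in range(10):
            n = int(rng.integers(10, 51))
            lncs = [f"L{i}" for i in range(n)]
            mirs = [f"M{i}" for i in range(n)]
            mrnas = [f"G{i}" for i in range(n)]
            strata = _strata(
                lnc_up=rng.choice(lncs, n // 2, replace=False),
                mir_down=rng.choice(mirs, n // 2, replace=False),
                mrna_up=rng.choice(mrnas, n // 2, replace=False))
            lnc_pairs = [_annot(m, l, "lncRNA") for m in mirs for l in lncs
                         if rng.random() < 0.15]
            mrna_pairs = [_annot(m, g, "mRNA") for m in mirs for g in mrnas
                          if rng.random() < 0.15]
            edges = [_edge(l, g, "lncRNA", "mRNA", 0.95) for l in lncs for g in mrnas
                     if rng.random() < 0.15]
            got = assemble_triplets(strata, lnc_pairs, mrna_pairs, edges, "UP")
            expected = assemble_oracle(strata, lnc_pairs, mrna_pairs, edges, "UP")
            assert {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in got} == expected
            # deterministic lexicographic ordering
            keys = [t.key() for t in got]
            assert keys == sorted(keys)

    def test_wrong_class_pair_rejected(self):
        strata = _strata(lnc_up=["L1"], mir_down=["M1"], mrna_up=["G1"])
        with pytest.raises(ValidationError, match="expected lncRNA"):
            assemble_triplets(strata, [_annot("M1", "G1", "mRNA")], [], [], "UP")


class TestBuildNetwork:
    def test_two_triplets_sharing_a_mirna(self):
        net = build_network([_triplet("L1", "M1", "G1"), _triplet("L2", "M1", "G2")])
        assert net.summary()["n_miRNA"] == 1
        assert net.summary()["n_lncRNA"] == 2
        assert net.n_edges == 4  # 2 lnc-mir + 2 mir-mrna, deduplicated

    def test_duplicate_edges_deduplicated(self):
        net = build_network([_triplet("L1", "M1", "G1"), _triplet("L1", "M1", "G2")])
        assert net.n_edges == 3  # one shared lnc-mir edge

    def test_empty_triplet_list(self):
        net = build_network([], stratum="UP")
        assert net.n_edges == 0 and not net.graph.nodes

    def test_mixed_strata_rejected(self):
        with pytest.raises(ValidationError, match="[Mm]ixed"):
            build_network([_triplet("L1", "M1", "G1", "UP"), _triplet("L2", "M2", "G2", "DOWN")])

    def test_no_orphan_edges_after_triplet_removal(self, rng):
        """Rebuilding from a triplet subset never leaves an edge without
        provenance (validated on every build)."""
        triplets = [_triplet(f"L{rng.integers(6)}", f"M{rng.integers(6)}", f"G{rng.integers(6)}")
                    for _ in range(20)]
        triplets = list({t.key(): t for t in triplets}.values())
        for _ in range(5):
            keep = [t for t in triplets if rng.random() < 0.5]
            net = build_network(keep, stratum="UP")  # validate() runs inside
            covered = set()
            for t in keep:
                covered.add(frozenset((f"lncRNA:{t.lncrna_id}", f"miRNA:{t.mirna_id}")))
                covered.add(frozenset((f"miRNA:{t.mirna_id}", f"mRNA:{t.mrna_id}")))
            for u, v in net.graph.edges:
                assert frozenset((u, v)) in covered


class TestDegreesAndHubs:
    def test_single_triplet_degrees(self):
        deg = node_degrees(build_network([_triplet("L1", "M1", "G1")]))
        assert deg["lncRNA:L1"] == 1
        assert deg["miRNA:M1"] == 2
        assert deg["mRNA:G1"] == 1

    def test_star_mirna_degree(self):
        k = 7
        triplets = [_triplet("L1", "M1", f"G{i}") for i in range(k)]
        deg = node_degrees(build_network(triplets))
        assert deg["miRNA:M1"] == k + 1

    def test_empty_network_degrees(self):
        assert node_degrees(build_network([], stratum="UP")).empty

    def test_degree_sum_is_twice_edge_count(self, rng):
        for _ in range(10):
            triplets = list({t.key(): t for t in
                             (_triplet(f"L{rng.integers(10)}", f"M{rng.integers(10)}",
                                       f"G{rng.integers(10)}") for _ in range(25))}.values())
            net = build_network(triplets, stratum="UP")
            assert int(node_degrees(net).sum()) == 2 * net.n_edges

    def test_degree_exactly_eight_is_not_a_hub(self):
        """'Exceeding 8' is strict: a lncRNA of degree 8 is excluded."""
        triplets = [_triplet("L1", f"M{i}", f"G{i}") for i in range(8)]
        net = build_network(triplets)
        assert node_degrees(net)["lncRNA:L1"] == 8
        assert extract_hub_subnetwork(net, 8).n_edges == 0

    def test_degree_nine_is_a_hub_with_partners(self):
        triplets = [_triplet("L1", f"M{i}", f"G{i}") for i in range(9)]
        triplets += [_triplet("L2", "M0", "G0")]
        net = build_network(triplets)
        hub = extract_hub_subnetwork(net, 8)
        assert hub.nodes_of_class("lncRNA") == {"L1"}
        assert hub.nodes_of_class("miRNA") == {f"M{i}" for i in range(9)}
        assert len(hub.triplets) == 9

    def test_hub_extraction_matches_filter_and_induce_oracle(self, rng):
        for _ in range(10):
            triplets = list({t.key(): t for t in
                             (_triplet(f"L{rng.integers(4)}", f"M{rng.integers(12)}",
                                       f"G{rng.integers(12)}") for _ in range(60))}.values())
            net = build_network(triplets, stratum="UP")
            threshold = int(rng.integers(2, 10))
            hub = extract_hub_subnetwork(net, threshold)
            assert {t.key() for t in hub.triplets} == hub_oracle(triplets, threshold)


class TestGenesetSubnetwork:
    OSTEO_GENES = {"SMAD6", "ALPL", "COL6A1", "SEMA7A", "COL1A1",
                   "BMP6", "SNAI2", "FBN2", "IGFBP5"}

    def test_term_genes_select_their_triplets(self):
        """Only triplets whose mRNA belongs to the gene set survive."""
        triplets = [_triplet("L1", "M1", "SMAD6"), _triplet("L1", "M1", "OTHER"),
                    _triplet("L2", "M2", "ALPL")]
        net = build_network(triplets)
        sub = extract_geneset_subnetwork(net, self.OSTEO_GENES)
        assert {t.mrna_id for t in sub.triplets} == {"SMAD6", "ALPL"}
        assert "mRNA:OTHER" not in sub.graph.nodes

    def test_disjoint_gene_set_gives_empty_network(self):
        net = build_network([_triplet("L1", "M1", "G1")])
        sub = extract_geneset_subnetwork(net, {"X", "Y"})
        assert sub.n_edges == 0

    def test_full_gene_set_is_identity(self):
        triplets = [_triplet("L1", "M1", "G1"), _triplet("L2", "M2", "G2")]
        net = build_network(triplets)
        sub = extract_geneset_subnetwork(net, {"G1", "G2"})
        assert {t.key() for t in sub.triplets} == {t.key() for t in net.triplets}
        assert set(sub.graph.nodes) == set(net.graph.nodes)

    def test_empty_gene_set_rejected(self):
        net = build_network([_triplet("L1", "M1", "G1")])
        with pytest.raises(ValidationError):
            extract_geneset_subnetwork(net, set())
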