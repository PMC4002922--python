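"""Margin-rule hit selection and similarity-network construction."""

import numpy as np
import pytest

from viromekit import contigs as ctg
from viromekit import fixtures as fx
from viromekit import network as net
from viromekit.errors import MappingError, UsageError

from conftest import make_hit


class TestMarginRule:
    def test_worked_example_keeps_three(self):
        hits = [make_hit(subject=f"s{i}", bit=b)
                for i, b in enumerate([100.0, 95.0, 90.0, 89.9])]
        kept = net.select_margin_hits(hits)
        assert sorted(h.bit_score for h in kept) == [90.0, 95.0, 100.0]

    def test_single_hit_is_its_own_best(self):
        hits = [make_hit(bit=42.0)]
        assert net.select_margin_hits(hits) == hits

    def test_evalue_screen_applies_before_margin(self):
        hits = [make_hit(subject="pass", bit=50.0, evalue=1e-5),
                make_hit(subject="fail", bit=100.0, evalue=0.01)]
        kept = net.select_margin_hits(hits)
        assert [h.subject_id for h in kept] == ["pass"]

    def test_empty_input(self):
        assert net.select_margin_hits([]) == []

    def test_matches_brute_force_on_random_hit_sets(self):
        """1,000 random ORF hit sets: the margin selection equals an
        independent brute-force recomputation, and always contains the
        best hit."""
        rng = np.random.default_rng(23)
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            hits = [make_hit(subject=f"s{j}",
                             bit=float(np.round(rng.uniform(20, 200), 2)),
                             evalue=float(10 ** rng.uniform(-60, 0)))
                    for j in range(n)]
            kept = net.select_margin_hits(hits, 1e-3, 0.10)
            # oracle: direct filter expression
            passing = [h for h in hits if h.evalue <= 1e-3]
            if not passing:
                assert kept == []
                continue
            best = max(h.bit_score for h in passing)
            expected = [h for h in passing if h.bit_score >= 0.9 * best]
            assert kept == expected
            assert any(h.bit_score == best for h in kept)


@pytest.fixture(scope="module")
def network_world(contig_fixture):
    """Predicted ORFs plus derived hits for the contig fixture (two
    contigs per reference, so contig pairs share reference proteins)."""
    _, taxonomy, _, virome, truth = contig_fixture
    orfs_by = {}
    lengths = {}
    for record in virome:
        contig = ctg.detect_and_trim_circular(record, k=10)
        orfs_by[record.id] = ctg.predict_orfs(contig, 120)
        lengths[record.id] = contig.trimmed_length
    hits, pmap = fx.derive_orf_hit_table(truth, orfs_by)
    orf_to_contig = {o.id: o.contig_id for orfs in orfs_by.values() for o in orfs}
    return taxonomy, truth, hits, pmap, orf_to_contig, lengths


class TestBuildNetwork:
    def test_mode_semantics_on_toy_input(self):
        hits = [make_hit(query="cA_1", subject="G1p1", bit=100.0),
                make_hit(query="cA_2", subject="G1p2", bit=80.0)]
        o2c = {"cA_1": "cA", "cA_2": "cA"}
        pmap = {"G1p1": "G1", "G1p2": "G1"}
        agg = net.build_network(hits, o2c, pmap, mode="aggregated")
        assert len(agg.edges) == 1
        assert agg.edges[0].shared_gene_count == 2
        per = net.build_network(hits, o2c, pmap, mode="per_orf")
        assert len(per.edges) == 2
        assert all(e.orf_id and e.bit_score for e in per.edges)

    def test_self_similarity_dropped(self):
        hits = [make_hit(query="cA_1", subject="cA_2", bit=100.0)]
        o2c = {"cA_1": "cA", "cA_2": "cA"}
        network = net.build_network(hits, o2c, {}, mode="aggregated")
        assert network.edges == [] and network.nodes == []

    def test_unresolvable_subject_raises(self):
        with pytest.raises(MappingError):
            net.build_network([make_hit(query="cA_1", subject="mystery")],
                              {"cA_1": "cA"}, {})

    def test_contigs_from_same_reference_connect_to_it(self, network_world):
        taxonomy, truth, hits, pmap, o2c, lengths = network_world
        network = net.build_network(hits, o2c, pmap, taxonomy,
                                    mode="aggregated", contig_lengths=lengths)
        node_ids = network.node_ids()
        neighbors = {n: set() for n in node_ids}
        for e in network.edges:
            neighbors[e.node_a].add(e.node_b)
            neighbors[e.node_b].add(e.node_a)
        by_source: dict[str, list[str]] = {}
        for contig_id, t in truth.entries.items():
            by_source.setdefault(t.source_ref, []).append(contig_id)
        for source, contig_ids in by_source.items():
            assert source in node_ids
            for contig_id in contig_ids:
                assert source in neighbors[contig_id]
        # sibling contigs also share genes directly
        for source, (a, b) in by_source.items():
            assert b in neighbors[a]

    def test_reference_nodes_carry_family_taxonomy(self, network_world):
        taxonomy, _, hits, pmap, o2c, lengths = network_world
        network = net.build_network(hits, o2c, pmap, taxonomy, mode="aggregated")
        for node in network.nodes:
            if node.kind == "reference":
                assert node.taxonomy == taxonomy.family(node.id)

    def test_aggregated_edges_never_exceed_per_orf(self, network_world):
        taxonomy, _, hits, pmap, o2c, _ = network_world
        agg = net.build_network(hits, o2c, pmap, taxonomy, mode="aggregated")
        per = net.build_network(hits, o2c, pmap, taxonomy, mode="per_orf")
        assert len(agg.edges) <= len(per.edges)
        assert agg.node_ids() == per.node_ids()


class TestFilterNetwork:
    def _network(self):
        hits = [make_hit(query="cA_1", subject="G1p1", bit=100.0),
                make_hit(query="cA_2", subject="G1p2", bit=90.0),
                make_hit(query="cB_1", subject="G1p1", bit=95.0)]
        o2c = {"cA_1": "cA", "cA_2": "cA", "cB_1": "cB"}
        pmap = {"G1p1": "G1", "G1p2": "G1"}
        return net.build_network(hits, o2c, pmap, mode="aggregated")

    def test_min_shared_genes_two_drops_single_gene_links(self):
        filtered = net.filter_network(self._network(), min_shared_genes=2)
        assert [(e.node_a, e.node_b, e.shared_gene_count)
                for e in filtered.edges] == [("G1", "cA", 2)]
        assert filtered.node_ids() == {"G1", "cA"}  # cB orphaned, removed

    def test_min_shared_genes_one_is_identity(self):
        network = self._network()
        filtered = net.filter_network(network, min_shared_genes=1)
        assert filtered.edges == network.edges
        assert filtered.nodes == network.nodes

    def test_max_nodes_bound(self):
        filtered = net.filter_network(self._network(), max_nodes=2)
        assert len(filtered.nodes) <= 2

    def test_filters_are_monotone_in_min_shared_genes(self):
        network = self._network()
        e1 = len(net.filter_network(network, min_shared_genes=1).edges)
        e2 = len(net.filter_network(network, min_shared_genes=2).edges)
        e3 = len(net.filter_network(network, min_shared_genes=3).edges)
        assert e1 >= e2 >= e3

    def test_shared_gene_filter_on_per_orf_network_rejected(self):
        per = net.build_network([make_hit(query="cA_1", subject="G1p1")],
                                {"cA_1": "cA"}, {"G1p1": "G1"}, mode="per_orf")
        with pytest.raises(UsageError):
            net.filter_network(per, min_shared_genes=2)

    def test_taxa_keep_restricts_reference_nodes(self, network_world):
        taxonomy, _, hits, pmap, o2c, _ = network_world
        network = net.build_network(hits, o2c, pmap, taxonomy, mode="aggregated")
        families = sorted({n.taxonomy for n in network.nodes
                           if n.kind == "reference"})
        assert len(families) >= 2
        filtered = net.filter_network(network, taxa_keep=[families[0]])
        kept = {n.taxonomy for n in filtered.nodes if n.kind == "reference"}
        assert kept == {families[0]}


def test_map_comparison_rows_ordered_by_coordinate(network_world):
    taxonomy, truth, hits, pmap, o2c, _ = network_world
    contig_id = sorted(o2c.values())[0]
    source = truth.entries[contig_id].source_ref
    orf_starts = {}
    rows = net.map_comparison_table(hits, o2c, pmap, contig_id, source,
                                    orf_starts)
    assert rows and all(r[1].startswith(source) for r in rows)
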