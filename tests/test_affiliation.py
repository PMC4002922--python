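"""Best hits, compositions and contig LCA calls."""

import numpy as np
import pytest

from viromekit import affiliation as aff
from viromekit import fixtures as fx
from viromekit.errors import DataError, UsageError
from viromekit.records import Hit, Lineage, TaxonomyTable

from conftest import make_hit


class TestBestHit:
    def test_highest_bit_score_wins(self):
        hits = [make_hit(bit=350.0, subject="a"), make_hit(bit=90.0, subject="b")]
        assert aff.best_hit(hits).subject_id == "a"

    def test_evalue_threshold_discards(self):
        assert aff.best_hit([make_hit(evalue=0.01)]) is None

    def test_threshold_is_inclusive(self):
        assert aff.best_hit([make_hit(evalue=1e-3)]) is not None

    def test_tie_break_by_evalue(self):
        hits = [make_hit(bit=100.0, evalue=1e-5, subject="worse"),
                make_hit(bit=100.0, evalue=1e-10, subject="better")]
        assert aff.best_hit(hits).subject_id == "better"

    def test_tie_break_by_identity_then_subject(self):
        hits = [make_hit(bit=100.0, evalue=1e-5, identity=85.0, subject="zz"),
                make_hit(bit=100.0, evalue=1e-5, identity=95.0, subject="aa"),
                make_hit(bit=100.0, evalue=1e-5, identity=95.0, subject="ab")]
        assert aff.best_hit(hits).subject_id == "aa"

    def test_mixed_queries_rejected(self):
        with pytest.raises(UsageError, match="mixed"):
            aff.best_hit([make_hit(query="q1"), make_hit(query="q2")])


class TestReadComposition:
    def _worked_example(self):
        taxonomy = TaxonomyTable(
            {"small": Lineage.from_string("Viruses;FamS;SpS"),
             "big": Lineage.from_string("Viruses;FamB;SpB")},
            {"small": 10000, "big": 40000},
        )
        best = {}
        for i in range(10):
            best[f"a{i}"] = make_hit(query=f"a{i}", subject="small")
        for i in range(20):
            best[f"b{i}"] = make_hit(query=f"b{i}", subject="big")
        return taxonomy, best

    def test_length_normalized_worked_example(self):
        taxonomy, best = self._worked_example()
        comp = aff.read_composition(best, taxonomy, "length_normalized")
        weights = {path[-1]: w for path, w in comp.weights.items()}
        assert weights["SpS"] == pytest.approx(2 / 3)
        assert weights["SpB"] == pytest.approx(1 / 3)

    def test_raw_mode_worked_example(self):
        taxonomy, best = self._worked_example()
        comp = aff.read_composition(best, taxonomy, "raw_best_hit")
        weights = {path[-1]: w for path, w in comp.weights.items()}
        assert weights["SpS"] == pytest.approx(1 / 3)
        assert weights["SpB"] == pytest.approx(2 / 3)

    def test_unassigned_counts_none_entries(self):
        taxonomy, best = self._worked_example()
        best["miss1"] = None
        best["miss2"] = None
        comp = aff.read_composition(best, taxonomy, "raw_best_hit")
        assert comp.unassigned == pytest.approx(2 / 32)
        assert sum(comp.weights.values()) + comp.unassigned == pytest.approx(1.0)

    def test_missing_genome_length_in_normalized_mode(self):
        taxonomy = TaxonomyTable({"x": Lineage.from_string("Viruses;X")}, {})
        best = {"q": make_hit(subject="x")}
        with pytest.raises(DataError):
            aff.read_composition(best, taxonomy, "length_normalized")

    def test_planted_dominant_family_recovered(self):
        """A virome simulated mostly from one family dominates the raw
        composition at the family rank."""
        refs, taxonomy = fx.generate_reference_set(11, 6, taxonomy_spec=(1, 2, 3))
        families = [taxonomy.family(r.id) for r in refs]
        dominant = families[0]
        counts = {r.id: (60 if taxonomy.family(r.id) == dominant else 5)
                  for r in refs}
        reads, truth = fx.generate_virome(
            11, refs, fx.ViromeParams(counts=counts, fragment_length=200, mu=0.02))
        hits = fx.derive_hit_table(truth, taxonomy, decoy_rate=0.0, seed=11)
        best = aff.best_hits_by_query(hits, all_query_ids=[r.id for r in reads])
        comp = aff.read_composition(best, taxonomy, "raw_best_hit")
        by_family: dict[str, float] = {}
        for path, w in comp.weights.items():
            by_family[path[2]] = by_family.get(path[2], 0.0) + w
        assert max(by_family, key=by_family.get) == dominant


class TestContigAffiliation:
    def test_lca_across_families(self, small_taxonomy):
        hits = [make_hit(query="o1", subject="myo1", bit=300.0),
                make_hit(query="o2", subject="sipho1", bit=280.0)]
        call = aff.contig_affiliation(hits, small_taxonomy, "lca")
        assert call.lineage.ranks == ("Viruses", "Caudovirales")
        assert call.level == 1 and call.support == 2

    def test_single_gene_full_lineage(self, small_taxonomy):
        call = aff.contig_affiliation([make_hit(subject="myo1")],
                                      small_taxonomy, "lca")
        assert call.lineage == small_taxonomy.lineage("myo1")

    def test_five_gene_rule_excludes_weak_discordant_genes(self, small_taxonomy):
        hits = [make_hit(query=f"o{i}", subject="myo1", bit=300.0 - i)
                for i in range(5)]
        hits += [make_hit(query=f"w{i}", subject="sipho1", bit=100.0 - i)
                 for i in range(2)]
        call = aff.contig_affiliation(hits, small_taxonomy, "lca")
        assert call.lineage.ranks[-1] == "SpeciesA"
        assert call.support == 5

    def test_best_hit_mode_takes_strongest_gene(self, small_taxonomy):
        hits = [make_hit(query="o1", subject="sipho1", bit=500.0),
                make_hit(query="o2", subject="myo1", bit=300.0)]
        call = aff.contig_affiliation(hits, small_taxonomy, "best_hit")
        assert call.subject_id == "sipho1"

    def test_no_affiliated_genes(self, small_taxonomy):
        assert aff.contig_affiliation([], small_taxonomy, "lca") is None

    def test_lca_equals_brute_force_oracle(self):
        """Over 1,000 random contigs with random lineages the LCA call
        equals an independent intersect-all-prefixes oracle."""
        rng = np.random.default_rng(7)
        depth_names = [["Viruses"], ["O1", "O2"], ["F1", "F2", "F3"],
                       ["G1", "G2"], ["S1", "S2", "S3", "S4"]]
        refs = {}
        for i in range(40):
            path = tuple(
                f"{names[rng.integers(0, len(names))]}d{d}"
                if d else "Viruses"
                for d, names in enumerate(depth_names)
            )
            refs[f"r{i}"] = Lineage(path)
        taxonomy = TaxonomyTable(refs, {})
        mismatches = 0
        for case in range(1000):
            n_genes = int(rng.integers(1, 9))
            hits = [
                make_hit(query=f"g{j}", subject=f"r{rng.integers(0, 40)}",
                         bit=float(rng.integers(50, 500)),
                         evalue=float(10.0 ** -int(rng.integers(4, 50))))
                for j in range(n_genes)
            ]
            call = aff.contig_affiliation(hits, taxonomy, "lca")
            # oracle: sort as the implementation declares, intersect the
            # full lineage prefixes of the top five positionwise
            ranked = sorted(hits, key=lambda h: (-h.bit_score, h.evalue,
                                                 -h.percent_identity,
                                                 h.subject_id, h.query_id))[:5]
            lineages = [taxonomy.lineage(h.subject_id).ranks for h in ranked]
            prefix = []
            for ranks in zip(*lineages):
                if len(set(ranks)) != 1:
                    break
                prefix.append(ranks[0])
            expected = tuple(prefix)
            got = () if call.lineage is None else call.lineage.ranks
            if got != expected:
                mismatches += 1
        assert mismatches == 0

    def test_lca_depth_monotone_under_discordance(self, small_taxonomy):
        """Adding a discordant gene into the top-5 set can only keep or
        shallow the LCA, never deepen it."""
        hits = [make_hit(query=f"o{i}", subject="myo1", bit=300.0 - i)
                for i in range(3)]
        depth0 = aff.contig_affiliation(hits, small_taxonomy, "lca").level
        hits.append(make_hit(query="d1", subject="myo2", bit=290.0))
        depth1 = aff.contig_affiliation(hits, small_taxonomy, "lca").level
        hits.append(make_hit(query="d2", subject="micro1", bit=295.0))
        depth2 = aff.contig_affiliation(hits, small_taxonomy, "lca").level
        assert depth0 >= depth1 >= depth2

    def test_planted_contigs_affiliate_within_source_lineage(self, contig_fixture):
        _, taxonomy, _, virome, truth = contig_fixture
        import dataclasses

        from viromekit import contigs as ctg

        orfs_by = {}
        for record in virome:
            contig = ctg.detect_and_trim_circular(record, k=10)
            orfs_by[record.id] = ctg.predict_orfs(contig, 120)
        hits, pmap = fx.derive_orf_hit_table(truth, orfs_by,
                                             include_contig_links=False)
        genome_hits = [dataclasses.replace(h, subject_id=pmap[h.subject_id])
                       for h in hits]
        best = aff.best_hits_by_query(genome_hits)
        for record in virome:
            per_contig = [best[o.id] for o in orfs_by[record.id]
                          if best.get(o.id) is not None]
            source_lineage = taxonomy.lineage(truth.entries[record.id].source_ref)
            for mode in ("best_hit", "lca"):
                call = aff.contig_affiliation(per_contig, taxonomy, mode)
                assert call is not None
                depth = len(call.lineage)
                assert call.lineage.ranks == source_lineage.ranks[:depth]


class TestCompositionTable:
    def test_parent_rows_sum_children(self, small_taxonomy):
        best = {f"q{i}": make_hit(query=f"q{i}", subject=s)
                for i, s in enumerate(["myo1", "myo1", "myo2", "sipho1"])}
        comp = aff.read_composition(best, small_taxonomy, "raw_best_hit", "v1")
        table = aff.composition_table([comp])
        fam = table.loc["Viruses;Caudovirales;Myoviridae", "v1"]
        children = [
            table.loc["Viruses;Caudovirales;Myoviridae;SpeciesA", "v1"],
            table.loc["Viruses;Caudovirales;Myoviridae;SpeciesB", "v1"],
        ]
        assert fam == pytest.approx(sum(children))
        assert table.loc["Viruses", "v1"] == pytest.approx(1.0 - comp.unassigned)

    def test_column_order_follows_input(self, small_taxonomy):
        best = {"q": make_hit(query="q", subject="myo1")}
        c1 = aff.read_composition(best, small_taxonomy, "raw_best_hit", "b")
        c2 = aff.read_composition(best, small_taxonomy, "raw_best_hit", "a")
        assert list(aff.composition_table([c1, c2]).columns) == ["b", "a"]

    def test_affiliation_composition_mixed_depths(self, small_taxonomy):
        calls = {
            "c1": aff.Affiliation(None, Lineage.from_string("Viruses;Caudovirales"),
                                  1, 3),
            "c2": aff.Affiliation("myo1", small_taxonomy.lineage("myo1"), 3, 1),
            "c3": None,
        }
        comp = aff.affiliation_composition(calls, "contig_lca", "v")
        assert comp.unassigned == pytest.approx(1 / 3)
        table = aff.composition_table([comp])
        assert table.loc["Viruses;Caudovirales", "v"] == pytest.approx(2 / 3)
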