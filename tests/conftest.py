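import pytest

from viromekit import fixtures as fx
from viromekit.records import Hit, Lineage, TaxonomyTable


@pytest.fixture(scope="session")
def small_taxonomy() -> TaxonomyTable:
    """Two caudoviral families plus an outgroup, with genome lengths."""
    lineages = {
        "myo1": "Viruses;Caudovirales;Myoviridae;SpeciesA",
        "myo2": "Viruses;Caudovirales;Myoviridae;SpeciesB",
        "sipho1": "Viruses;Caudovirales;Siphoviridae;SpeciesC",
        "micro1": "Viruses;Petitvirales;Microviridae;SpeciesD",
    }
    return TaxonomyTable(
        entries={k: Lineage.from_string(v) for k, v in lineages.items()},
        genome_lengths={"myo1": 50000, "myo2": 48000, "sipho1": 60000,
                        "micro1": 5000},
    )


def make_hit(query="q1", subject="s1", identity=90.0, length=100, evalue=1e-10,
             bit=200.0, s_start=1, s_end=100, mismatches=0):
    return Hit(query, subject, identity, length, mismatches, 0, 1, length,
               s_start, s_end, evalue, bit)


@pytest.fixture(scope="session")
def contig_fixture():
    """Gene-bearing references and a contig-mode virome: half circular
    (rotated into a gene, 10-nt terminal duplication), half linear."""
    refs, taxonomy, gene_maps = fx.generate_annotated_references(29, 6)
    virome, truth = fx.generate_virome(
        30, refs,
        fx.ViromeParams(mode="contigs", counts={r.id: 2 for r in refs},
                        circular_fraction=0.5, rotate_into_gene=True),
        gene_maps=gene_maps,
    )
    return refs, taxonomy, gene_maps, virome, truth
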