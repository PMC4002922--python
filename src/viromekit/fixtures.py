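"""Synthetic reference sets, viromes and hit tables with planted truth.

Every downstream module is testable offline against fixtures produced
here: reference genomes with a branching taxonomy, read- or contig-mode
viromes derived from them, and internally consistent similarity tables
whose best hit points back at the true source.

Design constraints the generators observe:

* everything is driven by explicit seeds; identical parameters give
  byte-identical output;
* mutations are substitutions only, so percent identity is exact
  arithmetic (``100 * (1 - mutations/length)``) and downstream oracles
  stay closed-form;
* the bit-score surrogate (``2 * matched bases``) is arbitrary but
  monotone in match count, which is all the downstream ordering and
  margin rules depend on;
* abundance profiles are exact counts, not multinomial draws.

Gene-bearing genomes are built as cassettes ``spacer gene spacer ...``
where spacers are runs of TAA codons: frame 0 then contains stop codons
everywhere outside genes and no start codons inside spacers, so the
naive ORF finder recovers every planted gene with exact protein
equality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError, UsageError
from .records import Hit, DomainHit, Lineage, SequenceRecord, TaxonomyTable

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
_RANK_LABELS = ("Order", "Family", "Genus", "Subgenus")


# ---------------------------------------------------------------------------
# Planted truth containers


@dataclass(frozen=True)
class PlantedGene:
    """A gene planted on a simulated contig (stop codon included in the
    interval; ``wraps`` when the gene spans the origin after rotation)."""

    start: int
    end: int
    strand: str
    protein: str
    wraps: bool = False
    source_ref: str = ""
    gene_index: int = -1


@dataclass(frozen=True)
class TruthRecord:
    """Provenance of one simulated sequence."""

    source_ref: str
    start: int          # 0-based half-open interval on the source genome
    end: int
    strand: str
    n_mutations: int
    circular: bool = False
    rotation: int = 0
    emitted_length: int = 0
    genes: tuple[PlantedGene, ...] = ()


@dataclass
class PlantedTruth:
    """Planted ground truth for a simulated virome."""

    entries: dict[str, TruthRecord] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {k: asdict(v) for k, v in self.entries.items()}, indent=1, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        raw = json.loads(text)
        entries = {}
        for k, v in raw.items():
            genes = tuple(PlantedGene(**g) for g in v.pop("genes", ()))
            entries[k] = TruthRecord(genes=genes, **v)
        return cls(entries)


# ---------------------------------------------------------------------------
# Reference sets


def _lineage_names(taxonomy_spec: Sequence[int]) -> list[tuple[str, ...]]:
    """Enumerate leaf lineages for branching counts per rank (root
    ``Viruses`` is implicit; the last rank becomes species names later)."""
    paths: list[tuple[str, ...]] = [("Viruses",)]
    for depth, count in enumerate(taxonomy_spec[:-1]):
        label = _RANK_LABELS[depth] if depth < len(_RANK_LABELS) else f"Rank{depth}"
        paths = [
            path + (f"{label}_{'.'.join(path[1:] + (str(i + 1),))}",)
            for path in paths
            for i in range(count)
        ]
    leaves = []
    for path in paths:
        for i in range(taxonomy_spec[-1]):
            leaves.append(path)
    return leaves


def _random_sequence(rng: np.random.Generator, length: int,
                     probs: Sequence[float] | None = None) -> str:
    draw = rng.choice(4, size=length, p=probs)
    return _BASES[draw].tobytes().decode()


def generate_reference_set(
    seed: int,
    n_genomes: int,
    length_range: tuple[int, int] = (5000, 5000),
    taxonomy_spec: Sequence[int] = (1, 2, 3),
    family_bias: float = 0.0,
) -> tuple[list[SequenceRecord], TaxonomyTable]:
    """Generate random reference genomes under a branching taxonomy.

    ``taxonomy_spec`` gives branching counts per rank below the root,
    e.g. ``(1, 2, 3)`` = one order, two families each, three species per
    family; the product must equal ``n_genomes``. Residues are uniform
    i.i.d. unless ``family_bias > 0``, in which case each family draws
    its own base composition (Dirichlet around uniform, concentration
    ``1/family_bias``), giving families a recoverable k-mer signature.
    """
    expected = int(np.prod(taxonomy_spec))
    if expected != n_genomes:
        raise DataError(
            f"taxonomy_spec {tuple(taxonomy_spec)} yields {expected} species, "
            f"but n_genomes={n_genomes}"
        )
    if n_genomes < 1:
        raise DataError("n_genomes must be >= 1")
    rng = np.random.default_rng(seed)
    paths = _lineage_names(taxonomy_spec)
    family_probs: dict[tuple[str, ...], np.ndarray] = {}
    records, entries, lengths = [], {}, {}
    for i, path in enumerate(paths):
        ref_id = f"ref{i + 1:03d}"
        species = f"Species_{ref_id}"
        entries[ref_id] = Lineage(path + (species,))
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        probs = None
        if family_bias > 0:
            if path not in family_probs:
                family_probs[path] = rng.dirichlet([1.0 / family_bias] * 4)
            probs = family_probs[path]
        records.append(SequenceRecord(ref_id, _random_sequence(rng, length, probs),
                                      description=species))
        lengths[ref_id] = length
    return records, TaxonomyTable(entries=entries, genome_lengths=lengths)


def _make_gene(rng: np.random.Generator, aa_length: int) -> tuple[str, str]:
    """Build one gene of ``aa_length`` amino acids (nt = 3*(aa+1) with
    the stop); returns (nucleotides, protein)."""
    codon_idx = rng.integers(0, len(_NONSTOP_CODONS), size=aa_length - 1)
    codons = ["ATG"] + [_NONSTOP_CODONS[j] for j in codon_idx]
    stop = _STOPS[int(rng.integers(0, 3))]
    nt = "".join(codons) + stop
    from Bio.Seq import Seq

    protein = str(Seq(nt[:-3]).translate(table=11))
    return nt, protein


def generate_annotated_references(
    seed: int,
    n_genomes: int,
    taxonomy_spec: Sequence[int] = (1, 2, 3),
    genes_per_genome: int = 5,
    gene_aa_range: tuple[int, int] = (60, 150),
    spacer_codon_range: tuple[int, int] = (5, 15),
) -> tuple[list[SequenceRecord], TaxonomyTable, dict[str, tuple[PlantedGene, ...]]]:
    """Generate gene-bearing reference genomes with a known gene map.

    Genomes are cassettes of planted genes separated by all-TAA spacers
    (see module docstring), so the naive ORF finder recovers each gene
    exactly. Returns the gene map keyed by reference id; planted gene
    intervals include the stop codon.
    """
    expected = int(np.prod(taxonomy_spec))
    if expected != n_genomes:
        raise DataError(
            f"taxonomy_spec {tuple(taxonomy_spec)} yields {expected} species, "
            f"but n_genomes={n_genomes}"
        )
    rng = np.random.default_rng(seed)
    paths = _lineage_names(taxonomy_spec)
    records, entries, lengths = [], {}, {}
    gene_maps: dict[str, tuple[PlantedGene, ...]] = {}
    for i, path in enumerate(paths):
        ref_id = f"ref{i + 1:03d}"
        entries[ref_id] = Lineage(path + (f"Species_{ref_id}",))
        # leading spacer uses TGA so a linear genome's two ends (leading
        # vs trailing spacer) can never look like a terminal repeat
        parts = ["TGA" * int(rng.integers(*spacer_codon_range))]
        genes = []
        pos = len(parts[0])
        for g in range(genes_per_genome):
            aa = int(rng.integers(gene_aa_range[0], gene_aa_range[1] + 1))
            nt, protein = _make_gene(rng, aa)
            genes.append(
                PlantedGene(pos, pos + len(nt), "+", protein,
                            source_ref=ref_id, gene_index=g)
            )
            parts.append(nt)
            pos += len(nt)
            spacer = "TAA" * int(rng.integers(*spacer_codon_range))
            parts.append(spacer)
            pos += len(spacer)
        seq = "".join(parts)
        records.append(SequenceRecord(ref_id, seq))
        lengths[ref_id] = len(seq)
        gene_maps[ref_id] = tuple(genes)
    return records, TaxonomyTable(entries=entries, genome_lengths=lengths), gene_maps


# ---------------------------------------------------------------------------
# Viromes


@dataclass(frozen=True)
class ViromeParams:
    """Parameters of a simulated virome.

    ``counts`` maps reference id to the exact number of sequences drawn
    from it. ``fragment_length`` is either an int or an inclusive range.
    ``mu`` is the per-base substitution rate. In contig mode a fraction
    ``circular_fraction`` of contigs are random rotations of the full
    genome with their first ``terminal_duplication_k`` bases appended at
    the end; ``rotate_into_gene`` places the rotation point inside a
    planted gene so the gene spans the origin.
    """

    mode: str = "reads"
    counts: Mapping[str, int] = field(default_factory=dict)
    fragment_length: int | tuple[int, int] = 300
    mu: float = 0.0
    circular_fraction: float = 0.0
    terminal_duplication_k: int = 10
    rotate_into_gene: bool = False
    minus_strand_fraction: float = 0.0


def _mutate(rng: np.random.Generator, seq: str, mu: float) -> tuple[str, int]:
    if mu <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < mu)[0]
    for i in hit:
        current = arr[i]
        options = [b for b in (b"A", b"C", b"G", b"T") if b != current]
        arr[i] = options[int(rng.integers(0, 3))]
    return arr.tobytes().decode(), int(hit.size)


def generate_virome(
    seed: int,
    references: Sequence[SequenceRecord],
    params: ViromeParams,
    gene_maps: Mapping[str, Sequence[PlantedGene]] | None = None,
    virome_id: str = "virome",
) -> tuple[list[SequenceRecord], PlantedTruth]:
    """Simulate a virome (reads or contigs) from reference genomes.

    Reads are mutated sub-fragments. Circular contigs are rotations of a
    full genome with a ``terminal_duplication_k``-nt terminal repeat;
    linear contigs are the full genome unrotated. When ``gene_maps`` is
    given, planted genes are carried onto each contig with rotated
    coordinates and recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    by_id = {r.id: r for r in references}
    records: list[SequenceRecord] = []
    truth = PlantedTruth()
    n = 0
    for ref_id in params.counts:
        if ref_id not in by_id:
            raise DataError(f"abundance profile names unknown reference {ref_id}")
    for ref_id, count in params.counts.items():
        genome = by_id[ref_id].residues
        length = len(genome)
        for _ in range(count):
            n += 1
            seq_id = f"{virome_id}_s{n:05d}"
            if params.mode == "reads":
                frag = params.fragment_length
                if not isinstance(frag, int):
                    frag = int(rng.integers(frag[0], frag[1] + 1))
                if frag > length:
                    raise DataError(
                        f"fragment length {frag} exceeds genome {ref_id} ({length} nt)"
                    )
                start = int(rng.integers(0, length - frag + 1))
                sub = genome[start:start + frag]
                strand = "+"
                if rng.random() < params.minus_strand_fraction:
                    strand = "-"
                    from Bio.Seq import Seq

                    sub = str(Seq(sub).reverse_complement())
                mutated, n_mut = _mutate(rng, sub, params.mu)
                records.append(SequenceRecord(seq_id, mutated))
                truth.entries[seq_id] = TruthRecord(
                    ref_id, start, start + frag, strand, n_mut,
                    emitted_length=frag,
                )
            elif params.mode == "contigs":
                circular = rng.random() < params.circular_fraction
                genes_src = tuple(gene_maps.get(ref_id, ())) if gene_maps else ()
                if circular:
                    if params.rotate_into_gene and genes_src:
                        gene = genes_src[int(rng.integers(0, len(genes_src)))]
                        span = gene.end - gene.start
                        r = (gene.start + span // 2) % length
                    else:
                        r = int(rng.integers(0, length))
                    rotated = genome[r:] + genome[:r]
                    k = params.terminal_duplication_k
                    emitted = rotated + rotated[:k]
                    genes = tuple(
                        PlantedGene(
                            (g.start - r) % length,
                            (g.end - r) % length or length,
                            g.strand, g.protein,
                            wraps=(g.start - r) % length + (g.end - g.start) > length,
                            source_ref=ref_id, gene_index=g.gene_index,
                        )
                        for g in genes_src
                    )
                    mutated, n_mut = _mutate(rng, emitted, params.mu)
                    records.append(SequenceRecord(seq_id, mutated))
                    truth.entries[seq_id] = TruthRecord(
                        ref_id, 0, length, "+", n_mut, circular=True,
                        rotation=r, emitted_length=len(emitted), genes=genes,
                    )
                else:
                    mutated, n_mut = _mutate(rng, genome, params.mu)
                    records.append(SequenceRecord(seq_id, mutated))
                    truth.entries[seq_id] = TruthRecord(
                        ref_id, 0, length, "+", n_mut,
                        emitted_length=length, genes=genes_src,
                    )
            else:
                raise UsageError(f"unknown virome mode: {params.mode!r}")
    return records, truth


# ---------------------------------------------------------------------------
# Derived hit tables

_EVALUE_FLOOR = 1e-180
_EVALUE_CEIL = 10.0


def _score_to_evalue(bit_score: float) -> float:
    return float(min(_EVALUE_CEIL, max(_EVALUE_FLOOR, 10 ** (-bit_score / 10))))


def derive_hit_table(
    truth: PlantedTruth,
    taxonomy: TaxonomyTable,
    decoy_rate: float = 0.0,
    seed: int = 0,
) -> list[Hit]:
    """Derive a consistent per-sequence hit table from planted truth.

    Each sequence gets one true hit against its source reference with
    ``percent_identity = 100*(1 - mutations/length)``, subject
    coordinates equal to the planted interval (1-based, reversed for
    minus-strand placements), ``bit_score = 2 * matched bases`` and
    ``evalue = 10^(-bit/10)`` capped to ``[1e-180, 10]``. With
    ``decoy_rate > 0`` some sequences also get a decoy hit against a
    random other reference at a strictly lower bit-score.
    """
    rng = np.random.default_rng(seed)
    refs = sorted(taxonomy.entries)
    hits: list[Hit] = []
    for seq_id in sorted(truth.entries):
        rec = truth.entries[seq_id]
        length = rec.emitted_length or (rec.end - rec.start)
        matched = length - rec.n_mutations
        identity = round(100.0 * matched / length, 4)
        bit = 2.0 * matched
        if rec.strand == "-":
            s_start, s_end = rec.end, rec.start + 1
        else:
            s_start, s_end = rec.start + 1, rec.end
        hits.append(
            Hit(seq_id, rec.source_ref, identity, length, rec.n_mutations, 0,
                1, length, s_start, s_end, _score_to_evalue(bit), bit)
        )
        if decoy_rate > 0 and len(refs) > 1 and rng.random() < decoy_rate:
            others = [r for r in refs if r != rec.source_ref]
            decoy_ref = others[int(rng.integers(0, len(others)))]
            frac = float(rng.uniform(0.3, 0.9))
            decoy_bit = bit * frac
            decoy_len = max(10, int(length * frac))
            decoy_mis = max(1, int(decoy_len * 0.25))
            ref_len = taxonomy.length(decoy_ref)
            span = min(decoy_len, ref_len)
            s0 = int(rng.integers(0, max(1, ref_len - span + 1)))
            hits.append(
                Hit(seq_id, decoy_ref,
                    round(100.0 * (decoy_len - decoy_mis) / decoy_len, 4),
                    decoy_len, decoy_mis, 0, 1, decoy_len, s0 + 1, s0 + span,
                    _score_to_evalue(decoy_bit), decoy_bit)
            )
    return hits


def derive_orf_hit_table(
    truth: PlantedTruth,
    orfs_by_contig: Mapping[str, Sequence],
    include_contig_links: bool = True,
) -> tuple[list[Hit], dict[str, str]]:
    """Derive per-ORF hits from planted genes on contig-mode fixtures.

    A predicted ORF matches a planted gene when start, end (modulo
    wrapping) and strand coincide. Matched ORFs hit the source
    reference's protein (subject id ``ref:gN``); with
    ``include_contig_links`` they additionally hit every other contig
    ORF matched to the same reference protein, which is what gives
    contig-contig edges in similarity networks. Returns the hit list
    and the protein-to-genome mapping for the reference subjects.
    """
    protein_to_genome: dict[str, str] = {}
    matched: dict[str, list] = {}  # protein subject -> [(orf, aa_len)]
    hits: list[Hit] = []
    for contig_id in sorted(orfs_by_contig):
        rec = truth.entries.get(contig_id)
        if rec is None:
            raise DataError(f"no planted truth for contig {contig_id}")
        gene_index = {(g.start, g.end, g.strand): g for g in rec.genes}
        for orf in orfs_by_contig[contig_id]:
            gene = gene_index.get((orf.start, orf.end, orf.strand))
            if gene is None:
                continue
            subject = f"{gene.source_ref}:g{gene.gene_index + 1}"
            protein_to_genome[subject] = gene.source_ref
            aa = len(gene.protein)
            nt_matched = 3 * (aa + 1)
            bit = 2.0 * nt_matched
            hits.append(
                Hit(orf.id, subject, 100.0, aa, 0, 0, 1, aa, 1, aa,
                    _score_to_evalue(bit), bit)
            )
            matched.setdefault(subject, []).append((orf, aa))
    if include_contig_links:
        for subject in sorted(matched):
            group = matched[subject]
            for orf_a, aa in group:
                for orf_b, _ in group:
                    if orf_a.id == orf_b.id:
                        continue
                    bit = 2.0 * 3 * (aa + 1)
                    hits.append(
                        Hit(orf_a.id, orf_b.id, 100.0, aa, 0, 0, 1, aa, 1, aa,
                            _score_to_evalue(bit), bit)
                    )
    return hits, protein_to_genome


def derive_domain_hits(
    truth: PlantedTruth,
    orfs_by_contig: Mapping[str, Sequence],
) -> list[DomainHit]:
    """Assign each gene-matched ORF a synthetic domain per gene family.

    The score grows with protein length (``25 + 0.1 * aa``), so short
    proteins fall below the conventional score-30 cutoff and exercise
    downstream threshold handling.
    """
    hits: list[DomainHit] = []
    for contig_id in sorted(orfs_by_contig):
        rec = truth.entries.get(contig_id)
        if rec is None:
            continue
        gene_index = {(g.start, g.end, g.strand): g for g in rec.genes}
        for orf in orfs_by_contig[contig_id]:
            gene = gene_index.get((orf.start, orf.end, orf.strand))
            if gene is None:
                continue
            aa = len(gene.protein)
            acc = f"PF{gene.gene_index + 1:05d}"
            hits.append(
                DomainHit(orf.id, acc, f"SynthFam{gene.gene_index + 1}",
                          score=round(25.0 + 0.1 * aa, 1),
                          evalue=_score_to_evalue(25.0 + 0.1 * aa))
            )
    return hits


# ---------------------------------------------------------------------------
# Longitudinal k-mer study and bundles


def generate_longitudinal_study(
    seed: int,
    n_subjects: int = 3,
    n_timepoints: int = 3,
    genome_length: int = 100_000,
    within_mu: float = 0.01,
) -> dict[str, list[SequenceRecord]]:
    """Simulate repeated sampling of per-subject viral communities.

    Each subject gets an independent random community sequence; each
    timepoint is a lightly mutated copy (rate ``within_mu``). Viromes
    from the same subject therefore share a k-mer signature that
    ordination should recover as within-subject proximity.
    """
    rng = np.random.default_rng(seed)
    study: dict[str, list[SequenceRecord]] = {}
    for s in range(1, n_subjects + 1):
        base = _random_sequence(rng, genome_length)
        for t in range(1, n_timepoints + 1):
            vid = f"S{s}_d{t}"
            mutated, _ = _mutate(rng, base, within_mu)
            study[vid] = [SequenceRecord(vid, mutated)]
    return study


def write_bundle(
    outdir: str | Path,
    references: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    virome: Sequence[SequenceRecord],
    truth: PlantedTruth,
    hits: Sequence[Hit],
    mode: str = "reads",
    protein_to_genome: Mapping[str, str] | None = None,
    domain_hits: Sequence[DomainHit] | None = None,
) -> Path:
    """Write a fixture bundle directory consumed verbatim by the CLI."""
    from . import io as vio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "refs.fasta").write_text(vio.write_fasta(references))
    name = "contigs.fasta" if mode == "contigs" else "reads.fasta"
    (outdir / name).write_text(vio.write_fasta(virome))
    lin, lens = vio.write_taxonomy(taxonomy)
    (outdir / "lineage.tsv").write_text(lin)
    (outdir / "lengths.tsv").write_text(lens)
    (outdir / "hits.tsv").write_text(vio.write_tabular_hits(hits))
    (outdir / "truth.json").write_text(truth.to_json())
    if protein_to_genome is not None:
        (outdir / "protein_map.tsv").write_text(
            "".join(f"{p}\t{g}\n" for p, g in sorted(protein_to_genome.items()))
        )
    if domain_hits is not None:
        (outdir / "domains.tsv").write_text(vio.write_domain_hits(domain_hits))
    return outdir
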