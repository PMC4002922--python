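"""Readers and writers for every on-disk format the toolkit touches.

FASTA, 12-column tabular similarity hits, per-target protein-domain
tables, lineage/genome-length TSVs, GenBank flat files and network
exports (GraphML, XGMML, CSV). Gzip-compressed text inputs are accepted
transparently. This module is the only place where 1-based inclusive
surface conventions are converted to the 0-based half-open coordinates
used internally.
"""

from __future__ import annotations

import gzip
import io as _stdio
import re
import warnings
from pathlib import Path
from typing import IO, Iterable, Union

import networkx as nx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, CoordinateError, DataError, ParseError, UsageError
from .records import DomainHit, Hit, Lineage, SequenceRecord, TaxonomyTable

Source = Union[str, Path, IO]

_VALID_DNA = re.compile(r"[^ACGTN]")


def _open_text(source: Source):
    """Open ``source`` as a text stream; gzip magic is detected on files."""
    if hasattr(source, "read"):
        return source, False
    path = Path(source)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt"), True
    return open(path, "rt"), True


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source: Source) -> list[SequenceRecord]:
    """Parse a (possibly gzipped) multi-FASTA file of DNA sequences.

    Ids are the first whitespace-delimited header token and must be
    unique. Residues are uppercased; anything outside ``ACGTN`` raises
    :class:`AlphabetError` naming the record and the offending position.
    """
    handle, owned = _open_text(source)
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ParseError(f"duplicate sequence id: {rec.id}")
            seen.add(rec.id)
            residues = str(rec.seq).upper()
            bad = _VALID_DNA.search(residues)
            if bad:
                raise AlphabetError(
                    f"record {rec.id}: invalid character {bad.group()!r} "
                    f"at position {bad.start() + 1}"
                )
            description = rec.description[len(rec.id):].strip()
            records.append(SequenceRecord(rec.id, residues, description))
    finally:
        if owned:
            handle.close()
    if not records:
        raise ParseError("no sequences found (empty input)")
    return records


def write_fasta(records: Iterable[SequenceRecord], width: int = 70) -> str:
    """Render records as FASTA text (fixed line width)."""
    out = []
    for rec in records:
        header = f">{rec.id} {rec.description}".rstrip()
        out.append(header)
        for i in range(0, len(rec.residues), width):
            out.append(rec.residues[i:i + width])
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Tabular similarity hits (12-column dialect)

_HIT_COLUMNS = 12


def parse_tabular_hits(source: Source) -> list[Hit]:
    """Parse a 12-column tab-separated hit table (``#`` comments skipped).

    Extra trailing columns are tolerated with a warning; fewer than 12
    columns or a non-numeric field is a :class:`ParseError` carrying the
    line number.
    """
    handle, owned = _open_text(handle_or(source))
    try:
        hits = []
        warned_extra = False
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _HIT_COLUMNS:
                raise ParseError(
                    f"expected {_HIT_COLUMNS} tab-separated columns, got {len(fields)}",
                    line=lineno,
                )
            if len(fields) > _HIT_COLUMNS and not warned_extra:
                warnings.warn(
                    f"hit table has {len(fields)} columns; extra columns ignored",
                    stacklevel=2,
                )
                warned_extra = True
            try:
                hits.append(
                    Hit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", line=lineno) from None
    finally:
        if owned:
            handle.close()
    return hits


def handle_or(source: Source) -> Source:
    """Accept raw text in addition to paths and handles (testing nicety)."""
    if isinstance(source, str) and ("\n" in source or "\t" in source or not source):
        return _stdio.StringIO(source)
    return source


def write_tabular_hits(hits: Iterable[Hit]) -> str:
    """Render hits in the 12-column dialect; floats use ``repr`` so that
    :func:`parse_tabular_hits` round-trips exactly."""
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    repr(h.percent_identity),
                    str(h.alignment_length),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(h.q_start),
                    str(h.q_end),
                    str(h.s_start),
                    str(h.s_end),
                    repr(h.evalue),
                    repr(h.bit_score),
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Per-target domain tables (hmmscan --tblout layout)

_DOMAIN_MIN_COLUMNS = 6


def parse_domain_hits(source: Source) -> list[DomainHit]:
    """Parse a whitespace-separated per-target domain table.

    Column layout follows the profile-search per-target convention:
    target (domain) name, target accession, query (ORF) name, query
    accession, full-sequence e-value, full-sequence score. Rows are
    returned unfiltered; score thresholds are applied downstream.
    """
    handle, owned = _open_text(handle_or(source))
    try:
        hits = []
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMAIN_MIN_COLUMNS:
                raise ParseError(
                    f"expected at least {_DOMAIN_MIN_COLUMNS} columns "
                    f"(missing score column?), got {len(fields)}",
                    line=lineno,
                )
            try:
                hits.append(
                    DomainHit(
                        domain_name=fields[0],
                        domain_accession=fields[1],
                        orf_id=fields[2],
                        evalue=float(fields[4]),
                        score=float(fields[5]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", line=lineno) from None
    finally:
        if owned:
            handle.close()
    return hits


def write_domain_hits(hits: Iterable[DomainHit]) -> str:
    lines = [
        f"{h.domain_name} {h.domain_accession} {h.orf_id} - {h.evalue!r} {h.score!r}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Taxonomy tables


def load_taxonomy(lineage_source: Source, length_source: Source | None = None) -> TaxonomyTable:
    """Load ``ref_id<TAB>root;...;species`` lineages and optional
    ``ref_id<TAB>length`` genome lengths into a :class:`TaxonomyTable`."""
    entries: dict[str, Lineage] = {}
    handle, owned = _open_text(handle_or(lineage_source))
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError("expected ref_id<TAB>lineage", line=lineno)
            ref, lineage_text = parts
            if ref in entries:
                raise ParseError(f"duplicate lineage for {ref}", line=lineno)
            entries[ref] = Lineage.from_string(lineage_text)
    finally:
        if owned:
            handle.close()

    lengths: dict[str, int] = {}
    if length_source is not None:
        handle, owned = _open_text(handle_or(length_source))
        try:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError("expected ref_id<TAB>length", line=lineno)
                ref, raw = parts
                try:
                    length = int(raw)
                except ValueError:
                    raise ParseError(f"non-integer length {raw!r}", line=lineno) from None
                if length < 1:
                    raise ParseError(f"non-positive length for {ref}", line=lineno)
                if ref in lengths:
                    raise ParseError(f"duplicate length for {ref}", line=lineno)
                lengths[ref] = length
        finally:
            if owned:
                handle.close()
    return TaxonomyTable(entries=entries, genome_lengths=lengths)


def write_taxonomy(taxonomy: TaxonomyTable) -> tuple[str, str]:
    """Render (lineage_tsv, length_tsv) for a taxonomy table."""
    lin = "".join(f"{ref}\t{lineage}\n" for ref, lineage in taxonomy.entries.items())
    lens = "".join(f"{ref}\t{n}\n" for ref, n in taxonomy.genome_lengths.items())
    return lin, lens


# ---------------------------------------------------------------------------
# GenBank flat files


def _orf_location(orf, contig_length: int, is_circular: bool):
    strand = 1 if orf.strand == "+" else -1
    if not orf.wraps_origin:
        if orf.end > contig_length:
            raise CoordinateError(
                f"ORF {orf.id} extends past the end of a linear contig"
            )
        return SimpleLocation(orf.start, orf.end, strand=strand)
    if not is_circular:
        raise CoordinateError(f"ORF {orf.id} wraps the origin of a linear contig")
    parts = [
        SimpleLocation(orf.start, contig_length, strand=strand),
        SimpleLocation(0, orf.end, strand=strand),
    ]
    if strand == -1:
        parts.reverse()
    return CompoundLocation(parts)


def write_genbank(contig, orfs, lca=None, orf_annotations=None) -> str:
    """Render one contig and its gene calls as a GenBank flat file.

    The LOCUS topology word reflects circularity, each ORF becomes a CDS
    feature with its translation (origin-wrapping genes as ``join``
    locations, minus-strand genes as ``complement``), the contig-level
    lowest-common-ancestor affiliation goes into the source feature, and
    per-ORF best-hit / domain annotations are carried as notes.

    ``orf_annotations`` maps orf_id to a dict with optional keys
    ``product``, ``best_hit`` and ``domains`` (list of accessions).
    """
    length = contig.trimmed_length
    annotations = orf_annotations or {}
    record = SeqRecord(
        Seq(contig.record.residues),
        id=contig.record.id,
        name=contig.record.id[:16],
        description=contig.record.description or f"virome contig {contig.record.id}",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if contig.is_circular else "linear",
            "data_file_division": "ENV",
        },
    )
    source_quals = {"organism": ["uncultured virus"], "mol_type": ["genomic DNA"]}
    if lca is not None and lca.lineage is not None:
        source_quals["note"] = [f"LCA affiliation: {lca.lineage}"]
    record.features.append(
        SeqFeature(SimpleLocation(0, length, strand=1), type="source",
                   qualifiers=source_quals)
    )
    for orf in orfs:
        quals: dict[str, list[str]] = {
            "locus_tag": [orf.id],
            "transl_table": ["11"],
            "translation": [orf.protein],
        }
        ann = annotations.get(orf.id, {})
        quals["product"] = [ann.get("product", "hypothetical protein")]
        notes = []
        if ann.get("best_hit"):
            notes.append(f"best hit: {ann['best_hit']}")
        for acc in ann.get("domains", ()):
            notes.append(f"domain: {acc}")
        if notes:
            quals["note"] = notes
        record.features.append(
            SeqFeature(
                _orf_location(orf, length, contig.is_circular),
                type="CDS",
                qualifiers=quals,
            )
        )
    buf = _stdio.StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Network export


def network_to_graph(network) -> "nx.Graph":
    """Convert a similarity network to a networkx graph (MultiGraph for
    per-ORF edge mode, where parallel edges between a pair are meaningful)."""
    graph = nx.MultiGraph() if network.mode == "per_orf" else nx.Graph()
    graph.graph["mode"] = network.mode
    for node in network.nodes:
        graph.add_node(
            node.id,
            kind=node.kind,
            taxonomy=node.taxonomy or "",
            length=int(node.length or 0),
        )
    for edge in network.edges:
        attrs = {}
        if edge.orf_id is not None:
            attrs["orf_id"] = edge.orf_id
        if edge.bit_score is not None:
            attrs["bit_score"] = float(edge.bit_score)
        if edge.shared_gene_count is not None:
            attrs["shared_gene_count"] = int(edge.shared_gene_count)
        graph.add_edge(edge.node_a, edge.node_b, **attrs)
    return graph


def _xgmml(graph: "nx.Graph") -> str:
    def attr(name, value):
        if isinstance(value, (int,)) and not isinstance(value, bool):
            return f'    <att name="{name}" type="integer" value="{value}"/>'
        if isinstance(value, float):
            return f'    <att name="{name}" type="real" value="{value!r}"/>'
        return f'    <att name="{name}" type="string" value="{value}"/>'

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<graph label="similarity network" directed="0" '
        'xmlns="http://www.cs.rpi.edu/XGMML">',
    ]
    index = {node: i for i, node in enumerate(graph.nodes)}
    for node, data in graph.nodes(data=True):
        lines.append(f'  <node id="{index[node]}" label="{node}">')
        lines.extend(attr(k, v) for k, v in data.items())
        lines.append("  </node>")
    for a, b, data in graph.edges(data=True):
        lines.append(
            f'  <edge source="{index[a]}" target="{index[b]}" label="{a}-{b}">'
        )
        lines.extend(attr(k, v) for k, v in data.items())
        lines.append("  </edge>")
    lines.append("</graph>")
    return "\n".join(lines) + "\n"


def export_network(network, fmt: str) -> str:
    """Serialize a similarity network as ``graphml``, ``xgmml`` or ``csv``
    (edge list with attributes)."""
    graph = network_to_graph(network)
    if fmt == "graphml":
        return "\n".join(nx.generate_graphml(graph, named_key_ids=True)) + "\n"
    if fmt == "xgmml":
        return _xgmml(graph)
    if fmt == "csv":
        lines = ["node_a,node_b,orf_id,bit_score,shared_gene_count"]
        for e in network.edges:
            lines.append(
                f"{e.node_a},{e.node_b},{e.orf_id or ''},"
                f"{'' if e.bit_score is None else repr(float(e.bit_score))},"
                f"{'' if e.shared_gene_count is None else e.shared_gene_count}"
            )
        return "\n".join(lines) + "\n"
    raise UsageError(f"unknown network export format: {fmt!r}")


def import_graphml(text: str) -> "nx.Graph":
    """Re-read a GraphML document (round-trip checking, downstream reuse)."""
    return nx.parse_graphml(text)
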