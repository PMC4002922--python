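"""Circular-contig handling and gene calling.

Assembled viral contigs whose two ends carry the same k-mer are evidence
of a complete circular genome (or a circularly permuted one): the
assembler walked all the way around and re-emitted the start. Such
contigs are detected by terminal-overlap search, trimmed of the
redundant terminal copy, and genes spanning the origin are recovered by
scanning a temporary sequence in which the first nucleotides are
duplicated at the end.

The built-in ORF finder is a deliberately naive six-frame scanner
(start codons ATG/GTG/TTG, stops TAA/TAG/TGA, bacterial code); the
production route for real data is :func:`import_orfs`, which adapts the
coordinate table of an external gene predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .errors import CoordinateError, DataError
from .records import SequenceRecord

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Number of leading nucleotides duplicated at the end of a circular
#: contig before gene scanning, so origin-spanning genes are seen intact.
ORIGIN_DUPLICATION_NT = 1000


@dataclass(frozen=True)
class Contig:
    """A contig with circularity status and trimming provenance."""

    record: SequenceRecord
    is_circular: bool
    trimmed_length: int
    original_length: int
    overlap_length: int = 0

    def __post_init__(self):
        if self.trimmed_length > self.original_length:
            raise DataError(f"contig {self.record.id}: trimmed longer than original")
        if self.trimmed_length != len(self.record.residues):
            raise DataError(f"contig {self.record.id}: trimmed length mismatch")


@dataclass(frozen=True)
class Orf:
    """A gene call on a contig; 0-based half-open on the trimmed sequence.

    ``wraps_origin`` marks genes crossing the origin of a circular
    contig, in which case ``start > end`` and the nucleotide span is
    ``residues[start:] + residues[:end]``.
    """

    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    wraps_origin: bool
    protein: str
    truncated_start: bool = False
    truncated_end: bool = False

    def nucleotide_span(self, length: int) -> int:
        if self.wraps_origin:
            return (length - self.start) + self.end
        return self.end - self.start


def as_contig(record: SequenceRecord, is_circular: bool = False) -> Contig:
    """Wrap a sequence as a contig without end-overlap detection."""
    return Contig(record, is_circular, len(record.residues), len(record.residues))


def detect_and_trim_circular(record: SequenceRecord, k: int = 10) -> Contig:
    """Detect a circular contig by identical k-mers at its two ends.

    The longest suffix equal to a prefix, of length at least ``k`` (and
    at most half the sequence), is treated as the assembler's redundant
    terminal copy and removed; ``trimmed_length = original - overlap``.
    Sequences too short to test (``len <= 2k``) are returned linear with
    a warning.
    """
    seq = record.residues
    n = len(seq)
    if n <= 2 * k:
        warnings.warn(
            f"contig {record.id} is shorter than 2k+1 ({n} nt, k={k}); "
            "circularity not tested",
            stacklevel=2,
        )
        return Contig(record, False, n, n)
    best = 0
    for olen in range(k, n // 2 + 1):
        if seq[:olen] == seq[n - olen:]:
            best = olen
    if best == 0:
        return Contig(record, False, n, n)
    trimmed = replace(record, residues=seq[: n - best])
    return Contig(trimmed, True, n - best, n, overlap_length=best)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate(nt: str, is_start_anchored: bool = True) -> str:
    """Translate a codon-aligned span with the bacterial code; an
    alternative start codon is rendered as M; terminal stop dropped."""
    protein = str(Seq(nt).translate(table=11))
    if protein.endswith("*"):
        protein = protein[:-1]
    if is_start_anchored and nt[:3] in START_CODONS and protein:
        protein = "M" + protein[1:]
    return protein


def _scan_frames(seq: str, min_length_nt: int):
    """Yield (start, end) spans of start..stop ORFs on the forward strand
    of ``seq`` (end includes the stop codon); first start after the
    previous in-frame stop wins (longest ORF per stop)."""
    n = len(seq)
    for frame in range(3):
        candidate = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                if candidate is not None and (i + 3 - candidate) >= min_length_nt:
                    yield candidate, i + 3
                candidate = None
            elif candidate is None and codon in START_CODONS:
                candidate = i


def orf_nucleotides(contig: Contig, orf: Orf) -> str:
    """Extract the oriented nucleotide sequence of an ORF (wrap-aware)."""
    seq = contig.record.residues
    if orf.wraps_origin:
        nt = seq[orf.start:] + seq[:orf.end]
    else:
        nt = seq[orf.start:orf.end]
    return _revcomp(nt) if orf.strand == "-" else nt


def predict_orfs(contig: Contig, min_length_nt: int = 120) -> list[Orf]:
    """Naive six-frame ORF prediction on a (possibly circular) contig.

    For circular contigs the scan runs on the trimmed sequence plus its
    first ``min(1000, length)`` nucleotides appended, then coordinates
    are reduced modulo the trimmed length; reduced duplicates are
    dropped and origin-wrapping genes get ``wraps_origin=True``.
    """
    if min_length_nt < 6 or min_length_nt % 3:
        raise DataError("min_length_nt must be >= 6 and divisible by 3")
    length = contig.trimmed_length
    seq = contig.record.residues
    if contig.is_circular:
        dup = min(ORIGIN_DUPLICATION_NT, length)
        scan_seq = seq + seq[:dup]
    else:
        scan_seq = seq
    n_ext = len(scan_seq)

    raw: list[tuple[int, int, str]] = []  # (start, end) on scan_seq, strand
    for s, e in _scan_frames(scan_seq, min_length_nt):
        raw.append((s, e, "+"))
    rc = _revcomp(scan_seq)
    for s, e in _scan_frames(rc, min_length_nt):
        raw.append((n_ext - e, n_ext - s, "-"))

    seen: set[tuple[int, str]] = set()
    orfs: list[tuple[int, int, str, bool]] = []
    for s, e, strand in raw:
        wraps = False
        if contig.is_circular:
            if s >= length:
                s -= length
                e -= length
            if e > length:
                e -= length
                wraps = True
                if e > s:
                    continue  # gene longer than the whole contig
        key = (s, strand)
        if key in seen:
            continue
        seen.add(key)
        orfs.append((s, e, strand, wraps))

    orfs.sort(key=lambda t: (t[0], t[1], t[2]))
    result = []
    for i, (s, e, strand, wraps) in enumerate(orfs, start=1):
        orf = Orf(
            id=f"{contig.record.id}_{i}",
            contig_id=contig.record.id,
            start=s,
            end=e,
            strand=strand,
            wraps_origin=wraps,
            protein="",
        )
        result.append(replace(orf, protein=_translate(orf_nucleotides(contig, orf))))
    return result


def import_orfs(contig: Contig, external_predictions: Iterable[Sequence]) -> list[Orf]:
    """Adapt an external gene predictor's coordinate table to :class:`Orf`.

    Rows are ``(contig_id, start, end, strand[, partial_start, partial_end])``
    with 1-based inclusive coordinates; a row with start > end on a
    circular contig denotes an origin-wrapping gene.
    """
    length = contig.trimmed_length
    result = []
    for i, row in enumerate(external_predictions, start=1):
        contig_id, start1, end1, strand = row[0], int(row[1]), int(row[2]), row[3]
        partial_start = bool(row[4]) if len(row) > 4 else False
        partial_end = bool(row[5]) if len(row) > 5 else False
        if contig_id != contig.record.id:
            raise DataError(
                f"prediction row for {contig_id} applied to contig {contig.record.id}"
            )
        if strand not in "+-":
            raise DataError(f"bad strand {strand!r} in prediction row {i}")
        if not (1 <= start1 <= length) or not (1 <= end1 <= length):
            raise CoordinateError(
                f"ORF coordinates ({start1},{end1}) outside contig "
                f"{contig.record.id} (length {length})"
            )
        wraps = start1 > end1
        if wraps and not contig.is_circular:
            raise CoordinateError(
                f"wrapping ORF on linear contig {contig.record.id}"
            )
        orf = Orf(
            id=f"{contig.record.id}_{i}",
            contig_id=contig.record.id,
            start=start1 - 1,
            end=end1,
            strand=strand,
            wraps_origin=wraps,
            protein="",
            truncated_start=partial_start,
            truncated_end=partial_end,
        )
        nt = orf_nucleotides(contig, orf)
        if len(nt) % 3:
            raise CoordinateError(f"ORF {orf.id}: span not a multiple of 3")
        result.append(
            replace(orf, protein=_translate(nt, is_start_anchored=not partial_start))
        )
    return result


def flag_truncated(orfs: Iterable[Orf], contig: Contig) -> list[Orf]:
    """Flag gene calls truncated by the contig edges.

    An ORF touching position 0 or the contig end without the codon that
    should anchor that side (start codon at its 5' end, stop codon at
    its 3' end) is marked truncated on that side. Circular contigs have
    no edges, so their genes are never flagged; the absence of any
    truncated gene on a linear contig is evidence it may be a complete
    genome.
    """
    length = contig.trimmed_length
    seq = contig.record.residues
    out = []
    for orf in orfs:
        if contig.is_circular:
            out.append(replace(orf, truncated_start=False, truncated_end=False))
            continue
        oriented = orf_nucleotides(contig, orf)
        has_start = oriented[:3] in START_CODONS
        # the stop codon, when present, lies just past the reported span
        if orf.strand == "+":
            stop = seq[orf.end:orf.end + 3]
            ends_with_stop = oriented[-3:] in STOP_CODONS or stop in STOP_CODONS
            t_start = orf.start == 0 and not has_start
            t_end = orf.end >= length - 2 and not ends_with_stop
        else:
            stop = seq[max(orf.start - 3, 0):orf.start]
            ends_with_stop = oriented[-3:] in STOP_CODONS or (
                len(stop) == 3 and _revcomp(stop) in STOP_CODONS
            )
            t_start = orf.start <= 2 and not ends_with_stop
            t_end = orf.end == length and not has_start
        out.append(replace(orf, truncated_start=t_start, truncated_end=t_end))
    return out


def orf_table(orfs: Iterable[Orf]) -> str:
    """Render gene calls as a TSV table."""
    lines = ["orf_id\tcontig_id\tstart\tend\tstrand\twraps_origin\t"
             "truncated_start\ttruncated_end"]
    for o in orfs:
        lines.append(
            f"{o.id}\t{o.contig_id}\t{o.start}\t{o.end}\t{o.strand}\t"
            f"{int(o.wraps_origin)}\t{int(o.truncated_start)}\t{int(o.truncated_end)}"
        )
    return "\n".join(lines) + "\n"
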