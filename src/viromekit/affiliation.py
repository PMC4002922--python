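"""Taxonomic affiliation from similarity hit tables.

Three affiliation strategies mirror how virome practitioners read a
BLAST table: per-sequence best hit (reads), per-contig best hit, and a
per-contig lowest-common-ancestor (LCA) call that pools the best hits
of up to five genes and reports the deepest rank they all share.
Virome-level compositions come in a raw best-hit flavor and a
genome-length-normalized flavor (longer genomes recruit more reads at
equal abundance, so counts are reweighted by 1/length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, UsageError
from .records import Hit, Lineage, TaxonomyTable, group_hits_by_query

EVALUE_MAX_DEFAULT = 1e-3
LCA_MAX_GENES = 5

COMPOSITION_MODES = (
    "raw_best_hit",
    "length_normalized",
    "gene_best_hit",
    "contig_best_hit",
    "contig_lca",
)


@dataclass(frozen=True)
class Affiliation:
    """A taxonomic call: the subject (best-hit mode), the lineage, the
    rank depth of the call, and the number of genes supporting it."""

    subject_id: str | None
    lineage: Lineage | None
    level: int
    support: int


@dataclass(frozen=True)
class Composition:
    """Taxon weights of one virome; weights plus the unassigned fraction
    sum to one."""

    virome_id: str
    mode: str
    weights: Mapping[tuple[str, ...], float]
    unassigned: float

    def __post_init__(self):
        total = sum(self.weights.values()) + self.unassigned
        if abs(total - 1.0) > 1e-9:
            raise DataError(
                f"composition {self.virome_id}: weights + unassigned = {total}"
            )


def _hit_sort_key(hit: Hit):
    # highest bit-score, then lowest e-value, then highest identity,
    # then lexicographic subject id: one pinned, deterministic order
    return (-hit.bit_score, hit.evalue, -hit.percent_identity, hit.subject_id)


def best_hit(hits: Sequence[Hit], evalue_max: float = EVALUE_MAX_DEFAULT) -> Hit | None:
    """Best hit of one query after the e-value screen (inclusive)."""
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise UsageError(f"best_hit called with mixed query ids: {sorted(queries)}")
    survivors = [h for h in hits if h.evalue <= evalue_max]
    if not survivors:
        return None
    return min(survivors, key=_hit_sort_key)


def best_hits_by_query(
    hits: Iterable[Hit],
    all_query_ids: Iterable[str] | None = None,
    evalue_max: float = EVALUE_MAX_DEFAULT,
) -> dict[str, Hit | None]:
    """Best hit per query; queries listed in ``all_query_ids`` but absent
    from the table map to ``None`` (needed to count unassigned reads)."""
    grouped = group_hits_by_query(hits)
    result: dict[str, Hit | None] = {}
    if all_query_ids is not None:
        for q in all_query_ids:
            result[q] = None
    for q, group in grouped.items():
        result[q] = best_hit(group, evalue_max)
    return result


def read_composition(
    best_hits: Mapping[str, Hit | None],
    taxonomy: TaxonomyTable,
    mode: str = "raw_best_hit",
    virome_id: str = "virome",
) -> Composition:
    """Virome composition from per-sequence best hits.

    ``raw_best_hit``: each best hit contributes one count to its
    reference's lineage. ``length_normalized``: per-reference counts are
    divided by genome length and renormalized over references, so a
    10 kb genome with 10 hits outweighs a 40 kb genome with 20.
    The unassigned fraction is the share of inputs with no best hit.
    """
    if mode not in ("raw_best_hit", "length_normalized"):
        raise UsageError(f"unknown composition mode: {mode!r}")
    total = len(best_hits)
    if total == 0:
        raise UsageError("empty best-hit mapping")
    counts: dict[str, int] = {}
    n_assigned = 0
    for hit in best_hits.values():
        if hit is None:
            continue
        n_assigned += 1
        if hit.subject_id not in taxonomy:
            raise DataError(f"best hit subject {hit.subject_id} not in taxonomy")
        counts[hit.subject_id] = counts.get(hit.subject_id, 0) + 1
    unassigned = (total - n_assigned) / total
    weights: dict[tuple[str, ...], float] = {}
    if n_assigned:
        if mode == "raw_best_hit":
            raw = {ref: c / total for ref, c in counts.items()}
        else:
            dens = {ref: c / taxonomy.length(ref) for ref, c in counts.items()}
            scale = (n_assigned / total) / sum(dens.values())
            raw = {ref: d * scale for ref, d in dens.items()}
        for ref, w in raw.items():
            path = taxonomy.lineage(ref).ranks
            weights[path] = weights.get(path, 0.0) + w
    return Composition(virome_id, mode, weights, unassigned)


def contig_affiliation(
    orf_best_hits: Sequence[Hit],
    taxonomy: TaxonomyTable,
    mode: str = "lca",
    max_genes: int = LCA_MAX_GENES,
) -> Affiliation | None:
    """Affiliate one contig from the best hits of its genes.

    ``best_hit`` mode returns the lineage of the single
    highest-bit-score gene hit. ``lca`` mode takes the ``max_genes``
    (default five) affiliated genes with the highest best-hit
    bit-scores and returns the deepest rank shared by all their
    lineages (the longest common lineage prefix). A contig with no
    affiliated gene returns ``None``.
    """
    if mode not in ("best_hit", "lca"):
        raise UsageError(f"unknown contig affiliation mode: {mode!r}")
    if not orf_best_hits:
        return None
    ranked = sorted(orf_best_hits, key=lambda h: _hit_sort_key(h) + (h.query_id,))
    if mode == "best_hit":
        top = ranked[0]
        lineage = taxonomy.lineage(top.subject_id)
        return Affiliation(top.subject_id, lineage, len(lineage) - 1, 1)
    chosen = ranked[:max_genes]
    lineages = [taxonomy.lineage(h.subject_id) for h in chosen]
    prefix = lineages[0].ranks
    for lin in lineages[1:]:
        prefix = Lineage(prefix).common_prefix(lin) if prefix else ()
    if not prefix:
        return Affiliation(None, None, -1, len(chosen))
    return Affiliation(None, Lineage(prefix), len(prefix) - 1, len(chosen))


def affiliation_composition(
    affiliations: Mapping[str, Affiliation | None],
    mode: str,
    virome_id: str = "virome",
) -> Composition:
    """Composition of a contig dataset from per-item affiliations
    (``gene_best_hit``, ``contig_best_hit`` or ``contig_lca`` mode);
    items with no affiliation count as unassigned."""
    if mode not in ("gene_best_hit", "contig_best_hit", "contig_lca"):
        raise UsageError(f"unknown affiliation composition mode: {mode!r}")
    total = len(affiliations)
    if total == 0:
        raise UsageError("empty affiliation mapping")
    weights: dict[tuple[str, ...], float] = {}
    unassigned = 0
    for aff in affiliations.values():
        if aff is None or aff.lineage is None:
            unassigned += 1
            continue
        path = aff.lineage.ranks
        weights[path] = weights.get(path, 0.0) + 1.0 / total
    return Composition(virome_id, mode, weights, unassigned / total)


def composition_table(compositions: Sequence[Composition]) -> pd.DataFrame:
    """Hierarchical taxa-by-virome table (heatmap data layer).

    Rows are every taxon path observed in any composition plus all its
    ancestors, parents sorted before children; a parent row equals the
    sum of its children. Columns follow the input order. Exportable as
    CSV as-is.
    """
    if not compositions:
        raise UsageError("no compositions given")
    paths: set[tuple[str, ...]] = set()
    for comp in compositions:
        for path in comp.weights:
            for depth in range(1, len(path) + 1):
                paths.add(path[:depth])
    rows = sorted(paths)
    data = {}
    for comp in compositions:
        col = []
        for row in rows:
            col.append(
                sum(w for path, w in comp.weights.items() if path[: len(row)] == row)
            )
        data[comp.virome_id] = col
    frame = pd.DataFrame(data, index=[";".join(r) for r in rows])
    frame.index.name = "taxon"
    return frame


def affiliation_table(
    affiliations: Mapping[str, Affiliation | None],
) -> pd.DataFrame:
    """Per-contig (or per-gene) affiliation table for CSV export."""
    rows = []
    for name in sorted(affiliations):
        aff = affiliations[name]
        rows.append(
            {
                "id": name,
                "subject_id": "" if aff is None or aff.subject_id is None else aff.subject_id,
                "lineage": "" if aff is None or aff.lineage is None else str(aff.lineage),
                "level": -1 if aff is None else aff.level,
                "support": 0 if aff is None else aff.support,
            }
        )
    return pd.DataFrame(rows, columns=["id", "subject_id", "lineage", "level", "support"])
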