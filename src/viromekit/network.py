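"""Gene-sharing similarity networks between contigs and reference genomes.

Contigs and reference genomes are nodes; retained protein similarities
are edges. To capture all relevant similarity rather than only the
single best hit, each ORF keeps every hit that passes the e-value
screen and whose bit-score lies within a 10% (multiplicative,
inclusive) margin of that ORF's best bit-score. Edges can be kept per
ORF (one edge per retained hit, carrying the bit-score) or aggregated
per node pair (one edge carrying the number of distinct shared genes),
and the aggregated form supports the classic "two or more shared
genes" filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import MappingError, UsageError
from .records import Hit, TaxonomyTable, group_hits_by_query

EVALUE_MAX_DEFAULT = 1e-3
MARGIN_DEFAULT = 0.10


@dataclass(frozen=True)
class NetworkNode:
    id: str
    kind: str                    # "contig" or "reference"
    taxonomy: str | None = None  # family-level taxon for reference nodes
    length: int | None = None


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    orf_id: str | None = None
    bit_score: float | None = None
    shared_gene_count: int | None = None

    def pair(self) -> tuple[str, str]:
        return (self.node_a, self.node_b) if self.node_a <= self.node_b else (
            self.node_b, self.node_a)


@dataclass
class SimilarityNetwork:
    mode: str
    nodes: list[NetworkNode] = field(default_factory=list)
    edges: list[NetworkEdge] = field(default_factory=list)

    def __post_init__(self):
        ids = {n.id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise UsageError("duplicate node ids")
        for e in self.edges:
            if e.node_a == e.node_b:
                raise UsageError(f"self loop on {e.node_a}")
            if e.node_a not in ids or e.node_b not in ids:
                raise UsageError(f"edge endpoint missing: {e.node_a}-{e.node_b}")

    def node_ids(self) -> set[str]:
        return {n.id for n in self.nodes}


def select_margin_hits(
    hits: Sequence[Hit],
    evalue_max: float = EVALUE_MAX_DEFAULT,
    margin: float = MARGIN_DEFAULT,
) -> list[Hit]:
    """Keep one ORF's hits that pass the e-value screen (inclusive) and
    score within the margin of the best: ``bit >= (1 - margin) * best``,
    inclusive. The best hit itself is always kept."""
    survivors = [h for h in hits if h.evalue <= evalue_max]
    if not survivors:
        return []
    best = max(h.bit_score for h in survivors)
    cutoff = (1.0 - margin) * best
    return [h for h in survivors if h.bit_score >= cutoff]


def build_network(
    orf_hits: Iterable[Hit],
    orf_to_contig: Mapping[str, str],
    protein_to_genome: Mapping[str, str],
    taxonomy: TaxonomyTable | None = None,
    mode: str = "aggregated",
    evalue_max: float = EVALUE_MAX_DEFAULT,
    margin: float = MARGIN_DEFAULT,
    contig_lengths: Mapping[str, int] | None = None,
) -> SimilarityNetwork:
    """Build the contig / reference similarity network from ORF hits.

    Hit subjects resolve either to a reference genome (via
    ``protein_to_genome``) or to another contig's ORF (via
    ``orf_to_contig``); anything else raises :class:`MappingError`.
    ORFs hitting their own contig are dropped. ``per_orf`` keeps one
    edge per retained hit; ``aggregated`` keeps one edge per node pair
    counting the distinct ORFs involved.
    """
    if mode not in ("per_orf", "aggregated"):
        raise UsageError(f"unknown network mode: {mode!r}")
    contig_nodes: set[str] = set()
    genome_nodes: set[str] = set()
    per_orf_edges: list[NetworkEdge] = []
    pair_orfs: dict[tuple[str, str], set[str]] = {}

    for orf_id, hits in group_hits_by_query(orf_hits).items():
        if orf_id not in orf_to_contig:
            raise MappingError(f"query ORF {orf_id} has no contig mapping")
        contig = orf_to_contig[orf_id]
        for hit in select_margin_hits(hits, evalue_max, margin):
            if hit.subject_id in protein_to_genome:
                target = protein_to_genome[hit.subject_id]
                is_genome = True
            elif hit.subject_id in orf_to_contig:
                target = orf_to_contig[hit.subject_id]
                is_genome = False
            else:
                raise MappingError(
                    f"hit subject {hit.subject_id} is neither a reference "
                    "protein nor a known ORF"
                )
            if target == contig:
                continue  # self similarity
            contig_nodes.add(contig)
            (genome_nodes if is_genome else contig_nodes).add(target)
            pair = (contig, target) if contig <= target else (target, contig)
            per_orf_edges.append(
                NetworkEdge(pair[0], pair[1], orf_id=orf_id, bit_score=hit.bit_score)
            )
            pair_orfs.setdefault(pair, set()).add(orf_id)

    nodes = [
        NetworkNode(cid, "contig", None,
                    None if contig_lengths is None else contig_lengths.get(cid))
        for cid in sorted(contig_nodes)
    ]
    nodes += [
        NetworkNode(
            gid, "reference",
            taxonomy.family(gid) if taxonomy is not None and gid in taxonomy else None,
            taxonomy.genome_lengths.get(gid) if taxonomy is not None else None,
        )
        for gid in sorted(genome_nodes)
    ]
    if mode == "per_orf":
        edges = sorted(per_orf_edges,
                       key=lambda e: (e.node_a, e.node_b, e.orf_id, -e.bit_score))
    else:
        edges = [
            NetworkEdge(a, b, shared_gene_count=len(orfs))
            for (a, b), orfs in sorted(pair_orfs.items())
        ]
    return SimilarityNetwork(mode, nodes, edges)


def filter_network(
    network: SimilarityNetwork,
    min_shared_genes: int = 1,
    taxa_keep: Iterable[str] | None = None,
    max_nodes: int | None = None,
) -> SimilarityNetwork:
    """Filter an aggregated network for display.

    Drops aggregated edges below ``min_shared_genes`` (the "two or more
    shared genes" view), optionally restricts reference nodes to given
    family taxa, optionally keeps only the ``max_nodes`` highest-degree
    nodes; nodes orphaned by the filtering are removed. With no filter
    requested the network is returned unchanged.
    """
    if min_shared_genes > 1 and network.mode != "aggregated":
        raise UsageError("shared-gene filtering needs an aggregated network")
    if min_shared_genes <= 1 and taxa_keep is None and max_nodes is None:
        return SimilarityNetwork(network.mode, list(network.nodes),
                                 list(network.edges))
    nodes = list(network.nodes)
    edges = list(network.edges)
    if min_shared_genes > 1:
        edges = [e for e in edges if (e.shared_gene_count or 0) >= min_shared_genes]
    if taxa_keep is not None:
        keep_taxa = set(taxa_keep)
        kept_ids = {
            n.id for n in nodes
            if n.kind != "reference" or (n.taxonomy in keep_taxa)
        }
        nodes = [n for n in nodes if n.id in kept_ids]
        edges = [e for e in edges if e.node_a in kept_ids and e.node_b in kept_ids]
    if max_nodes is not None:
        degree: dict[str, int] = {n.id: 0 for n in nodes}
        for e in edges:
            degree[e.node_a] += 1
            degree[e.node_b] += 1
        ranked = sorted(nodes, key=lambda n: (-degree[n.id], n.id))
        kept_ids = {n.id for n in ranked[:max_nodes]}
        nodes = [n for n in nodes if n.id in kept_ids]
        edges = [e for e in edges if e.node_a in kept_ids and e.node_b in kept_ids]
    connected: set[str] = set()
    for e in edges:
        connected.add(e.node_a)
        connected.add(e.node_b)
    nodes = [n for n in nodes if n.id in connected]
    return SimilarityNetwork(network.mode, nodes, edges)


def map_comparison_table(
    orf_hits: Iterable[Hit],
    orf_to_contig: Mapping[str, str],
    protein_to_genome: Mapping[str, str],
    node_a: str,
    node_b: str,
    orf_starts: Mapping[str, int],
    evalue_max: float = EVALUE_MAX_DEFAULT,
    margin: float = MARGIN_DEFAULT,
) -> list[tuple[str, str, float, int]]:
    """Gene-pair hits linking two chosen sequences, ordered by the query
    gene's coordinate (data layer of a map-to-map comparison).

    Returns rows ``(orf_id, subject_id, bit_score, orf_start)``.
    """
    rows = []
    for orf_id, hits in group_hits_by_query(orf_hits).items():
        contig = orf_to_contig.get(orf_id)
        if contig != node_a:
            continue
        for hit in select_margin_hits(hits, evalue_max, margin):
            target = protein_to_genome.get(hit.subject_id,
                                           orf_to_contig.get(hit.subject_id))
            if target != node_b:
                continue
            rows.append((orf_id, hit.subject_id, hit.bit_score,
                         orf_starts.get(orf_id, 0)))
    rows.sort(key=lambda r: (r[3], r[0], r[1]))
    return rows
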