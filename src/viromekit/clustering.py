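"""Protein clustering and diversity (rarefaction) estimation.

Two complementary clusterings of a virome's predicted proteins:

* greedy centroid clustering at a fixed identity threshold (the
  75/90/98% tiers familiar from virome annotation pipelines): proteins
  are taken longest-first, each either joins the first existing
  centroid it matches at or above the threshold or founds a new
  cluster;
* seeded domain clustering: proteins are taken longest-first as seeds
  for an injected ``recruiter`` (in production an iterative profile
  search wrapped externally; for testing a plain alignment-identity
  recruiter), each seed absorbing everything it recruits.

Identity here is pinned as global-alignment identities over alignment
columns. Cluster richness as a function of sampling depth is estimated
by rarefaction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .errors import DataError, UsageError
from .records import DomainHit

DEFAULT_IDENTITY_THRESHOLDS = (0.75, 0.90, 0.98)
DOMAIN_SCORE_MIN = 30.0


@dataclass(frozen=True)
class ProteinCluster:
    cluster_id: str
    centroid_id: str
    member_ids: tuple[str, ...]
    threshold: float | None = None
    domain_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.centroid_id not in self.member_ids:
            raise DataError(f"cluster {self.cluster_id}: centroid not a member")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def alignment_identity(a: str, b: str) -> float:
    """Global alignment identity: matches / alignment columns (gaps
    included in the denominator)."""
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def _by_length(items: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    # longest first; ties broken by id for determinism
    return sorted(items, key=lambda kv: (-len(kv[1]), kv[0]))


def cluster_by_identity(
    proteins: Mapping[str, str] | Sequence[tuple[str, str]],
    threshold: float,
) -> list[ProteinCluster]:
    """Greedy centroid clustering at a global-identity threshold.

    Proteins are processed by decreasing length; each joins the first
    (oldest) centroid it matches with identity >= threshold, otherwise
    founds a new cluster with itself as centroid. Because identity is
    at most min(len)/max(len), pairs whose length ratio is below the
    threshold are skipped without aligning.
    """
    if not 0 < threshold <= 1:
        raise UsageError(f"identity threshold must be in (0, 1], got {threshold}")
    items = _by_length(list(proteins.items()) if isinstance(proteins, Mapping)
                       else list(proteins))
    centroids: list[tuple[str, str]] = []
    members: list[list[str]] = []
    for pid, seq in items:
        placed = False
        for ci, (cid, cseq) in enumerate(centroids):
            if min(len(seq), len(cseq)) / max(len(seq), len(cseq)) < threshold:
                continue
            if alignment_identity(seq, cseq) >= threshold:
                members[ci].append(pid)
                placed = True
                break
        if not placed:
            centroids.append((pid, seq))
            members.append([pid])
    return [
        ProteinCluster(f"IC{i + 1:05d}", cid, tuple(mem), threshold=threshold)
        for i, ((cid, _), mem) in enumerate(zip(centroids, members))
    ]


Recruiter = Callable[[tuple[str, str], Sequence[tuple[str, str]]], Sequence[str]]


def identity_recruiter(threshold: float = 0.5) -> Recruiter:
    """Test-double recruiter: recruits pool members with global identity
    >= threshold to the seed (stands in for an iterative profile search)."""

    def recruiter(seed: tuple[str, str], pool: Sequence[tuple[str, str]]) -> list[str]:
        _, seed_seq = seed
        out = []
        for pid, seq in pool:
            # identity is bounded by min(len)/max(len); skip hopeless pairs
            if min(len(seq), len(seed_seq)) / max(len(seq), len(seed_seq)) < threshold:
                continue
            if alignment_identity(seed_seq, seq) >= threshold:
                out.append(pid)
        return out

    return recruiter


def cluster_by_domain_seed(
    proteins: Mapping[str, str] | Sequence[tuple[str, str]],
    recruiter: Recruiter,
) -> list[ProteinCluster]:
    """Seeded clustering: longest remaining protein seeds a cluster of
    everything the recruiter gathers, which is then removed from play.
    Singletons are allowed; the result is always a partition."""
    remaining = _by_length(list(proteins.items()) if isinstance(proteins, Mapping)
                           else list(proteins))
    clusters = []
    i = 0
    while remaining:
        seed = remaining.pop(0)
        pool = list(remaining)
        recruited = list(recruiter(seed, pool))
        pool_ids = {pid for pid, _ in pool}
        bad = set(recruited) - pool_ids
        if bad:
            raise UsageError(f"recruiter returned ids outside the pool: {sorted(bad)}")
        recruited_set = set(recruited)
        member_ids = (seed[0],) + tuple(pid for pid, _ in remaining
                                        if pid in recruited_set)
        remaining = [(pid, seq) for pid, seq in remaining
                     if pid not in recruited_set]
        i += 1
        clusters.append(ProteinCluster(f"DC{i:05d}", seed[0], member_ids))
    return clusters


def affiliate_domain_clusters(
    clusters: Sequence[ProteinCluster],
    domain_hits: Iterable[DomainHit],
    score_min: float = DOMAIN_SCORE_MIN,
) -> list[ProteinCluster]:
    """Label clusters with the domains their members hit.

    Only hits with score >= ``score_min`` count; labels are ordered by
    total member score, strongest first (ties by accession)."""
    by_orf: dict[str, list[DomainHit]] = {}
    for hit in domain_hits:
        if hit.score >= score_min:
            by_orf.setdefault(hit.orf_id, []).append(hit)
    out = []
    for cluster in clusters:
        totals: dict[str, float] = {}
        for pid in cluster.member_ids:
            for hit in by_orf.get(pid, ()):
                totals[hit.domain_accession] = (
                    totals.get(hit.domain_accession, 0.0) + hit.score
                )
        labels = tuple(sorted(totals, key=lambda acc: (-totals[acc], acc)))
        out.append(replace(cluster, domain_labels=labels))
    return out


@dataclass(frozen=True)
class RarefactionPoint:
    sample_size: int
    mean_clusters: float
    sd_clusters: float


def rarefaction_curve(
    membership: Mapping[str, str],
    steps: Sequence[int],
    reps: int = 10,
    seed: int = 0,
) -> list[RarefactionPoint]:
    """Rarefaction of cluster richness.

    For each sample size, ``reps`` seeded subsamples without replacement
    are drawn from the clustered proteins and the number of distinct
    clusters touched is counted; means are monotone non-decreasing and
    reach the total cluster count at full depth.
    """
    ids = sorted(membership)
    n = len(ids)
    if n == 0:
        raise UsageError("empty membership")
    rng = np.random.default_rng(seed)
    clusters_of = np.array([membership[i] for i in ids])
    curve = []
    for s in steps:
        if not 1 <= s <= n:
            raise UsageError(f"sample size {s} outside [1, {n}]")
        richness = np.empty(reps)
        for r in range(reps):
            take = rng.choice(n, size=s, replace=False)
            richness[r] = len(set(clusters_of[take]))
        curve.append(RarefactionPoint(s, float(richness.mean()),
                                      float(richness.std())))
    return curve


def membership_of(clusters: Sequence[ProteinCluster]) -> dict[str, str]:
    """Flatten clusters to an ORF -> cluster id mapping; a duplicate ORF
    means the clusters are not a partition and is an error."""
    membership: dict[str, str] = {}
    for cluster in clusters:
        for pid in cluster.member_ids:
            if pid in membership:
                raise DataError(f"{pid} appears in two clusters")
            membership[pid] = cluster.cluster_id
    return membership


def clusters_table(clusters: Sequence[ProteinCluster]) -> str:
    """Cluster membership CSV."""
    lines = ["cluster_id,centroid_id,member_id,threshold,domain_labels"]
    for c in clusters:
        thr = "" if c.threshold is None else repr(c.threshold)
        doms = ";".join(c.domain_labels)
        for pid in c.member_ids:
            lines.append(f"{c.cluster_id},{c.centroid_id},{pid},{thr},{doms}")
    return "\n".join(lines) + "\n"
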