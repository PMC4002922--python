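"""Alignment-free virome comparison through k-mer word usage.

Most virome reads match nothing in reference databases, so whole-dataset
signatures matter: short-word (di-, tri-, tetranucleotide) usage is a
community fingerprint that separates samples without any alignment.
Profiles come in two flavors: plain ``frequency`` (word counts over
total windows) and ``bias``, the observed/expected ratio under a
zero-order (mononucleotide) null — the standard word-usage-deviation
construction, where 1 means no bias. Viromes are compared by euclidean
distance between profiles, then summarized by average-linkage
hierarchical clustering or non-metric multidimensional scaling (NMDS).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .errors import DataError, UsageError
from .records import SequenceRecord

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

NMDS_RESTARTS = 20


def kmer_words(k: int) -> list[str]:
    """All k-mers over ACGT in lexicographic order."""
    return ["".join(p) for p in product("ACGT", repeat=k)]


@dataclass(frozen=True)
class KmerProfile:
    """Per-virome k-mer vector, length 4^k, lexicographic word order."""

    virome_id: str
    k: int
    mode: str
    vector: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.vector, index=kmer_words(self.k), name=self.virome_id)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between viromes."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise DataError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise DataError("invalid distance matrix")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))


def _count_kmers(sequences: Sequence[SequenceRecord], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pooled overlapping k-mer counts (windows containing N skipped) and
    mononucleotide counts over all sequences."""
    kmer_counts = np.zeros(4 ** k, dtype=np.int64)
    mono_counts = np.zeros(4, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1)
    for rec in sequences:
        codes = _CODE[np.frombuffer(rec.residues.encode(), dtype=np.uint8)]
        valid_mono = codes >= 0
        mono_counts += np.bincount(codes[valid_mono], minlength=4)
        if codes.size < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        ok = (windows >= 0).all(axis=1)
        if not ok.any():
            continue
        idx = windows[ok] @ powers
        kmer_counts += np.bincount(idx, minlength=4 ** k)
    return kmer_counts, mono_counts


def kmer_profile(
    sequences: Sequence[SequenceRecord],
    k: int,
    mode: str = "bias",
    virome_id: str = "virome",
) -> KmerProfile:
    """Compute the pooled k-mer profile of a virome.

    ``frequency``: counts / total windows. ``bias``: frequency divided
    by the product of the mononucleotide frequencies of the word's
    letters (observed/expected; 0 where the expectation is 0). Counts
    are pooled over all sequences, forward strand.
    """
    if k not in (2, 3, 4):
        raise UsageError(f"k must be 2, 3 or 4, got {k}")
    if mode not in ("frequency", "bias"):
        raise UsageError(f"unknown profile mode: {mode!r}")
    if not sequences:
        raise UsageError("no sequences given")
    counts, mono = _count_kmers(sequences, k)
    total = counts.sum()
    freq = counts / total if total else counts.astype(float)
    if mode == "frequency":
        return KmerProfile(virome_id, k, mode, freq)
    mono_total = mono.sum()
    mono_freq = mono / mono_total if mono_total else mono.astype(float)
    # expected frequency of each word under the zero-order null
    digits = np.array(
        [[(i // 4 ** p) % 4 for p in range(k - 1, -1, -1)] for i in range(4 ** k)]
    )
    expected = np.prod(mono_freq[digits], axis=1)
    bias = np.zeros_like(freq)
    nonzero = expected > 0
    bias[nonzero] = freq[nonzero] / expected[nonzero]
    return KmerProfile(virome_id, k, "bias", bias)


def profile_distances(profiles: Sequence[KmerProfile]) -> DistanceMatrix:
    """Pairwise euclidean distances between virome profiles."""
    if len(profiles) < 2:
        raise UsageError("need at least two profiles")
    ks = {p.k for p in profiles}
    modes = {p.mode for p in profiles}
    if len(ks) > 1 or len(modes) > 1:
        raise UsageError(f"mixed profiles: k={sorted(ks)}, mode={sorted(modes)}")
    matrix = np.vstack([p.vector for p in profiles])
    values = squareform(pdist(matrix, metric="euclidean"))
    return DistanceMatrix(tuple(p.virome_id for p in profiles), values)


@dataclass(frozen=True)
class Ordination:
    """Result of summarizing a distance matrix.

    ``hclust``: ``merges`` holds the scipy linkage matrix and ``tree``
    a nested-parenthesis (newick) rendering. ``nmds``: ``coordinates``
    holds the 2-d embedding and ``stress`` the final normalized stress.
    """

    method: str
    labels: tuple[str, ...]
    merges: np.ndarray | None = None
    tree: str | None = None
    coordinates: pd.DataFrame | None = None
    stress: float | None = None


def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    return f"({left},{right}):{node.dist:.6g}"


def ordinate(matrix: DistanceMatrix, method: str = "nmds", seed: int = 0) -> Ordination:
    """Summarize a distance matrix by hierarchical clustering or NMDS.

    ``hclust`` uses average linkage; the smallest pairwise distance is
    always the first merge. ``nmds`` embeds in two dimensions, best of
    ``NMDS_RESTARTS`` seeded random starts, reporting normalized stress.
    """
    if method == "hclust":
        merges = linkage(matrix.condensed(), method="average")
        tree = _newick(to_tree(merges), list(matrix.labels)) + ";"
        return Ordination("hclust", matrix.labels, merges=merges, tree=tree)
    if method == "nmds":
        n = len(matrix.labels)
        if n < 3:
            raise UsageError(f"nmds needs at least 3 viromes, got {n}")
        model = MDS(
            n_components=2,
            metric_mds=False,
            metric="precomputed",
            n_init=NMDS_RESTARTS,
            init="random",
            random_state=seed,
            normalized_stress=True,
            max_iter=500,
        )
        coords = model.fit_transform(matrix.values)
        frame = pd.DataFrame(coords, index=list(matrix.labels), columns=["NMDS1", "NMDS2"])
        return Ordination("nmds", matrix.labels, coordinates=frame,
                          stress=float(model.stress_))
    raise UsageError(f"unknown ordination method: {method!r}")


def profile_matrix(profiles: Sequence[KmerProfile]) -> pd.DataFrame:
    """Viromes-by-words profile matrix for CSV export."""
    return pd.DataFrame([p.as_series() for p in profiles])
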