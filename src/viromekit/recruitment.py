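"""Fragment recruitment plots against a chosen reference genome.

Every read whose *best* hit lands on the selected genome is "recruited"
by it; a recruitment plot shows where on the genome the reads fall and
how similar they are. The data layer here produces the scatter points
(one per read: position, percent identity) and per-500-nt histogram
counts, kept per virome so several datasets can be stacked in one plot.
A read's position is the midpoint of its subject alignment interval, so
each read occupies exactly one bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError
from .records import Hit

BIN_WIDTH_NT = 500
#: Convenience cutoff used when listing viromes worth stacking: only
#: datasets with more than this many recruited reads are kept by default.
MIN_RECRUITED_DEFAULT = 200


@dataclass(frozen=True)
class RecruitmentPoint:
    virome_id: str
    position: int       # 1-based nt on the reference genome
    identity: float     # percent


def recruit(
    best_hits_by_virome: Mapping[str, Mapping[str, Hit | None]],
    genome_id: str,
) -> list[RecruitmentPoint]:
    """Collect recruitment points for one reference genome.

    ``best_hits_by_virome`` maps virome id to its per-read best hits
    (:func:`viromekit.affiliation.best_hits_by_query` output). A read
    contributes a point only when its best hit subject is ``genome_id``;
    reads whose best hit is another genome are excluded even if they
    have a weaker hit here. The position is the floor midpoint of the
    strand-normalized subject interval.
    """
    points: list[RecruitmentPoint] = []
    for virome_id, best in best_hits_by_virome.items():
        for read_id in sorted(best):
            hit = best[read_id]
            if hit is None or hit.subject_id != genome_id:
                continue
            lo = min(hit.s_start, hit.s_end)
            hi = max(hit.s_start, hit.s_end)
            points.append(RecruitmentPoint(virome_id, (lo + hi) // 2,
                                           hit.percent_identity))
    return points


def n_bins(genome_length: int, bin_width: int = BIN_WIDTH_NT) -> int:
    return ceil(genome_length / bin_width)


def bin_histogram(
    points: Sequence[RecruitmentPoint],
    genome_length: int,
    viromes_selected: Iterable[str] | None = None,
    bin_width: int = BIN_WIDTH_NT,
) -> dict[tuple[str, int], int]:
    """Per-virome histogram of recruited reads in ``bin_width``-nt bins.

    Bin ``i`` covers positions ``[i*w + 1, (i+1)*w]``; the last bin
    covers the genome remainder. Counts are conserved: per virome they
    sum to the number of that virome's points.
    """
    selected = None if viromes_selected is None else set(viromes_selected)
    bins: dict[tuple[str, int], int] = {}
    for pt in points:
        if selected is not None and pt.virome_id not in selected:
            continue
        if pt.position > genome_length:
            raise DataError(
                f"recruited position {pt.position} beyond genome length {genome_length}"
            )
        if pt.position < 1:
            raise DataError(f"recruited position {pt.position} < 1")
        idx = (pt.position - 1) // bin_width
        bins[(pt.virome_id, idx)] = bins.get((pt.virome_id, idx), 0) + 1
    return bins


def select_viromes(
    points: Sequence[RecruitmentPoint],
    min_recruited: int = MIN_RECRUITED_DEFAULT,
) -> list[str]:
    """Viromes with more than ``min_recruited`` recruited reads, sorted."""
    counts: dict[str, int] = {}
    for pt in points:
        counts[pt.virome_id] = counts.get(pt.virome_id, 0) + 1
    return sorted(v for v, c in counts.items() if c > min_recruited)


@dataclass(frozen=True)
class RecruitmentPlot:
    """Assembled recruitment-plot data for one reference genome."""

    genome_id: str
    genome_length: int
    points: tuple[RecruitmentPoint, ...]
    bins: Mapping[tuple[str, int], int]

    @classmethod
    def build(
        cls,
        best_hits_by_virome: Mapping[str, Mapping[str, Hit | None]],
        genome_id: str,
        genome_length: int,
        viromes_selected: Iterable[str] | None = None,
    ) -> "RecruitmentPlot":
        points = recruit(best_hits_by_virome, genome_id)
        if viromes_selected is not None:
            selected = set(viromes_selected)
            points = [p for p in points if p.virome_id in selected]
        return cls(genome_id, genome_length, tuple(points),
                   bin_histogram(points, genome_length))

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.virome_id, p.position, p.identity) for p in self.points],
            columns=["virome_id", "position", "identity"],
        )

    def histogram_frame(self, bin_width: int = BIN_WIDTH_NT) -> pd.DataFrame:
        rows = []
        for (virome_id, idx), count in sorted(self.bins.items()):
            start = idx * bin_width + 1
            end = min((idx + 1) * bin_width, self.genome_length)
            rows.append((virome_id, start, end, count))
        return pd.DataFrame(rows, columns=["virome_id", "bin_start", "bin_end", "count"])


def plot_figure(plot: RecruitmentPlot):
    """Optional static rendering (scatter over stacked histogram).

    Requires matplotlib; returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_scatter, ax_hist) = plt.subplots(
        2, 1, sharex=True, figsize=(10, 6),
        gridspec_kw={"height_ratios": [2, 1]},
    )
    viromes = sorted({p.virome_id for p in plot.points})
    cmap = plt.get_cmap("tab10")
    bottom = [0] * n_bins(plot.genome_length)
    for vi, virome in enumerate(viromes):
        pts = [p for p in plot.points if p.virome_id == virome]
        ax_scatter.scatter([p.position for p in pts], [p.identity for p in pts],
                           s=6, color=cmap(vi % 10), label=virome)
        heights = [plot.bins.get((virome, b), 0) for b in range(len(bottom))]
        ax_hist.bar(
            [b * BIN_WIDTH_NT + BIN_WIDTH_NT / 2 for b in range(len(bottom))],
            heights, width=BIN_WIDTH_NT * 0.9, bottom=bottom,
            color=cmap(vi % 10),
        )
        bottom = [b + h for b, h in zip(bottom, heights)]
    ax_scatter.set_ylabel("% identity")
    ax_scatter.legend(fontsize=7)
    ax_hist.set_ylabel("reads / 500 nt")
    ax_hist.set_xlabel(f"position on {plot.genome_id} (nt)")
    fig.tight_layout()
    return fig
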