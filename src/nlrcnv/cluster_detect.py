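"""Windowed NLR cluster detection.

NLR genes are counted in non-overlapping 1-Mbp windows tiled from
coordinate 1 on each chromosome; a gene is assigned to the window holding
the majority (>50%) of its span (an exact 50/50 split goes to the left
window so every gene is counted once).  Adjacent occupied windows are
merged to a fixpoint — equivalently, maximal runs of consecutive non-empty
windows — and merged runs holding at least ``min_size`` (default 3) NLRs
are called clusters.

Unplaced scaffolds ("Chr0") are excluded from clustering: window adjacency
is meaningless on unordered sequence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from nlrcnv.io_formats import GeneModel

DEFAULT_WINDOW = 1_000_000
UNPLACED = "Chr0"


@dataclass
class WindowGrid:
    chrom: str
    window_size: int = DEFAULT_WINDOW
    counts: dict[int, list[str]] = field(default_factory=dict)


@dataclass
class NLRCluster:
    cluster_id: str
    genotype: str
    chrom: str
    window_span: tuple[int, int]
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)

    def span_bp(self, window_size: int = DEFAULT_WINDOW) -> tuple[int, int]:
        """1-based inclusive bp span of the merged windows."""
        first, last = self.window_span
        return first * window_size + 1, (last + 1) * window_size


def majority_window(gene: GeneModel, window_size: int) -> int:
    """Index of the window holding the majority of the gene's span.

    Windows tile [k*W+1, (k+1)*W].  For a gene covering several windows the
    window with the largest overlap wins; ties go to the lower index.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    w_first = (gene.start - 1) // window_size
    w_last = (gene.end - 1) // window_size
    best_w, best_ov = w_first, -1
    for w in range(w_first, w_last + 1):
        lo = max(gene.start, w * window_size + 1)
        hi = min(gene.end, (w + 1) * window_size)
        ov = hi - lo + 1
        if ov > best_ov:
            best_w, best_ov = w, ov
    return best_w


def assign_windows(
    nlrs: Iterable[GeneModel],
    window_size: int = DEFAULT_WINDOW,
    include_unplaced: bool = False,
) -> dict[str, WindowGrid]:
    """Assign each NLR gene to exactly one window per the majority rule."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    grids: dict[str, WindowGrid] = {}
    for g in nlrs:
        if g.chrom == UNPLACED and not include_unplaced:
            continue
        grid = grids.setdefault(g.chrom, WindowGrid(chrom=g.chrom, window_size=window_size))
        grid.counts.setdefault(majority_window(g, window_size), []).append(g.gene_id)
    return grids


def merge_windows(grid: WindowGrid) -> list[tuple[int, int, list[str]]]:
    """Maximal runs of consecutive occupied windows — the fixpoint of
    repeated pairwise merging of adjacent occupied windows.

    Returns (first_index, last_index, member gene ids) per run, member
    lists concatenated in window order.
    """
    runs: list[tuple[int, int, list[str]]] = []
    for w in sorted(grid.counts):
        if runs and w == runs[-1][1] + 1:
            first, _, members = runs[-1]
            runs[-1] = (first, w, members + grid.counts[w])
        else:
            runs.append((w, w, list(grid.counts[w])))
    return runs


def call_clusters(
    runs: Iterable[tuple[int, int, list[str]]],
    genotype: str,
    chrom: str,
    min_size: int = 3,
) -> list[NLRCluster]:
    """Merged runs with >= min_size members become clusters."""
    return [
        NLRCluster(
            cluster_id=f"{genotype}:{chrom}:{first}",
            genotype=genotype,
            chrom=chrom,
            window_span=(first, last),
            members=members,
        )
        for first, last, members in runs
        if len(members) >= min_size
    ]


def detect_clusters(
    nlrs: Iterable[GeneModel],
    genotype: str,
    window_size: int = DEFAULT_WINDOW,
    min_size: int = 3,
) -> list[NLRCluster]:
    """assign_windows -> merge_windows -> call_clusters over one genotype."""
    clusters: list[NLRCluster] = []
    for chrom, grid in sorted(assign_windows(nlrs, window_size).items()):
        clusters.extend(call_clusters(merge_windows(grid), genotype, chrom, min_size))
    return clusters


def cluster_summary(
    clusters: Iterable[NLRCluster],
) -> dict[str, tuple[int, Optional[float]]]:
    """Per-genotype (cluster count, mean size); mean is None with no clusters."""
    by_gt: dict[str, list[int]] = defaultdict(list)
    for c in clusters:
        by_gt[c.genotype].append(c.size)
    return {
        gt: (len(sizes), sum(sizes) / len(sizes) if sizes else None)
        for gt, sizes in by_gt.items()
    }


def write_cluster_bed(clusters: Iterable[NLRCluster], path, window_size: int = DEFAULT_WINDOW) -> None:
    """BED track (0-based half-open) of cluster spans."""
    with open(path, "w") as fh:
        for c in clusters:
            start1, end1 = c.span_bp(window_size)
            fh.write(f"{c.chrom}\t{start1 - 1}\t{end1}\t{c.cluster_id}\t{c.size}\n")
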