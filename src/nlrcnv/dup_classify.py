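"""Duplicate-gene classification and collinear-block chaining.

Genes are ordered along each chromosome and every gene receives exactly one
duplication type, with precedence

    wgd_segmental > tandem > proximal > dispersed > singleton

where: anchors of a collinear block are WGD/segmental duplicates; a gene
with a same-chromosome similarity partner at rank distance 1 is a tandem
duplicate; at rank distance 2..proximal_max (default 20) a proximal
duplicate; any other partner makes it dispersed; no partner, a singleton.

Collinear blocks are found by dynamic-programming chaining of similarity
hits mapped to rank coordinates, in the spirit of MCScanX: a chain extends
through points whose rank increments on both genomes are positive (or
consistently negative on the second genome, for inverted blocks) and at
most ``max_gaps``; chains of at least ``match_size`` anchor pairs are
reported, extracted greedily by descending score.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

from nlrcnv.io_formats import GeneModel, SimilarityHit

logger = logging.getLogger(__name__)

DUP_TYPES = ("singleton", "dispersed", "proximal", "tandem", "wgd_segmental")


@dataclass(frozen=True)
class RankedGene:
    gene_id: str
    chrom: str
    rank: int
    start: int
    end: int


@dataclass(frozen=True)
class CollinearParams:
    match_score: float = 50.0
    gap_penalty: float = -1.0
    match_size: int = 5
    max_gaps: int = 20
    evalue_cut: float = 1e-10

    def __post_init__(self) -> None:
        if self.match_size < 2:
            raise ValueError("match_size must be >= 2")
        if self.max_gaps < 1:
            raise ValueError("max_gaps must be >= 1")


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]
    orientation: str  # "same" | "inverted"
    score: float


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    dup_type: str


# ---------------------------------------------------------------------------


def rank_genes(genes: Iterable[GeneModel]) -> list[RankedGene]:
    """Sort one genotype's genes by (chrom, start, end, gene_id) and assign
    0-based ranks within each chromosome."""
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    seen: set[str] = set()
    ranked: list[RankedGene] = []
    counter: dict[str, int] = defaultdict(int)
    for g in ordered:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)
        ranked.append(
            RankedGene(
                gene_id=g.gene_id,
                chrom=g.chrom,
                rank=counter[g.chrom],
                start=g.start,
                end=g.end,
            )
        )
        counter[g.chrom] += 1
    return ranked


def _filter_hits(
    hits: Iterable[SimilarityHit],
    known: set[str],
    evalue_cut: float,
) -> list[SimilarityHit]:
    out = []
    for h in hits:
        if h.query_id == h.subject_id or h.evalue > evalue_cut:
            continue
        if h.query_id not in known or h.subject_id not in known:
            logger.warning("similarity hit references unknown gene; skipped")
            continue
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# collinear chaining
# ---------------------------------------------------------------------------


def _chain_points(
    points: list[tuple[int, int, str, str]],
    p: CollinearParams,
    orientation: str,
) -> list[tuple[list[int], float]]:
    """All-pairs DP over rank points (ra, rb, ga, gb); returns candidate
    chains (index lists, scores) from every end point, best-first."""
    sign = 1 if orientation == "same" else -1
    pts = sorted(range(len(points)), key=lambda i: (points[i][0], sign * points[i][1]))
    best_score = [p.match_score] * len(points)
    back: list[int | None] = [None] * len(points)
    best_len = [1] * len(points)
    for ii, i in enumerate(pts):
        ra, rb, _, _ = points[i]
        for j in pts[:ii]:
            qa, qb, _, _ = points[j]
            da = ra - qa
            db = (rb - qb) * sign
            if 0 < da <= p.max_gaps and 0 < db <= p.max_gaps:
                gap = (da - 1) + (db - 1)
                cand = best_score[j] + p.match_score + p.gap_penalty * gap
                if cand > best_score[i] or (
                    cand == best_score[i] and best_len[j] + 1 > best_len[i]
                ):
                    best_score[i] = cand
                    back[i] = j
                    best_len[i] = best_len[j] + 1
    chains = []
    for i in range(len(points)):
        if best_len[i] >= p.match_size:
            idx = []
            k: int | None = i
            while k is not None:
                idx.append(k)
                k = back[k]
            idx.reverse()
            chains.append((idx, best_score[i]))
    chains.sort(key=lambda c: (-c[1], [points[i][:2] for i in c[0]]))
    return chains


def find_collinear_blocks(
    hits: Iterable[SimilarityHit],
    ranks: list[RankedGene],
    p: CollinearParams = CollinearParams(),
) -> list[CollinearBlock]:
    """Chain similarity hits into collinear blocks of >= match_size anchors.

    A hit consumed by one reported block is not reused in another (greedy
    extraction by descending score).  Within-chromosome blocks are allowed
    only when the two rank intervals do not overlap.
    """
    rank_of = {r.gene_id: (r.chrom, r.rank) for r in ranks}
    hits = _filter_hits(list(hits), set(rank_of), p.evalue_cut)

    # map hits to rank points per unordered chromosome pair, deduplicated
    by_pair: dict[tuple[str, str], set[tuple[int, int, str, str]]] = defaultdict(set)
    for h in hits:
        ca, ra = rank_of[h.query_id]
        cb, rb = rank_of[h.subject_id]
        ga, gb = h.query_id, h.subject_id
        if (cb, rb, gb) < (ca, ra, ga):
            (ca, ra, ga), (cb, rb, gb) = (cb, rb, gb), (ca, ra, ga)
        by_pair[(ca, cb)].add((ra, rb, ga, gb))

    blocks: list[CollinearBlock] = []
    for (ca, cb), ptset in sorted(by_pair.items()):
        remaining = sorted(ptset)
        while True:
            candidates = []
            for orient in ("same", "inverted"):
                for idx, score in _chain_points(remaining, p, orient):
                    candidates.append((score, orient, idx))
            candidates.sort(key=lambda c: -c[0])
            accepted = None
            for score, orient, idx in candidates:
                pts = [remaining[i] for i in idx]
                if ca == cb:
                    a_lo, a_hi = min(q[0] for q in pts), max(q[0] for q in pts)
                    b_lo, b_hi = min(q[1] for q in pts), max(q[1] for q in pts)
                    if not (a_hi < b_lo or b_hi < a_lo):
                        continue  # overlapping rank intervals on one chromosome
                accepted = (score, orient, idx, pts)
                break
            if accepted is None:
                break
            score, orient, idx, pts = accepted
            blocks.append(
                CollinearBlock(
                    chrom_a=ca,
                    chrom_b=cb,
                    anchors=[(q[2], q[3]) for q in pts],
                    orientation=orient,
                    score=score,
                )
            )
            used = set(idx)
            remaining = [q for i, q in enumerate(remaining) if i not in used]
            if len(remaining) < p.match_size:
                break
    return blocks


# ---------------------------------------------------------------------------
# duplicate classification
# ---------------------------------------------------------------------------


def classify_duplicates(
    ranks: list[RankedGene],
    hits: Iterable[SimilarityHit],
    blocks: Iterable[CollinearBlock],
    evalue_cut: float = 1e-10,
    proximal_max: int = 20,
) -> list[DuplicationCall]:
    """Assign one duplication type per gene (precedence wgd_segmental >
    tandem > proximal > dispersed > singleton)."""
    rank_of = {r.gene_id: (r.chrom, r.rank) for r in ranks}
    hits = _filter_hits(list(hits), set(rank_of), evalue_cut)

    partners: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        partners[h.query_id].add(h.subject_id)
        partners[h.subject_id].add(h.query_id)

    anchors: set[str] = set()
    for b in blocks:
        for ga, gb in b.anchors:
            anchors.add(ga)
            anchors.add(gb)

    calls = []
    for r in ranks:
        if r.gene_id in anchors:
            dup = "wgd_segmental"
        else:
            ps = partners.get(r.gene_id, set())
            if not ps:
                dup = "singleton"
            else:
                dists = [
                    abs(rank_of[q][1] - r.rank)
                    for q in ps
                    if rank_of[q][0] == r.chrom
                ]
                if any(d == 1 for d in dists):
                    dup = "tandem"
                elif any(2 <= d <= proximal_max for d in dists):
                    dup = "proximal"
                else:
                    dup = "dispersed"
        calls.append(DuplicationCall(gene_id=r.gene_id, dup_type=dup))
    return calls
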