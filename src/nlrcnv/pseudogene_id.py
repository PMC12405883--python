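"""Pseudogene identification from pseudoexon evidence.

Candidate pseudoexons are protein-vs-genome similarity hits for NLR
proteins.  The pipeline (i) keeps non-genic hits longer than 30 aa and
above 40% identity with no significant (e < 1e-5) repeat-library match,
(ii) links surviving pseudoexons of the same best-hit parent NLR into
contigs when the genomic gap between consecutive fragments is inside the
99th percentile of the genotype's intron-length distribution, and (iii)
retains only contigs whose 6-frame translation carries at least one common
NLR domain (LRR/NB-ARC/TIR/RPW8/CC Pfam families).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
from intervaltree import IntervalTree

from nlrcnv.io_formats import GeneModel, PseudoexonHit

logger = logging.getLogger(__name__)

#: Pfam families counted as "common" NLR domains for contig confirmation.
COMMON_NLR_DOMAINS = frozenset(
    {
        "PF00560", "PF07725", "PF12799", "PF13855",  # LRR
        "PF00931",  # NB-ARC
        "PF01582", "PF13676",  # TIR
        "PF05659",  # RPW8
        "PF18052",  # CC (Rx N-terminal)
    }
)


@dataclass(frozen=True)
class PseudoFilter:
    """Thresholds of the pseudogene pipeline.

    aa-length and identity gates are exclusive (a 30-aa or 40.0%-identity
    hit is removed); the repeat gate is strict-less-than; the candidate
    e-value gate is applied upstream by the similarity search.
    """

    cand_evalue: float = 1e-20
    min_aa_len: int = 30
    min_identity: float = 40.0
    repeat_evalue: float = 1e-5
    intron_quantile: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.intron_quantile < 1:
            raise ValueError("intron_quantile must be in (0, 1)")


@dataclass
class PseudogeneContig:
    contig_id: str
    genotype: str
    chrom: str
    span: tuple[int, int]
    pseudoexons: list[PseudoexonHit]
    parent_protein: str
    domains_found: set[str] = field(default_factory=set)
    passed_domain_filter: bool = False

    @property
    def n_exons(self) -> int:
        return len(self.pseudoexons)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def pseudoexon_locus_id(h: PseudoexonHit) -> str:
    """Stable identifier for a pseudoexon's genomic locus, used to join the
    repeat-library hit table."""
    return f"{h.chrom}:{h.g_start}-{h.g_end}"


def filter_candidates(
    hits: Iterable[PseudoexonHit],
    genes: Iterable[GeneModel],
    repeats: Iterable[tuple[str, float]],
    f: PseudoFilter = PseudoFilter(),
) -> tuple[list[PseudoexonHit], Counter]:
    """Apply the non-genic / length / identity / repeat filters.

    ``repeats`` pairs pseudoexon locus ids (see ``pseudoexon_locus_id``)
    with repeat-library e-values.

    Returns the surviving hits and a Counter of removal reasons (the first
    failing criterion per hit, in order genic > short > low_identity >
    repeat); reason counts sum to input - output.
    """
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        # interval tree uses half-open coords; +1 converts inclusive end
        trees[(g.genotype, g.chrom)].addi(g.start, g.end + 1, g.gene_id)

    repeat_evalues: dict[str, float] = {}
    for hid, ev in repeats:
        repeat_evalues[hid] = min(ev, repeat_evalues.get(hid, np.inf))

    kept: list[PseudoexonHit] = []
    reasons: Counter = Counter()
    for h in hits:
        if trees[(h.genotype, h.chrom)].overlap(h.g_start, h.g_end + 1):
            reasons["genic"] += 1
            continue
        if h.aa_len <= f.min_aa_len:
            reasons["short"] += 1
            continue
        if h.pct_identity <= f.min_identity:
            reasons["low_identity"] += 1
            continue
        if repeat_evalues.get(pseudoexon_locus_id(h), np.inf) < f.repeat_evalue:
            reasons["repeat"] += 1
            continue
        kept.append(h)
    return kept, reasons


# ---------------------------------------------------------------------------
# intron-length quantile
# ---------------------------------------------------------------------------


def intron_q99(genes: Iterable[GeneModel], q: float = 0.99) -> float:
    """q-th empirical quantile (linear interpolation) of all intron lengths
    pooled across the genotype's annotated genes."""
    lengths = [l for g in genes for l in g.intron_lengths()]
    if not lengths:
        raise ValueError(
            "annotation contains no introns; configure an explicit gap limit"
        )
    return float(np.quantile(lengths, q, method="linear"))


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------


def best_hit_parents(hits: Iterable[PseudoexonHit]) -> list[PseudoexonHit]:
    """Resolve overlapping same-locus hits to their best parent: for hits at
    identical genomic intervals keep the lowest e-value (ties: highest
    identity, then lexicographic parent id)."""
    by_locus: dict[tuple, list[PseudoexonHit]] = defaultdict(list)
    for h in hits:
        by_locus[(h.genotype, h.chrom, h.g_start, h.g_end)].append(h)
    out = []
    for locus_hits in by_locus.values():
        out.append(
            min(locus_hits, key=lambda h: (h.evalue, -h.pct_identity, h.parent_protein))
        )
    return out


def link_pseudoexons(
    exons: Iterable[PseudoexonHit],
    q99: float,
    min_exons: int = 1,
) -> list[PseudogeneContig]:
    """Chain pseudoexons into pseudogene contigs.

    Within each (genotype, chromosome, parent) group, hits are sorted by
    genomic start; overlapping same-parent hits are merged (span union,
    logged); consecutive fragments are chained while the gap
    (next.g_start - prev.g_end - 1) is <= q99.  Maximal chains with at
    least ``min_exons`` fragments become contigs.
    """
    groups: dict[tuple[str, str, str], list[PseudoexonHit]] = defaultdict(list)
    for h in exons:
        groups[(h.genotype, h.chrom, h.parent_protein)].append(h)

    contigs: list[PseudogeneContig] = []
    for (gt, chrom, parent), hs in sorted(groups.items()):
        hs = sorted(hs, key=lambda h: (h.g_start, h.g_end))
        merged: list[PseudoexonHit] = []
        for h in hs:
            if merged and h.g_start <= merged[-1].g_end:
                prev = merged[-1]
                logger.info(
                    "merged overlapping pseudoexons of %s at %s:%d", parent, chrom, h.g_start
                )
                merged[-1] = replace(
                    prev,
                    g_end=max(prev.g_end, h.g_end),
                    aa_len=max(prev.aa_len, h.aa_len),
                    pct_identity=max(prev.pct_identity, h.pct_identity),
                    evalue=min(prev.evalue, h.evalue),
                )
            else:
                merged.append(h)
        chain: list[PseudoexonHit] = []
        chains: list[list[PseudoexonHit]] = []
        for h in merged:
            if chain and (h.g_start - chain[-1].g_end - 1) > q99:
                chains.append(chain)
                chain = []
            chain.append(h)
        if chain:
            chains.append(chain)
        for c in chains:
            if len(c) < min_exons:
                continue
            contigs.append(
                PseudogeneContig(
                    contig_id=f"{gt}:{chrom}:{c[0].g_start}:{parent}",
                    genotype=gt,
                    chrom=chrom,
                    span=(c[0].g_start, c[-1].g_end),
                    pseudoexons=c,
                    parent_protein=parent,
                )
            )
    contigs.sort(key=lambda c: (c.genotype, c.chrom, c.span))
    return contigs


# ---------------------------------------------------------------------------
# domain confirmation and summary
# ---------------------------------------------------------------------------


def domain_confirm(
    contigs: Iterable[PseudogeneContig],
    translated_domain_hits: Iterable[tuple[str, str]],
    common: frozenset[str] = COMMON_NLR_DOMAINS,
) -> list[PseudogeneContig]:
    """Keep contigs whose 6-frame translation hit at least one common NLR
    domain; contigs with no translation record are treated as domainless."""
    by_contig: dict[str, set[str]] = defaultdict(set)
    for cid, acc in translated_domain_hits:
        by_contig[cid].add(acc)
    kept = []
    for c in contigs:
        c.domains_found = by_contig.get(c.contig_id, set())
        c.passed_domain_filter = bool(c.domains_found & common)
        if c.passed_domain_filter:
            kept.append(c)
    return kept


def pseudogene_parent_ratio(
    pseudogenes: Iterable[PseudogeneContig],
) -> dict[str, tuple[int, int, Optional[float]]]:
    """Per-genotype (n_pseudogenes, n_distinct_parents, ratio).

    The ratio (pseudogenes per parent NLR) is None when a genotype has no
    parents; report it rounded to 1 decimal for display.
    """
    by_gt: dict[str, list[PseudogeneContig]] = defaultdict(list)
    for p in pseudogenes:
        by_gt[p.genotype].append(p)
    out = {}
    for gt, ps in by_gt.items():
        parents = {p.parent_protein for p in ps}
        ratio = len(ps) / len(parents) if parents else None
        out[gt] = (len(ps), len(parents), ratio)
    return out


def write_pseudogene_gff3(contigs: Iterable[PseudogeneContig], path) -> None:
    """Write pseudogene/pseudogenic_exon features with Parent_NLR attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in sorted(contigs, key=lambda c: (c.genotype, c.chrom, c.span)):
            fh.write(
                f"{c.chrom}\tnlrcnv\tpseudogene\t{c.span[0]}\t{c.span[1]}\t.\t.\t.\t"
                f"ID={c.contig_id};Parent_NLR={c.parent_protein};genotype={c.genotype}\n"
            )
            for i, e in enumerate(c.pseudoexons, 1):
                fh.write(
                    f"{c.chrom}\tnlrcnv\tpseudogenic_exon\t{e.g_start}\t{e.g_end}\t.\t.\t.\t"
                    f"ID={c.contig_id}.e{i};Parent={c.contig_id}\n"
                )
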