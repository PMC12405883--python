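"""Gene ranking, collinear chaining, and duplicate-type rules vs oracles."""

import itertools

import numpy as np
import pytest

from nlrcnv.dup_classify import (
    CollinearParams,
    DuplicationCall,
    classify_duplicates,
    find_collinear_blocks,
    rank_genes,
)
from nlrcnv.io_formats import SimilarityHit
from tests.conftest import gene


def hit(q, s, ev=1e-30):
    return SimilarityHit(q, s, 90.0, 100, ev, 1, 100, 1, 100)


def test_rank_genes_sorting_and_per_chrom_ranks():
    genes = [
        gene("a", "chr1", 100, 200),
        gene("b", "chr1", 50, 80),
        gene("c", "chr1", 200, 300),
        gene("d", "chr2", 10, 20),
    ]
    ranked = {r.gene_id: (r.chrom, r.rank) for r in rank_genes(genes)}
    assert ranked == {"b": ("chr1", 0), "a": ("chr1", 1), "c": ("chr1", 2), "d": ("chr2", 0)}


def test_rank_genes_duplicate_id_rejected():
    with pytest.raises(ValueError):
        rank_genes([gene("a", "c", 1, 2), gene("a", "c", 5, 9)])


def _two_chrom_layout(n=8):
    genes = [gene(f"a{i}", "chrA", 1000 * i + 1, 1000 * i + 500) for i in range(n)]
    genes += [gene(f"b{i}", "chrB", 1000 * i + 1, 1000 * i + 500) for i in range(n)]
    return rank_genes(genes)


def _oracle_best_chain(points, match_size, max_gaps, match_score=50, gap_penalty=-1):
    """Exhaustive chain enumeration over every subsequence (small n only)."""
    best = None
    idxs = range(len(points))
    for r in range(match_size, len(points) + 1):
        for combo in itertools.combinations(idxs, r):
            pts = sorted((points[i] for i in combo))
            das = [pts[k + 1][0] - pts[k][0] for k in range(len(pts) - 1)]
            dbs = [pts[k + 1][1] - pts[k][1] for k in range(len(pts) - 1)]
            for sign in (1, -1):
                if all(0 < da <= max_gaps for da in das) and all(
                    0 < sign * db <= max_gaps for db in dbs
                ):
                    score = match_score * len(pts) + gap_penalty * sum(
                        (da - 1) + (abs(db) - 1) for da, db in zip(das, dbs)
                    )
                    if best is None or score > best[0]:
                        best = (score, len(pts), sign)
    return best


def test_planted_collinear_block_same_orientation():
    ranks = _two_chrom_layout(8)
    hits = [hit(f"a{i+1}", f"b{i+1}") for i in range(6)]
    blocks = find_collinear_blocks(hits, ranks)
    assert len(blocks) == 1
    b = blocks[0]
    assert len(b.anchors) == 6 and b.orientation == "same"
    oracle = _oracle_best_chain([(i + 1, i + 1) for i in range(6)], 5, 20)
    assert b.score == oracle[0] and len(b.anchors) == oracle[1]


def test_planted_collinear_block_inverted():
    ranks = _two_chrom_layout(8)
    hits = [hit(f"a{i+1}", f"b{6-i}") for i in range(6)]
    blocks = find_collinear_blocks(hits, ranks)
    assert len(blocks) == 1
    assert blocks[0].orientation == "inverted"
    assert len(blocks[0].anchors) == 6


def test_four_pairs_below_match_size_no_block():
    ranks = _two_chrom_layout(8)
    hits = [hit(f"a{i}", f"b{i}") for i in range(4)]
    assert find_collinear_blocks(hits, ranks) == []


def test_chain_respects_max_gaps():
    # 5 pairs but one rank jump of 25 > max_gaps splits the chain
    genes = [gene(f"a{i}", "chrA", 1000 * i + 1, 1000 * i + 500) for i in range(40)]
    genes += [gene(f"b{i}", "chrB", 1000 * i + 1, 1000 * i + 500) for i in range(40)]
    ranks = rank_genes(genes)
    pairs = [(0, 0), (1, 1), (2, 2), (3, 3), (29, 29)]
    hits = [hit(f"a{i}", f"b{j}") for i, j in pairs]
    assert find_collinear_blocks(hits, ranks) == []


def test_within_chromosome_block_requires_disjoint_intervals():
    genes = [gene(f"g{i}", "chrA", 1000 * i + 1, 1000 * i + 500) for i in range(20)]
    ranks = rank_genes(genes)
    # planted duplicated run: ranks 0..4 vs 10..14
    hits = [hit(f"g{i}", f"g{i+10}") for i in range(5)]
    blocks = find_collinear_blocks(hits, ranks)
    assert len(blocks) == 1 and len(blocks[0].anchors) == 5
    # overlapping intervals (a tandem ladder) must not become a block
    ladder = [hit(f"g{i}", f"g{i+1}") for i in range(6)]
    assert find_collinear_blocks(ladder, ranks) == []


@pytest.mark.parametrize(
    "distance,expected",
    [(1, "tandem"), (2, "proximal"), (10, "proximal"), (20, "proximal"), (21, "dispersed")],
)
def test_rank_distance_boundaries(distance, expected):
    genes = [gene(f"g{i}", "chrA", 1000 * i + 1, 1000 * i + 500) for i in range(25)]
    ranks = rank_genes(genes)
    calls = {
        c.gene_id: c.dup_type
        for c in classify_duplicates(ranks, [hit("g0", f"g{distance}")], [])
    }
    assert calls["g0"] == expected and calls[f"g{distance}"] == expected
    assert calls["g1" if distance != 1 else "g2"] == "singleton"


def test_anchor_precedence_over_tandem():
    genes = [gene(f"g{i}", "chrA", 1000 * i + 1, 1000 * i + 500) for i in range(20)]
    ranks = rank_genes(genes)
    hits = [hit(f"g{i}", f"g{i+10}") for i in range(5)] + [hit("g0", "g1")]
    blocks = find_collinear_blocks(hits, ranks)
    calls = {c.gene_id: c.dup_type for c in classify_duplicates(ranks, hits, blocks)}
    assert calls["g0"] == "wgd_segmental"  # anchor wins over its tandem hit
    assert calls["g1"] == "wgd_segmental"


def _oracle_classify(ranks, hits, blocks, proximal_max=20):
    """Direct rule application, written independently of the classifier."""
    pos = {r.gene_id: (r.chrom, r.rank) for r in ranks}
    anchors = {g for b in blocks for pair in b.anchors for g in pair}
    partners = {}
    for h in hits:
        if h.evalue > 1e-10 or h.query_id == h.subject_id:
            continue
        partners.setdefault(h.query_id, set()).add(h.subject_id)
        partners.setdefault(h.subject_id, set()).add(h.query_id)
    out = {}
    for r in ranks:
        if r.gene_id in anchors:
            out[r.gene_id] = "wgd_segmental"
            continue
        same = [
            abs(pos[p][1] - r.rank)
            for p in partners.get(r.gene_id, ())
            if pos[p][0] == r.chrom
        ]
        if not partners.get(r.gene_id):
            out[r.gene_id] = "singleton"
        elif 1 in same:
            out[r.gene_id] = "tandem"
        elif any(2 <= d <= proximal_max for d in same):
            out[r.gene_id] = "proximal"
        else:
            out[r.gene_id] = "dispersed"
    return out


def test_classifier_equals_oracle_on_random_genomes():
    """1,000 random genomes of up to 200 genes, random hit graphs."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(5, 201))
        n_chrom = int(rng.integers(1, 4))
        genes = []
        for i in range(n):
            c = f"chr{rng.integers(n_chrom)}"
            s = int(rng.integers(1, 10_000_000))
            genes.append(gene(f"g{i}", c, s, s + 100))
        ranks = rank_genes(genes)
        n_hits = int(rng.integers(0, n))
        hits = []
        for _ in range(n_hits):
            a, b = rng.integers(n, size=2)
            if a == b:
                continue
            hits.append(hit(f"g{a}", f"g{b}", ev=10.0 ** -int(rng.integers(5, 40))))
        blocks = find_collinear_blocks(hits, ranks)
        calls = {c.gene_id: c.dup_type for c in classify_duplicates(ranks, hits, blocks)}
        assert calls == _oracle_classify(ranks, hits, blocks)


def test_calls_partition_gene_set(small_cohort):
    _, dataset = small_cohort
    for data in dataset:
        ranks = rank_genes(data.genes)
        blocks = find_collinear_blocks(data.similarity, ranks)
        calls = classify_duplicates(ranks, data.similarity, blocks)
        assert len(calls) == len(data.genes)
        assert {c.gene_id for c in calls} == {g.gene_id for g in data.genes}


def test_monotonicity_adding_hit_never_demotes():
    order = ["singleton", "dispersed", "proximal", "tandem", "wgd_segmental"]
    genes = [gene(f"g{i}", "chrA", 1000 * i + 1, 1000 * i + 500) for i in range(30)]
    ranks = rank_genes(genes)
    rng = np.random.default_rng(3)
    hits = []
    prev = {c.gene_id: c.dup_type for c in classify_duplicates(ranks, hits, [])}
    for _ in range(40):
        a, b = rng.integers(30, size=2)
        if a == b:
            continue
        hits.append(hit(f"g{a}", f"g{b}"))
        cur = {c.gene_id: c.dup_type for c in classify_duplicates(ranks, hits, [])}
        for gid in cur:
            assert order.index(cur[gid]) >= order.index(prev[gid])
        prev = cur
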