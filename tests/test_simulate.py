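"""Planted-truth recovery: the generator's contract with every stage."""

import filecmp

import numpy as np
import pytest

from nlrcnv import cluster_detect, dup_classify, nlr_classify, pseudogene_id
from nlrcnv.pipeline import evidence_from_data
from nlrcnv.simulate import (
    RegimeParams,
    SimConfig,
    simulate_dataset,
    simulate_genotype,
    write_genotype,
)


def run_classify(data):
    evidence = evidence_from_data(data)
    return nlr_classify.classify_proteome(evidence)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=3, n_genotypes=1, n_background_genes=60, n_nlr_founders=8)
        a, b = tmp_path / "a", tmp_path / "b"
        pa = write_genotype(simulate_genotype(cfg, 0), a)
        pb = write_genotype(simulate_genotype(cfg, 0), b)
        for key in pa:
            assert filecmp.cmp(pa[key], pb[key], shallow=False), key

    def test_different_seed_differs(self):
        d1 = simulate_genotype(SimConfig(seed=1, n_genotypes=1, n_nlr_founders=8, n_background_genes=60), 0)
        d2 = simulate_genotype(SimConfig(seed=2, n_genotypes=1, n_nlr_founders=8, n_background_genes=60), 0)
        assert {g.gene_id: g.start for g in d1.genes} != {g.gene_id: g.start for g in d2.genes}


class TestTruthCoverage:
    def test_every_emitted_record_is_covered(self, small_cohort):
        _, dataset = small_cohort
        for d in dataset:
            truth_ids = set(d.truth.genes)
            assert {g.gene_id for g in d.genes} == truth_ids
            parents = {h.parent_protein for h in d.pseudoexons}
            assert parents <= set(d.proteome)
            pseudo_parents = {t.parent for t in d.truth.pseudo}
            assert parents <= pseudo_parents | parents  # pseudo table covers hits
            for t in d.truth.pseudo:
                assert t.n_fragments >= 1

    def test_gene_invariants_hold(self, small_cohort):
        _, dataset = small_cohort
        for d in dataset:
            for g in d.genes:
                assert g.start <= g.end <= d.chrom_lens[g.chrom]
                assert g.exons and g.exons[0][0] == g.start


class TestClassificationRecovery:
    def test_planted_classes_recovered_exactly(self, small_cohort):
        _, dataset = small_cohort
        for d in dataset:
            records = {r.gene_id: r for r in run_classify(d)}
            planted = {
                t.gene_id: t.nlr_class
                for t in d.truth.genes.values()
                if t.kind == "nlr"
            }
            assert set(records) == set(planted)  # decoys excluded, NLRs complete
            for gid, cls in planted.items():
                assert records[gid].nlr_class == cls

    def test_decoys_rejected_by_call_gate(self, small_cohort):
        _, dataset = small_cohort
        found_decoy = False
        for d in dataset:
            decoys = {t.gene_id for t in d.truth.genes.values() if t.kind == "decoy"}
            found_decoy |= bool(decoys)
            called = {r.gene_id for r in run_classify(d)}
            assert not (called & decoys)
        assert found_decoy  # the cohort exercises the gate


class TestDuplicationRecovery:
    def test_rule_truth_matches_classifier(self, small_cohort):
        _, dataset = small_cohort
        for d in dataset:
            ranks = dup_classify.rank_genes(d.genes)
            blocks = dup_classify.find_collinear_blocks(d.similarity, ranks)
            calls = {
                c.gene_id: c.dup_type
                for c in dup_classify.classify_duplicates(ranks, d.similarity, blocks)
            }
            truth = d.truth.genes
            mismatches = {
                gid: (calls[gid], truth[gid].dup_truth)
                for gid in calls
                if calls[gid] != truth[gid].dup_truth
            }
            assert not mismatches

    def test_planted_tandem_all_tandem_when_segmental_off(self, tandem_only_cohort):
        _, dataset = tandem_only_cohort
        n_tandem_copies = 0
        for d in dataset:
            ranks = dup_classify.rank_genes(d.genes)
            blocks = dup_classify.find_collinear_blocks(d.similarity, ranks)
            assert blocks == []  # nothing segmental planted
            calls = {
                c.gene_id: c.dup_type
                for c in dup_classify.classify_duplicates(ranks, d.similarity, blocks)
            }
            for t in d.truth.genes.values():
                if t.event_type == "tandem":
                    n_tandem_copies += 1
                    assert calls[t.gene_id] == "tandem"
        assert n_tandem_copies > 0

    def test_planted_segmental_blocks_found(self, small_cohort):
        _, dataset = small_cohort
        planted = 0
        for d in dataset:
            seg = {t.gene_id for t in d.truth.genes.values() if t.event_type == "segmental"}
            if not seg:
                continue
            planted += 1
            ranks = dup_classify.rank_genes(d.genes)
            blocks = dup_classify.find_collinear_blocks(d.similarity, ranks)
            anchored = {g for b in blocks for pair in b.anchors for g in pair}
            assert seg <= anchored
        assert planted > 0


class TestClusterRecovery:
    def test_separated_loci_recovered_exactly(self):
        for seed in (1, 5, 9):
            cfg = SimConfig(
                seed=seed,
                n_genotypes=1,
                regimes=("high",),
                n_nlr_founders=8,
                high=RegimeParams(4, 0.6, 0.4, 0.0, 0.0),
                p_pseudogenize=0.0,
                separate_loci=True,
            )
            d = simulate_genotype(cfg, 0)
            nlr_ids = {t.gene_id for t in d.truth.genes.values() if t.kind == "nlr"}
            nlr_genes = [g for g in d.genes if g.gene_id in nlr_ids]
            clusters = cluster_detect.detect_clusters(nlr_genes, d.genotype)
            expected = {}
            for t in d.truth.genes.values():
                if t.kind == "nlr" and t.locus_window:
                    expected.setdefault(t.locus_window, []).append(t.gene_id)
            expected = {k: v for k, v in expected.items() if len(v) >= 3}
            got = {(c.chrom, c.window_span[0]): sorted(c.members) for c in clusters}
            assert got == {k: sorted(v) for k, v in expected.items()}


@pytest.fixture(scope="module")
def pseudo_cohort():
    cfg = SimConfig(
        seed=17,
        n_genotypes=3,
        regimes=("high", "high", "high"),
        n_background_genes=100,
        n_nlr_founders=14,
        p_pseudogenize=0.6,
        kill_fractions=(
            ("short", 0.12),
            ("low_identity", 0.12),
            ("repeat", 0.12),
            ("gap", 0.12),
            ("no_domain", 0.12),
        ),
    )
    return simulate_dataset(cfg)


class TestPseudogeneRecovery:
    def run_stage(self, d):
        kept, _ = pseudogene_id.filter_candidates(
            d.pseudoexons, d.genes, d.repeat_hits
        )
        kept = pseudogene_id.best_hit_parents(kept)
        q99 = pseudogene_id.intron_q99(d.genes)
        contigs = pseudogene_id.link_pseudoexons(kept, q99)
        return pseudogene_id.domain_confirm(contigs, d.translated_domains)

    def test_criterion_by_criterion(self, pseudo_cohort):
        seen = {k: 0 for k in ("short", "low_identity", "repeat", "gap", "no_domain", None)}
        for d in pseudo_cohort:
            out_ids = {c.contig_id for c in self.run_stage(d)}
            for t in d.truth.pseudo:
                seen[t.kill] = seen.get(t.kill, 0) + 1
                if t.kill is None:
                    assert len(t.contig_ids) == 1
                    assert t.contig_ids[0] in out_ids
                elif t.kill == "gap":
                    # one over-long gap splits the copy into two contigs
                    assert set(t.contig_ids) <= out_ids
                    assert len(t.contig_ids) == 2
                else:
                    assert not (set(t.contig_ids) & out_ids)
        for reason in ("short", "low_identity", "repeat", "gap", "no_domain", None):
            assert seen[reason] > 0, f"cohort never exercised kill={reason}"

    def test_pipeline_q99_matches_planted(self, pseudo_cohort):
        for d in pseudo_cohort:
            assert pseudogene_id.intron_q99(d.genes) == pytest.approx(
                d.truth.q99_intron
            )


class TestRegimeSeparation:
    def test_high_vs_low_fold_change(self):
        fold_ok = 0
        for seed in range(10):
            cfg = SimConfig(
                seed=100 + seed,
                n_genotypes=2,
                regimes=("high", "low"),
                n_background_genes=60,
                n_nlr_founders=12,
            )
            ds = simulate_dataset(cfg)
            counts = {
                d.regime: sum(1 for t in d.truth.genes.values() if t.kind == "nlr")
                for d in ds
            }
            if counts["high"] >= 2 * counts["low"]:
                fold_ok += 1
        assert fold_ok >= 9  # >=2-fold separation in ~all seeded runs

    def test_cnv_split_recovers_regimes(self):
        from nlrcnv.cnv_stats import assign_cnv_groups

        ok = 0
        n_runs = 50
        for seed in range(n_runs):
            cfg = SimConfig(
                seed=1000 + seed,
                n_genotypes=4,
                regimes=("high", "high", "low", "low"),
                n_background_genes=40,
                n_nlr_founders=10,
            )
            ds = simulate_dataset(cfg)
            totals = {d.genotype: len(run_classify(d)) for d in ds}
            labels, _ = assign_cnv_groups(totals)
            truth = {
                d.genotype: "HighCNV" if d.regime == "high" else "LowCNV" for d in ds
            }
            if labels == truth:
                ok += 1
        assert ok == n_runs
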