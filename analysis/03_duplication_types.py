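#!/usr/bin/env python
"""Classify duplication types for every gene of the simulated cohort.

Ranks genes along each chromosome, chains similarity hits into collinear
blocks (match_score 50, gap_penalty -1, match_size 5, max_gaps 20), and
assigns singleton/dispersed/proximal/tandem/WGD-segmental with the usual
precedence.  Writes per-genotype NLR duplicate-type counts to
results/03_dup_counts.tsv.
"""

from pathlib import Path

from nlrcnv import dup_classify, io_formats

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    with open(out / "03_dup_counts.tsv", "w") as fh:
        fh.write("genotype\t" + "\t".join(dup_classify.DUP_TYPES) + "\tn_blocks\n")
        for gdir in sorted(COHORT.iterdir()):
            if not gdir.is_dir():
                continue
            genes = io_formats.read_gff3(gdir / "annotation.gff3", genotype=gdir.name)
            hits = io_formats.read_tabular_hits(gdir / "blastp.tsv", "similarity")
            nlr_ids = set()
            with open(gdir / "truth" / "genes.tsv") as tfh:
                next(tfh)
                for line in tfh:
                    cols = line.split("\t")
                    if cols[1] == "nlr":
                        nlr_ids.add(cols[0])
            ranks = dup_classify.rank_genes(genes)
            blocks = dup_classify.find_collinear_blocks(hits, ranks)
            calls = dup_classify.classify_duplicates(ranks, hits, blocks)
            counts = {t: 0 for t in dup_classify.DUP_TYPES}
            for c in calls:
                if c.gene_id in nlr_ids:
                    counts[c.dup_type] += 1
            fh.write(
                gdir.name + "\t"
                + "\t".join(str(counts[t]) for t in dup_classify.DUP_TYPES)
                + f"\t{len(blocks)}\n"
            )
            local = counts["tandem"] + counts["proximal"]
            print(
                f"{gdir.name}: {sum(counts.values())} NLRs, "
                f"{local} tandem+proximal, {counts['wgd_segmental']} segmental, "
                f"{len(blocks)} collinear blocks"
            )


if __name__ == "__main__":
    main()
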