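#!/usr/bin/env python
"""Call NLR clusters with the 1-Mbp window / >=3-NLR rule.

Counts NLRs in non-overlapping 1-Mbp windows (majority-overlap assignment),
merges adjacent occupied windows to a fixpoint, and reports merged runs
holding at least 3 NLRs.  Writes results/04_clusters.tsv.
"""

from pathlib import Path

from nlrcnv import cluster_detect, io_formats, nlr_classify
from nlrcnv.pipeline import load_evidence

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"

FILES = {
    "gff": "annotation.gff3", "proteome": "proteome.faa", "pfam": "interproscan.tsv",
    "hmm": "custom_hmm.tsv", "parser": "nlr_parser.tsv", "coils": "coils.tsv",
    "chroms": "chroms.tsv",
}


def main() -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    all_clusters = []
    for gdir in sorted(COHORT.iterdir()):
        if not gdir.is_dir():
            continue
        paths = {k: gdir / v for k, v in FILES.items()}
        evidence, genes, _ = load_evidence(gdir.name, paths)
        called = {r.gene_id for r in nlr_classify.classify_proteome(evidence)}
        nlr_genes = [g for g in genes if g.gene_id in called]
        clusters = cluster_detect.detect_clusters(nlr_genes, gdir.name)
        all_clusters.extend(clusters)
        summary = cluster_detect.cluster_summary(clusters).get(gdir.name, (0, None))
        mean = f"{summary[1]:.1f}" if summary[1] is not None else "-"
        print(f"{gdir.name}: {summary[0]} clusters, mean size {mean}")
    with open(out / "04_clusters.tsv", "w") as fh:
        fh.write("cluster_id\tgenotype\tchrom\tstart\tend\tsize\n")
        for c in all_clusters:
            s, e = c.span_bp()
            fh.write(f"{c.cluster_id}\t{c.genotype}\t{c.chrom}\t{s}\t{e}\t{c.size}\n")


if __name__ == "__main__":
    main()
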