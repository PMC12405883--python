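#!/usr/bin/env python
"""Identify NLR pseudogenes from pseudoexon evidence.

Applies the non-genic / >30 aa / >40% identity / repeat (<1e-5) filters,
links surviving fragments of the same parent NLR with gaps inside the 99th
percentile of the intron-length distribution, and keeps contigs whose
6-frame translation retains a common NLR domain.  Writes per-genotype
pseudogene:parent ratios to results/05_pseudogene_ratios.tsv.
"""

from pathlib import Path

from nlrcnv import io_formats, pseudogene_id

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    with open(out / "05_pseudogene_ratios.tsv", "w") as fh:
        fh.write("genotype\tn_pseudogenes\tn_parents\tratio\tq99_intron_bp\n")
        for gdir in sorted(COHORT.iterdir()):
            if not gdir.is_dir():
                continue
            gt = gdir.name
            genes = io_formats.read_gff3(gdir / "annotation.gff3", genotype=gt)
            hits = io_formats.read_tabular_hits(gdir / "tblastn.tsv", "pseudoexon", genotype=gt)
            repeats = io_formats.read_tabular_hits(gdir / "repeats.tsv", "repeat")
            kept, reasons = pseudogene_id.filter_candidates(hits, genes, repeats)
            kept = pseudogene_id.best_hit_parents(kept)
            q99 = pseudogene_id.intron_q99(genes)
            contigs = pseudogene_id.link_pseudoexons(kept, q99)
            translated = []
            with open(gdir / "translated_domains.tsv") as tfh:
                for line in tfh:
                    if line.strip():
                        cid, acc = line.rstrip("\n").split("\t")[:2]
                        translated.append((cid, acc))
            confirmed = pseudogene_id.domain_confirm(contigs, translated)
            ratios = pseudogene_id.pseudogene_parent_ratio(confirmed)
            n, n_par, ratio = ratios.get(gt, (0, 0, None))
            fh.write(
                f"{gt}\t{n}\t{n_par}\t{'' if ratio is None else f'{ratio:.1f}'}\t{q99:.0f}\n"
            )
            dropped = ", ".join(f"{k} {v}" for k, v in sorted(reasons.items())) or "none"
            print(
                f"{gt}: {n} pseudogenes from {n_par} parents "
                f"(ratio {'-' if ratio is None else f'{ratio:.1f}'}; "
                f"q99 intron {q99:.0f} bp; removed: {dropped})"
            )


if __name__ == "__main__":
    main()
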