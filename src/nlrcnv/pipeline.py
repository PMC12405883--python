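"""Stage orchestration: classify -> duplicates -> clusters -> pseudogenes -> stats.

Each stage reads the typed inputs through io_formats, writes a plain TSV
(or GFF3) into the run directory before the next stage starts, and can be
re-run standalone.  Completed stages are skipped on re-run unless forced;
all numbers in the final report trace to a stage output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nlrcnv import __version__, cluster_detect, cnv_stats, dup_classify, nlr_classify
from nlrcnv import io_formats, pseudogene_id
from nlrcnv.cluster_detect import NLRCluster
from nlrcnv.dup_classify import CollinearParams, DuplicationCall
from nlrcnv.nlr_classify import ClassifyThresholds, NLRRecord, ProteinEvidence
from nlrcnv.pseudogene_id import PseudoFilter, PseudogeneContig

logger = logging.getLogger(__name__)

GENOTYPE_FILES = (
    "gff",
    "proteome",
    "pfam",
    "hmm",
    "parser",
    "coils",
    "similarity",
    "pseudoexons",
    "repeats",
    "translated",
    "chroms",
)

STAGES = ("classify", "duplicates", "clusters", "pseudogenes", "stats")


@dataclass
class RunConfig:
    genotypes: dict[str, dict[str, Path]]
    out_dir: Path
    thresholds: ClassifyThresholds = field(default_factory=ClassifyThresholds)
    collinear: CollinearParams = field(default_factory=CollinearParams)
    pseudo_filter: PseudoFilter = field(default_factory=PseudoFilter)
    window_size: int = cluster_detect.DEFAULT_WINDOW
    min_cluster_size: int = 3
    force: bool = False


def validate_config(raw: dict | str | Path) -> RunConfig:
    """Schema-check a YAML/JSON/dict run configuration, filling threshold
    defaults; missing files and out-of-range thresholds are named errors."""
    if not isinstance(raw, dict):
        with open(raw) as fh:
            raw = yaml.safe_load(fh)
    if "genotypes" not in raw or not raw["genotypes"]:
        raise ValueError("config must list at least one genotype")
    genotypes: dict[str, dict[str, Path]] = {}
    for gt, files in raw["genotypes"].items():
        genotypes[gt] = {}
        for key in GENOTYPE_FILES:
            if key not in files:
                raise ValueError(f"genotype {gt}: missing input field {key!r}")
            p = Path(files[key])
            if not p.exists():
                raise ValueError(f"genotype {gt}: {key} file not found: {p}")
            genotypes[gt][key] = p
    thr = ClassifyThresholds(**raw.get("thresholds", {}))
    col = CollinearParams(**raw.get("collinear", {}))
    pf = PseudoFilter(**raw.get("pseudo_filter", {}))
    window = int(raw.get("window_size", cluster_detect.DEFAULT_WINDOW))
    if window <= 0:
        raise ValueError("window_size must be positive")
    return RunConfig(
        genotypes=genotypes,
        out_dir=Path(raw.get("out_dir", "nlrcnv_run")),
        thresholds=thr,
        collinear=col,
        pseudo_filter=pf,
        window_size=window,
        min_cluster_size=int(raw.get("min_cluster_size", 3)),
        force=bool(raw.get("force", False)),
    )


def config_for_dataset(dataset_dir: str | Path, out_dir: str | Path, **kw) -> RunConfig:
    """Build a RunConfig for a directory written by simulate.write_dataset."""
    dataset_dir = Path(dataset_dir)
    names = {
        "gff": "annotation.gff3",
        "proteome": "proteome.faa",
        "pfam": "interproscan.tsv",
        "hmm": "custom_hmm.tsv",
        "parser": "nlr_parser.tsv",
        "coils": "coils.tsv",
        "similarity": "blastp.tsv",
        "pseudoexons": "tblastn.tsv",
        "repeats": "repeats.tsv",
        "translated": "translated_domains.tsv",
        "chroms": "chroms.tsv",
    }
    genotypes = {}
    for gdir in sorted(p for p in dataset_dir.iterdir() if p.is_dir()):
        genotypes[gdir.name] = {k: str(gdir / v) for k, v in names.items()}
    return validate_config({"genotypes": genotypes, "out_dir": str(out_dir), **kw})


# ---------------------------------------------------------------------------
# evidence assembly
# ---------------------------------------------------------------------------


def load_evidence(gt: str, files: dict[str, Path]) -> tuple[list[ProteinEvidence], list, dict]:
    """Read one genotype's inputs into ProteinEvidence records.

    Returns (evidence, gene models, chromosome lengths).  Protein ids are
    gene ids (one protein per gene, the longest-mRNA translation).
    """
    genes = io_formats.read_gff3(files["gff"], genotype=gt)
    by_id = {g.gene_id: g for g in genes}
    chrom_lens: dict[str, int] = {}
    with open(files["chroms"]) as fh:
        for line in fh:
            c, ln = line.split("\t")
            chrom_lens[c] = int(ln)
    hits = io_formats.read_interproscan(files["pfam"]) + io_formats.read_hmm_hits(files["hmm"])
    by_protein: dict[str, list] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    parser_cc = io_formats.read_motif_calls(files["parser"])
    coils_cc = io_formats.read_coils(files["coils"])
    proteins = set(by_protein) | parser_cc | coils_cc | set(by_id)
    evidence = []
    for pid in sorted(proteins):
        gene = by_id.get(pid)
        evidence.append(
            ProteinEvidence(
                protein_id=pid,
                genotype=gt,
                domain_hits=by_protein.get(pid, []),
                parser_cc=pid in parser_cc,
                coils_cc=pid in coils_cc,
                scaffold=gene.chrom if gene else "",
                scaffold_len=chrom_lens.get(gene.chrom, 0) if gene else 0,
                gene=gene,
            )
        )
    return evidence, genes, chrom_lens


def evidence_from_data(data) -> list[ProteinEvidence]:
    """ProteinEvidence records straight from an in-memory GenotypeData
    (simulate module), bypassing file round-trips."""
    by_id = {g.gene_id: g for g in data.genes}
    by_protein: dict[str, list] = {}
    for h in list(data.pfam_hits) + list(data.hmm_hits):
        by_protein.setdefault(h.protein_id, []).append(h)
    proteins = set(by_protein) | data.parser_cc | data.coils_cc | set(by_id)
    evidence = []
    for pid in sorted(proteins):
        gene = by_id.get(pid)
        evidence.append(
            ProteinEvidence(
                protein_id=pid,
                genotype=data.genotype,
                domain_hits=by_protein.get(pid, []),
                parser_cc=pid in data.parser_cc,
                coils_cc=pid in data.coils_cc,
                scaffold=gene.chrom if gene else "",
                scaffold_len=data.chrom_lens.get(gene.chrom, 0) if gene else 0,
                gene=gene,
            )
        )
    return evidence


# ---------------------------------------------------------------------------
# stage output files
# ---------------------------------------------------------------------------


def _write_nlr_calls(records: list[NLRRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tgenotype\tnlr_class\thas_nbarc\thas_lrr\thas_tir\thas_rpw8\t"
            "has_cc\tcomplete\tnbarc_rel_pos\n"
        )
        for r in records:
            pos = "" if r.nbarc_rel_pos is None else f"{r.nbarc_rel_pos:.6f}"
            fh.write(
                f"{r.gene_id}\t{r.genotype}\t{r.nlr_class}\t{int(r.has_nbarc)}\t"
                f"{int(r.has_lrr)}\t{int(r.has_tir)}\t{int(r.has_rpw8)}\t{int(r.has_cc)}\t"
                f"{int(r.complete)}\t{pos}\n"
            )


def _read_nlr_calls(path: Path) -> list[NLRRecord]:
    records = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            c = line.rstrip("\n").split("\t")
            records.append(
                NLRRecord(
                    gene_id=c[0], genotype=c[1], nlr_class=c[2],
                    has_nbarc=bool(int(c[3])), has_lrr=bool(int(c[4])),
                    has_tir=bool(int(c[5])), has_rpw8=bool(int(c[6])),
                    has_cc=bool(int(c[7])), complete=bool(int(c[8])),
                    nbarc_rel_pos=float(c[9]) if c[9] else None,
                )
            )
    return records


def _write_dups(calls: dict[str, list[DuplicationCall]], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgenotype\tdup_type\n")
        for gt in sorted(calls):
            for c in calls[gt]:
                fh.write(f"{c.gene_id}\t{gt}\t{c.dup_type}\n")


def _read_dups(path: Path) -> dict[str, list[DuplicationCall]]:
    out: dict[str, list[DuplicationCall]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            gid, gt, dup = line.rstrip("\n").split("\t")
            out.setdefault(gt, []).append(DuplicationCall(gene_id=gid, dup_type=dup))
    return out


def _write_clusters(clusters: list[NLRCluster], path: Path, window: int) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tgenotype\tchrom\tstart\tend\tn_members\tmembers\n")
        for c in clusters:
            s, e = c.span_bp(window)
            fh.write(
                f"{c.cluster_id}\t{c.genotype}\t{c.chrom}\t{s}\t{e}\t{c.size}\t"
                f"{','.join(c.members)}\n"
            )


def _read_clusters(path: Path) -> list[NLRCluster]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            cid, gt, chrom, s, e, n, members = line.rstrip("\n").split("\t")
            first = int(cid.rsplit(":", 1)[1])
            out.append(
                NLRCluster(
                    cluster_id=cid, genotype=gt, chrom=chrom,
                    window_span=(first, first),  # span recoverable from bp columns
                    members=members.split(","),
                )
            )
    return out


def _write_pseudo(contigs: list[PseudogeneContig], path: Path) -> None:
    pseudogene_id.write_pseudogene_gff3(contigs, path)


def _read_pseudo(path: Path) -> list[PseudogeneContig]:
    contigs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[2] != "pseudogene":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";"))
            contigs.append(
                PseudogeneContig(
                    contig_id=attrs["ID"],
                    genotype=attrs["genotype"],
                    chrom=cols[0],
                    span=(int(cols[3]), int(cols[4])),
                    pseudoexons=[],
                    parent_protein=attrs["Parent_NLR"],
                    passed_domain_filter=True,
                )
            )
    return contigs


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the run report (also written to disk)."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stage_files = {
        "classify": out / "nlr_calls.tsv",
        "duplicates": out / "duplications.tsv",
        "blocks": out / "collinear_blocks.tsv",
        "clusters": out / "clusters.tsv",
        "pseudogenes": out / "pseudogenes.gff3",
        "ratios": out / "pseudogene_ratios.tsv",
        "report": out / "report.json",
    }

    evidence_cache: dict[str, tuple] = {}

    def genes_of(gt: str):
        if gt not in evidence_cache:
            evidence_cache[gt] = load_evidence(gt, cfg.genotypes[gt])
        return evidence_cache[gt]

    # --- classify
    if stage_files["classify"].exists() and not cfg.force:
        logger.info("classify: output exists, skipping")
        nlr_records = _read_nlr_calls(stage_files["classify"])
    else:
        nlr_records = []
        representatives: list[tuple[str, str]] = []
        for gt in sorted(cfg.genotypes):
            evidence, _, _ = genes_of(gt)
            nlr_records.extend(nlr_classify.classify_proteome(evidence, cfg.thresholds))
            # seed-domain representatives for external profile-HMM building
            proteome = io_formats.read_fasta(cfg.genotypes[gt]["proteome"])
            seeds = nlr_classify.select_seed_domains(
                [h for p in evidence for h in p.domain_hits if h.source == "pfam_hmm"],
                cfg.thresholds,
            )
            seqs = nlr_classify.extract_domain_seqs(seeds, proteome)
            if seqs:
                representatives.extend(
                    nlr_classify.cluster_representatives(seqs, cfg.thresholds)
                )
        if representatives:
            io_formats.write_fasta(representatives, out / "seed_representatives.faa")
        _write_nlr_calls(nlr_records, stage_files["classify"])
    nlr_ids = {(r.genotype, r.gene_id) for r in nlr_records}

    # --- duplicates
    if stage_files["duplicates"].exists() and not cfg.force:
        logger.info("duplicates: output exists, skipping")
        dup_calls = _read_dups(stage_files["duplicates"])
    else:
        dup_calls = {}
        with open(stage_files["blocks"], "w") as bfh:
            bfh.write("genotype\tblock\tchrom_a\tchrom_b\torientation\tscore\tanchors\n")
            for gt in sorted(cfg.genotypes):
                _, genes, _ = genes_of(gt)
                ranks = dup_classify.rank_genes(genes)
                hits = io_formats.read_tabular_hits(
                    cfg.genotypes[gt]["similarity"], "similarity"
                )
                blocks = dup_classify.find_collinear_blocks(hits, ranks, cfg.collinear)
                dup_calls[gt] = dup_classify.classify_duplicates(
                    ranks, hits, blocks, cfg.collinear.evalue_cut
                )
                for i, b in enumerate(blocks):
                    bfh.write(
                        f"{gt}\t{i}\t{b.chrom_a}\t{b.chrom_b}\t{b.orientation}\t"
                        f"{b.score:.1f}\t"
                        + ";".join(f"{a},{s}" for a, s in b.anchors)
                        + "\n"
                    )
        _write_dups(dup_calls, stage_files["duplicates"])

    # --- clusters
    if stage_files["clusters"].exists() and not cfg.force:
        logger.info("clusters: output exists, skipping")
        clusters = _read_clusters(stage_files["clusters"])
    else:
        clusters = []
        for gt in sorted(cfg.genotypes):
            _, genes, _ = genes_of(gt)
            nlr_genes = [g for g in genes if (gt, g.gene_id) in nlr_ids]
            clusters.extend(
                cluster_detect.detect_clusters(
                    nlr_genes, gt, cfg.window_size, cfg.min_cluster_size
                )
            )
        _write_clusters(clusters, stage_files["clusters"], cfg.window_size)
        cluster_detect.write_cluster_bed(clusters, out / "clusters.bed", cfg.window_size)

    # --- pseudogenes
    if stage_files["pseudogenes"].exists() and not cfg.force:
        logger.info("pseudogenes: output exists, skipping")
        pseudogenes = _read_pseudo(stage_files["pseudogenes"])
    else:
        pseudogenes = []
        for gt in sorted(cfg.genotypes):
            _, genes, _ = genes_of(gt)
            hits = io_formats.read_tabular_hits(
                cfg.genotypes[gt]["pseudoexons"], "pseudoexon", genotype=gt
            )
            repeats = io_formats.read_tabular_hits(cfg.genotypes[gt]["repeats"], "repeat")
            kept, _ = pseudogene_id.filter_candidates(
                hits, genes, repeats, cfg.pseudo_filter
            )
            kept = pseudogene_id.best_hit_parents(kept)
            q99 = pseudogene_id.intron_q99(genes, cfg.pseudo_filter.intron_quantile)
            contigs = pseudogene_id.link_pseudoexons(kept, q99)
            translated = []
            with open(cfg.genotypes[gt]["translated"]) as fh:
                for line in fh:
                    if line.strip():
                        cid, acc = line.rstrip("\n").split("\t")[:2]
                        translated.append((cid, acc))
            pseudogenes.extend(pseudogene_id.domain_confirm(contigs, translated))
        _write_pseudo(pseudogenes, stage_files["pseudogenes"])
        ratios = pseudogene_id.pseudogene_parent_ratio(pseudogenes)
        with open(stage_files["ratios"], "w") as fh:
            fh.write("genotype\tn_pseudogenes\tn_parents\tratio\n")
            for gt in sorted(cfg.genotypes):
                n, np_, ratio = ratios.get(gt, (0, 0, None))
                fh.write(
                    f"{gt}\t{n}\t{np_}\t{'' if ratio is None else f'{ratio:.1f}'}\n"
                )

    # --- stats
    gene_chroms = {}
    for gt in sorted(cfg.genotypes):
        _, genes, _ = genes_of(gt)
        for g in genes:
            gene_chroms[g.gene_id] = g.chrom
    matrix = cnv_stats.build_cnv_matrix(
        nlr_records, pseudogenes, clusters, sorted(cfg.genotypes), gene_chroms
    )
    matrix.to_csv(out / "cnv_matrix.tsv", sep="\t")

    report = build_report(matrix, nlr_records, dup_calls, cfg)
    write_report(report, out)
    return report


def build_report(
    matrix: pd.DataFrame,
    nlr_records: list[NLRRecord],
    dup_calls: dict[str, list[DuplicationCall]],
    cfg: RunConfig,
) -> dict:
    """Group summaries, tests, and provenance from the stage outputs."""
    totals = matrix["total"].to_dict()
    report: dict = {
        "per_genotype": json.loads(matrix.to_json(orient="index")),
        "provenance": {
            "version": __version__,
            "config_hash": hashlib.sha256(
                json.dumps(
                    {gt: {k: str(v) for k, v in fs.items()} for gt, fs in cfg.genotypes.items()},
                    sort_keys=True,
                ).encode()
            ).hexdigest()[:16],
            "window_size": cfg.window_size,
            "min_cluster_size": cfg.min_cluster_size,
        },
    }
    if len(totals) >= 2 and len(set(totals.values())) > 1:
        labels, gap = cnv_stats.assign_cnv_groups(totals)
        by_group: dict[str, list[float]] = {}
        for gt, lab in labels.items():
            by_group.setdefault(lab, []).append(totals[gt])
        summaries, diff = cnv_stats.group_summary(by_group)
        report["cnv_groups"] = {
            "labels": labels,
            "gap_statistic": gap,
            "summaries": {
                g: {"n": s.n, "mean": s.mean, "sem": s.sem, "ci95": s.ci95}
                for g, s in summaries.items()
            },
            "mean_difference": diff,
        }
        if len(by_group) == 2 and all(len(v) for v in by_group.values()):
            u, p = cnv_stats.mann_whitney(
                by_group.get("HighCNV", []), by_group.get("LowCNV", [])
            )
            report["cnv_groups"]["mann_whitney"] = {"U": u, "p": p}
        recs_by_group: dict[str, list[NLRRecord]] = {"HighCNV": [], "LowCNV": []}
        for r in nlr_records:
            recs_by_group[labels[r.genotype]].append(r)
        if all(recs_by_group.values()):
            table, chi2, p = cnv_stats.complete_partial_table(recs_by_group)
            report["complete_partial"] = {
                "table": json.loads(table.to_json(orient="index")),
                "chi2": chi2,
                "p": p,
            }
        # class-level counts for the reporting GLM
        rows = []
        for gt in matrix.index:
            for cls in cnv_stats.NLR_CLASSES:
                rows.append(
                    {
                        "genotype": gt,
                        "group": labels[gt],
                        "nlr_class": cls,
                        "count": int(matrix.loc[gt, cls]),
                    }
                )
        try:
            report["glms"] = cnv_stats.report_glms(pd.DataFrame(rows))
        except Exception as exc:  # pragma: no cover
            logger.warning("GLM reporting failed: %s", exc)
            report["glms"] = None
    dup_counts: dict[str, dict[str, int]] = {}
    for gt, calls in dup_calls.items():
        counts: dict[str, int] = {t: 0 for t in dup_classify.DUP_TYPES}
        nlr_of_gt = {r.gene_id for r in nlr_records if r.genotype == gt}
        for c in calls:
            if c.gene_id in nlr_of_gt:
                counts[c.dup_type] += 1
        dup_counts[gt] = counts
    report["nlr_duplication_counts"] = dup_counts
    return report


def write_report(report: dict, out_dir: str | Path) -> None:
    """Machine- (JSON, TSV) and human-readable (markdown) report files."""
    out = Path(out_dir)

    def _clean(o):
        if isinstance(o, dict):
            return {k: _clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_clean(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, float) and not np.isfinite(o):
            return None
        return o

    report = _clean(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    pd.DataFrame.from_dict(report["per_genotype"], orient="index").to_csv(
        out / "report_per_genotype.tsv", sep="\t"
    )
    lines = ["# NLR CNV run report", "", "## Per-genotype NLR counts", ""]
    df = pd.DataFrame.from_dict(report["per_genotype"], orient="index")
    cols = [c for c in ("NL", "CNL", "TNL", "RNL", "total", "pseudogenes", "n_clusters") if c in df]
    lines.append(df[cols].to_markdown())
    if "cnv_groups" in report:
        g = report["cnv_groups"]
        lines += [
            "",
            "## CNV groups",
            "",
            f"Group mean difference (High - Low): {g['mean_difference']:.2f}",
            f"Gap statistic: {g['gap_statistic']:.3f}",
        ]
        if "mann_whitney" in g:
            lines.append(
                f"Mann-Whitney U = {g['mann_whitney']['U']:.1f}, p = {g['mann_whitney']['p']:.4g}"
            )
    with open(out / "report.md", "w") as fh:
        fh.write("\n".join(lines) + "\n")
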