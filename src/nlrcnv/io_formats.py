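"""Readers and writers for the external tables the pipeline consumes.

All genomic coordinates are GFF3-style: 1-based, inclusive on both ends.
Downstream modules operate only on the typed records defined here; no other
module re-parses files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


class RecordError(ValueError):
    """A malformed record in an input file (message names the line)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A positioned, stranded, exon-structured gene on one genotype's chromosome."""

    gene_id: str
    genotype: str
    chrom: str
    start: int  # bp, 1-based inclusive
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    aed: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise RecordError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise RecordError(f"gene {self.gene_id}: bad exon ({s},{e})")
            if prev_end is not None and s <= prev_end:
                raise RecordError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def intron_lengths(self) -> list[int]:
        """Gap lengths between consecutive exons (next_start - prev_end - 1)."""
        return [
            self.exons[i + 1][0] - self.exons[i][1] - 1
            for i in range(len(self.exons) - 1)
        ]


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain hit (Pfam via Interproscan, or a custom NLR HMM)."""

    protein_id: str
    source: str  # "pfam_hmm" | "custom_hmm"
    accession: str  # e.g. PF00931
    evalue: float
    aa_start: int  # 1-based inclusive amino-acid positions
    aa_end: int

    def __post_init__(self) -> None:
        if self.aa_start > self.aa_end:
            raise RecordError(
                f"domain hit {self.protein_id}/{self.accession}: aa_start > aa_end"
            )


@dataclass(frozen=True)
class SimilarityHit:
    """One row of an all-vs-all protein similarity search (outfmt-6-like)."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int


@dataclass(frozen=True)
class PseudoexonHit:
    """A protein-vs-genome hit: candidate pseudoexon of a parent NLR."""

    parent_protein: str
    genotype: str
    chrom: str
    g_start: int  # bp, 1-based inclusive, g_start <= g_end
    g_end: int
    frame: int  # -3..-1, 1..3 (sign = genomic strand)
    pct_identity: float
    aa_len: int
    evalue: float

    def __post_init__(self) -> None:
        if self.g_start > self.g_end:
            raise RecordError("pseudoexon: g_start > g_end")
        if self.aa_len < 1:
            raise RecordError("pseudoexon: aa_len < 1")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _prevalidate_gff3(path: Path) -> int:
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise RecordError(f"{path}:{lineno}: fewer than 8 GFF3 columns")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise RecordError(f"{path}:{lineno}: non-integer coordinates")
            if end < start:
                raise RecordError(f"{path}:{lineno}: end {end} < start {start}")
            n_features += 1
    return n_features


def read_gff3(path: str | Path, genotype: str = "") -> list[GeneModel]:
    """Parse a GFF3 annotation into GeneModel records.

    One record per ``gene`` feature; exons are taken from the representative
    mRNA, chosen as the one with the greatest summed exon length (tie: first
    in file order).  The MAKER annotation-edit-distance attribute ``_AED`` is
    parsed when present.  Genes without exon children are kept with an empty
    exon list and a logged warning.
    """
    path = Path(path)
    if _prevalidate_gff3(path) == 0:
        return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        aed = None
        if "_AED" in g.attributes:
            aed = float(g.attributes["_AED"][0])
        mrnas = list(db.children(g, featuretype="mRNA", order_by="start"))
        exons: list[tuple[int, int]] = []
        if mrnas:
            best, best_len = None, -1
            for m in mrnas:
                ex = [(e.start, e.end) for e in db.children(m, featuretype="exon")]
                total = sum(e - s + 1 for s, e in ex)
                if total > best_len:
                    best, best_len = ex, total
            exons = sorted(best or [])
        else:
            exons = sorted(
                (e.start, e.end) for e in db.children(g, featuretype="exon")
            )
        if not exons:
            logger.warning("gene %s has no exons; kept with empty exon list", g.id)
        genes.append(
            GeneModel(
                gene_id=g.id,
                genotype=genotype,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exons=exons,
                aed=aed,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModels as gene/mRNA/exon features (inverse of read_gff3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.chrom, x.start, x.end, x.gene_id)):
            attrs = f"ID={g.gene_id}"
            if g.aed is not None:
                attrs += f";_AED={g.aed:.2f}"
            fh.write(
                f"{g.chrom}\tnlrcnv\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tnlrcnv\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tnlrcnv\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.exon{i};Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# tabular alignment hits (12-column outfmt-6-like)
# ---------------------------------------------------------------------------

_OUTFMT6_NCOL = 12


def read_tabular_hits(
    path: str | Path,
    kind: str,
    genotype: str = "",
) -> list:
    """Read a 12-column tab-separated alignment table.

    kind="similarity": protein-vs-protein rows -> SimilarityHit; self-hits
    (qseqid == sseqid) are dropped and their count logged.

    kind="pseudoexon": protein-vs-genome rows -> PseudoexonHit; subject
    coordinates are genomic, and s_start > s_end denotes the reverse strand
    (negative frame).

    kind="repeat": pseudoexon-vs-repeat-library rows -> (query_id, evalue).
    """
    if kind not in {"similarity", "pseudoexon", "repeat"}:
        raise ValueError(f"unknown kind {kind!r}")
    out: list = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != _OUTFMT6_NCOL:
                raise RecordError(
                    f"{path}:{lineno}: expected {_OUTFMT6_NCOL} columns, got {len(cols)}"
                )
            (q, s, pident, length, _mm, _go, qs, qe, ss, se, ev, _bits) = cols
            if kind == "similarity":
                if q == s:
                    n_self += 1
                    continue
                out.append(
                    SimilarityHit(
                        query_id=q,
                        subject_id=s,
                        pct_identity=float(pident),
                        align_len=int(length),
                        evalue=float(ev),
                        q_start=int(qs),
                        q_end=int(qe),
                        s_start=int(ss),
                        s_end=int(se),
                    )
                )
            elif kind == "pseudoexon":
                ssi, sei = int(ss), int(se)
                reverse = ssi > sei
                g_start, g_end = (sei, ssi) if reverse else (ssi, sei)
                aa_len = int(qe) - int(qs) + 1
                frame = -(((g_start - 1) % 3) + 1) if reverse else ((g_start - 1) % 3) + 1
                out.append(
                    PseudoexonHit(
                        parent_protein=q,
                        genotype=genotype,
                        chrom=s,
                        g_start=g_start,
                        g_end=g_end,
                        frame=frame,
                        pct_identity=float(pident),
                        aa_len=aa_len,
                        evalue=float(ev),
                    )
                )
            else:  # repeat
                out.append((q, float(ev)))
    if n_self:
        logger.info("dropped %d self-hits from %s", n_self, path)
    return out


# ---------------------------------------------------------------------------
# domain / motif evidence tables
# ---------------------------------------------------------------------------


def read_interproscan(path: str | Path) -> list[DomainHit]:
    """Interproscan-style TSV: protein, md5, length, analysis, accession,
    description, start, end, evalue (first 9 columns used)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise RecordError(f"{path}:{lineno}: fewer than 9 columns")
            hits.append(
                DomainHit(
                    protein_id=cols[0],
                    source="pfam_hmm",
                    accession=cols[4],
                    evalue=float(cols[8]),
                    aa_start=int(cols[6]),
                    aa_end=int(cols[7]),
                )
            )
    return hits


def read_hmm_hits(path: str | Path) -> list[DomainHit]:
    """Custom-HMM hit table: protein_id, accession, evalue, aa_start, aa_end."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise RecordError(f"{path}:{lineno}: fewer than 5 columns")
            hits.append(
                DomainHit(
                    protein_id=cols[0],
                    source="custom_hmm",
                    accession=cols[1],
                    evalue=float(cols[2]),
                    aa_start=int(cols[3]),
                    aa_end=int(cols[4]),
                )
            )
    return hits


def read_motif_calls(path: str | Path) -> set[str]:
    """NLR-parser-style TSV: protein ids with a CC motif call (column 1;
    optional column 2 must contain 'CC' to count)."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) == 1 or "CC" in cols[1].upper():
                ids.add(cols[0])
    return ids


def read_coils(path: str | Path) -> set[str]:
    """COILS-style table: protein ids with a predicted coiled-coil segment."""
    return read_motif_calls(path)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in items]
    SeqIO.write(records, str(path), "fasta")
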