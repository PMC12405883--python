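"""NLR identification and architecture classification.

The classifier mirrors the standard evidence chain for plant immune
receptors: seed domains (NB-ARC, TIR, RPW8) are selected from Pfam scans at
stringent e-value gates, near-identical domain sequences are collapsed to
representatives (for external profile-HMM construction), proteins are called
NLRs from custom-HMM hits at e <= 1e-4 or a motif-parser CC call, and each
NLR is assigned one architecture class:

  TNL  TIR-NB-ARC-LRR
  RNL  RPW8-NB-ARC-LRR (helper clade)
  CNL  CC-NB-ARC-LRR (Rx N-terminal domain PF18052, or parser CC + COILS CC)
  NL   NB-ARC-LRR backbone with no recognised N-terminal domain

Rule precedence is TNL > RNL > CNL > NL; conflicts are logged.  Profile-HMM
search itself is external — this module only selects seeds, emits
representative sequences, and consumes hit tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import Align

from nlrcnv.io_formats import DomainHit, GeneModel

logger = logging.getLogger(__name__)

# Pfam accessions for the canonical NLR domains
NBARC = "PF00931"
TIR_ACCS = frozenset({"PF01582", "PF13676"})
RPW8_ACCS = frozenset({"PF05659"})
RX_NTERM = "PF18052"  # CC (Rx-type N-terminal)
LRR_ACCS = frozenset({"PF00560", "PF07725", "PF12799", "PF13855"})

SEED_ACCS = frozenset({NBARC}) | TIR_ACCS | RPW8_ACCS


@dataclass(frozen=True)
class ClassifyThresholds:
    """E-value gates and identity threshold of the classification stage."""

    seed_evalue_nbarc: float = 1e-60
    seed_evalue_tir_rpw8: float = 1e-40
    hmm_call_evalue: float = 1e-4
    rep_identity: float = 0.98

    def __post_init__(self) -> None:
        for v in (self.seed_evalue_nbarc, self.seed_evalue_tir_rpw8, self.hmm_call_evalue):
            if not 0 < v <= 1:
                raise ValueError("e-value thresholds must be in (0, 1]")
        if not 0 < self.rep_identity <= 1:
            raise ValueError("rep_identity must be in (0, 1]")


@dataclass
class ProteinEvidence:
    """All per-protein evidence needed to call and classify one NLR."""

    protein_id: str
    genotype: str
    domain_hits: list[DomainHit] = field(default_factory=list)
    parser_cc: bool = False
    coils_cc: bool = False
    scaffold: str = ""
    scaffold_len: int = 0
    gene: Optional[GeneModel] = None


@dataclass
class NLRRecord:
    """One classified NLR gene."""

    gene_id: str
    genotype: str
    nlr_class: str  # TNL | RNL | CNL | NL
    has_nbarc: bool
    has_lrr: bool
    has_tir: bool
    has_rpw8: bool
    has_cc: bool
    complete: bool
    nbarc_rel_pos: Optional[float] = None


# ---------------------------------------------------------------------------
# seed selection and representative clustering
# ---------------------------------------------------------------------------


def select_seed_domains(
    hits: Iterable[DomainHit], t: ClassifyThresholds = ClassifyThresholds()
) -> list[DomainHit]:
    """Keep NB-ARC hits at e <= 1e-60 and TIR/RPW8 hits at e <= 1e-40.

    Hits to accessions outside the three seed families are ignored (counted
    in the log).  Both gates are inclusive.
    """
    kept: list[DomainHit] = []
    n_other = 0
    for h in hits:
        if h.accession == NBARC:
            if h.evalue <= t.seed_evalue_nbarc:
                kept.append(h)
        elif h.accession in TIR_ACCS or h.accession in RPW8_ACCS:
            if h.evalue <= t.seed_evalue_tir_rpw8:
                kept.append(h)
        else:
            n_other += 1
    if n_other:
        logger.debug("ignored %d non-seed-domain hits", n_other)
    return kept


def extract_domain_seqs(
    seeds: Iterable[DomainHit], proteins: dict[str, str]
) -> list[tuple[str, str]]:
    """Cut each seed hit's [aa_start, aa_end] substring from its protein.

    Hits whose coordinates exceed the protein length (or whose protein is
    missing) are skipped with a warning.
    """
    out: list[tuple[str, str]] = []
    for h in seeds:
        seq = proteins.get(h.protein_id)
        if seq is None or h.aa_end > len(seq):
            logger.warning(
                "seed hit %s:%s %d-%d out of bounds; skipped",
                h.protein_id, h.accession, h.aa_start, h.aa_end,
            )
            continue
        out.append(
            (
                f"{h.protein_id}:{h.accession}:{h.aa_start}-{h.aa_end}",
                seq[h.aa_start - 1 : h.aa_end],
            )
        )
    return out


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-1,
    extend_gap_score=-1,
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns (gaps count).

    Alignment scoring is match +1, mismatch 0, linear gap -1; the score only
    selects the alignment, identity is then read off its columns.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_representatives(
    seqs: list[tuple[str, str]], t: ClassifyThresholds = ClassifyThresholds()
) -> list[tuple[str, str]]:
    """Greedy centroid clustering at ``rep_identity``; returns one
    representative (the centroid) per cluster.

    Sequences are processed in decreasing length order (ties broken by id);
    each joins the first centroid it matches at identity >= rep_identity,
    else founds a new cluster.  Output order is centroid first-seen order.
    """
    if not seqs:
        raise ValueError("cluster_representatives requires at least one sequence")
    ordered = sorted(seqs, key=lambda x: (-len(x[1]), x[0]))
    centroids: list[tuple[str, str]] = []
    for sid, seq in ordered:
        for _, cseq in centroids:
            if pairwise_identity(seq, cseq) >= t.rep_identity:
                break
        else:
            centroids.append((sid, seq))
    return centroids


# ---------------------------------------------------------------------------
# NLR calling and architecture
# ---------------------------------------------------------------------------


def identify_nlrs(
    evidence: Iterable[ProteinEvidence], t: ClassifyThresholds = ClassifyThresholds()
) -> set[str]:
    """Union of custom-HMM seed-domain hits at e <= hmm_call_evalue and
    motif-parser CC calls.  A COILS call alone is not a criterion."""
    called = set()
    for p in evidence:
        hmm_hit = any(
            h.source == "custom_hmm"
            and h.accession in SEED_ACCS
            and h.evalue <= t.hmm_call_evalue
            for h in p.domain_hits
        )
        if hmm_hit or p.parser_cc:
            called.add(p.protein_id)
    return called


def _domain_flags(p: ProteinEvidence) -> dict[str, bool]:
    accs = {h.accession for h in p.domain_hits if h.source == "pfam_hmm"}
    return {
        "has_nbarc": NBARC in accs
        or any(
            h.source == "custom_hmm" and h.accession == NBARC for h in p.domain_hits
        ),
        "has_tir": bool(accs & TIR_ACCS),
        "has_rpw8": bool(accs & RPW8_ACCS),
        "has_lrr": bool(accs & LRR_ACCS),
        "has_rx": RX_NTERM in accs,
    }


def assign_architecture(p: ProteinEvidence) -> NLRRecord:
    """Assign one of TNL/RNL/CNL/NL by first matching rule.

    TIR -> TNL; RPW8 -> RNL; Rx N-terminal domain or (parser CC and COILS
    CC) -> CNL; otherwise NL.  ``complete`` means canonical N-terminal +
    NB-ARC + LRR.  Proteins carrying both TIR and RPW8 are logged.
    """
    f = _domain_flags(p)
    has_cc = f["has_rx"] or (p.parser_cc and p.coils_cc)
    if f["has_tir"] and f["has_rpw8"]:
        logger.info("protein %s has both TIR and RPW8; classed TNL", p.protein_id)
    if f["has_tir"]:
        nlr_class = "TNL"
    elif f["has_rpw8"]:
        nlr_class = "RNL"
    elif has_cc:
        nlr_class = "CNL"
    else:
        nlr_class = "NL"
    complete = (
        f["has_nbarc"]
        and f["has_lrr"]
        and (f["has_tir"] or f["has_rpw8"] or has_cc)
    )
    return NLRRecord(
        gene_id=p.gene.gene_id if p.gene else p.protein_id,
        genotype=p.genotype,
        nlr_class=nlr_class,
        has_nbarc=f["has_nbarc"],
        has_lrr=f["has_lrr"],
        has_tir=f["has_tir"],
        has_rpw8=f["has_rpw8"],
        has_cc=has_cc,
        complete=complete,
    )


def nbarc_relative_position(gene: GeneModel, scaffold_len: int) -> float:
    """Distance of the gene's genomic midpoint to the nearer scaffold end,
    normalised by scaffold length; in [0, 0.5]."""
    if scaffold_len < gene.end:
        raise ValueError(
            f"scaffold length {scaffold_len} < gene end {gene.end} ({gene.gene_id})"
        )
    d5 = gene.midpoint
    d3 = scaffold_len - d5
    return min(d5, d3) / scaffold_len


def classify_proteome(
    evidence: list[ProteinEvidence],
    t: ClassifyThresholds = ClassifyThresholds(),
) -> list[NLRRecord]:
    """Full per-proteome classification: call NLRs, then assign classes and,
    where possible, NB-ARC relative positions."""
    called = identify_nlrs(evidence, t)
    records = []
    for p in evidence:
        if p.protein_id not in called:
            continue
        rec = assign_architecture(p)
        if p.gene is not None and p.scaffold_len >= p.gene.end and rec.has_nbarc:
            rec.nbarc_rel_pos = nbarc_relative_position(p.gene, p.scaffold_len)
        records.append(rec)
    return records
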