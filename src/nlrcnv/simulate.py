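"""Synthetic multi-genotype datasets with planted ground truth.

The generator emulates the evidence tables of a multi-genotype NLR survey:
each genotype receives background genes and NLR founder loci (concentrated
on four designated chromosomes, as NLR hotspots are in real plant genomes),
then per-founder duplication events under a "high" or "low" regime:

  tandem      copy inserted at an adjacent gene rank
  proximal    copy inserted 2-20 ranks away (filler genes in between)
  dispersed   copy placed on a different chromosome
  segmental   a 5-gene run duplicated onto another chromosome in order,
              producing a collinear block of 5 anchor pairs

Copy identity to the source decays linearly per duplication event.  With
probability ``p_pseudogenize`` a copy is emitted not as a gene but as
degraded pseudoexon fragments, optionally violating exactly one pseudogene
filter (planted kill reasons) so the filter chain is testable
criterion-by-criterion.

No nucleotide sequence is generated: the pipeline consumes evidence tables,
so the generator emits those tables directly (protein sequences are emitted
because the seed-domain clustering stage aligns them).  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from nlrcnv.io_formats import (
    DomainHit,
    GeneModel,
    PseudoexonHit,
    SimilarityHit,
    write_fasta,
    write_gff3,
)

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

NBARC = "PF00931"
LRR = "PF00560"
TIR = "PF01582"
RPW8 = "PF05659"
RX = "PF18052"
KINASE = "PF00069"  # decoy, not a common NLR domain

KILL_REASONS = ("short", "low_identity", "repeat", "gap", "no_domain")


@dataclass(frozen=True)
class RegimeParams:
    """Per-founder duplication intensity for one CNV regime."""

    events_per_founder: int
    p_tandem: float
    p_proximal: float
    p_dispersed: float
    p_segmental: float

    @property
    def p_any(self) -> float:
        return self.p_tandem + self.p_proximal + self.p_dispersed + self.p_segmental


#: Defaults chosen so high-regime genotypes carry >= 2-fold more NLRs than
#: low-regime ones, echoing the bimodal CNV structure of real surveys.
HIGH_REGIME = RegimeParams(3, 0.50, 0.30, 0.15, 0.05)
LOW_REGIME = RegimeParams(1, 0.05, 0.05, 0.20, 0.10)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genotypes: int = 5
    regimes: Optional[tuple[str, ...]] = None  # "high"/"low" per genotype
    n_chroms: int = 10
    chrom_len: int = 5_000_000
    window_size: int = 1_000_000
    n_background_genes: int = 400
    n_nlr_founders: int = 30
    nlr_bias_chroms: tuple[str, ...] = ("Chr5", "Chr6", "Chr7", "Chr10")
    nlr_bias_weight: float = 5.0
    high: RegimeParams = HIGH_REGIME
    low: RegimeParams = LOW_REGIME
    p_pseudogenize: float = 0.15
    kill_fractions: tuple[tuple[str, float], ...] = (
        ("short", 0.06),
        ("low_identity", 0.06),
        ("repeat", 0.06),
        ("gap", 0.06),
        ("no_domain", 0.06),
    )
    identity_decay: float = 1.5  # % identity lost per duplication event
    mean_intron_len: float = 400.0
    intron_sd: float = 250.0
    p_decoy: float = 0.05
    class_probs: tuple[tuple[str, float], ...] = (
        ("NL", 0.52),
        ("CNL", 0.35),
        ("TNL", 0.10),
        ("RNL", 0.03),
    )
    protein_len: int = 220
    separate_loci: bool = False
    include_chr0: bool = True

    def regime_of(self, idx: int) -> str:
        if self.regimes is not None:
            return self.regimes[idx]
        # default split echoes a 7-high / 4-low cohort proportionally
        n_high = max(1, round(self.n_genotypes * 7 / 11))
        return "high" if idx < n_high else "low"

    def regime_params(self, name: str) -> RegimeParams:
        return self.high if name == "high" else self.low


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


@dataclass
class GeneTruth:
    gene_id: str
    kind: str  # background | nlr | decoy
    nlr_class: Optional[str]
    event_type: str  # background | decoy | founder | tandem | proximal | dispersed | segmental
    dup_truth: str = "singleton"
    family: Optional[str] = None
    steps: int = 0
    locus_window: Optional[tuple[str, int]] = None


@dataclass
class PseudoTruth:
    pseudo_id: str
    parent: str
    genotype: str
    chrom: str
    n_fragments: int
    kill: Optional[str]  # None => recoverable
    expected_contigs: int
    contig_ids: list[str]
    fragments: list[tuple[int, int]]


@dataclass
class TruthTable:
    genes: dict[str, GeneTruth]
    pseudo: list[PseudoTruth]
    q99_intron: float


@dataclass
class GenotypeData:
    """Everything the pipeline consumes for one genotype, plus truth."""

    genotype: str
    regime: str
    genes: list[GeneModel]
    chrom_lens: dict[str, int]
    proteome: dict[str, str]
    pfam_hits: list[DomainHit]
    hmm_hits: list[DomainHit]
    parser_cc: set[str]
    coils_cc: set[str]
    similarity: list[SimilarityHit]
    pseudoexons: list[PseudoexonHit]
    repeat_hits: list[tuple[str, float]]
    translated_domains: list[tuple[str, str]]
    phenotype_ratings: list[str]
    truth: TruthTable


# ---------------------------------------------------------------------------
# internal gene bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class _Spec:
    gene_id: str
    kind: str  # background | nlr | decoy
    family: Optional[str] = None
    steps: int = 0
    nlr_class: Optional[str] = None
    event_type: str = "background"
    cnl_route: Optional[str] = None  # "rx" | "motif"
    block: int = -1  # territory / block identifier


def _loguniform(rng: np.random.Generator, lo_exp: float, hi_exp: float) -> float:
    return float(10.0 ** rng.uniform(lo_exp, hi_exp))


def _mutate(rng: np.random.Generator, seq: str, pct: float) -> str:
    """Substitute ~pct% of positions with a different residue."""
    n = max(1, round(len(seq) * pct / 100.0))
    pos = rng.choice(len(seq), size=min(n, len(seq)), replace=False)
    arr = np.array(list(seq))
    for p in pos:
        choices = AA_ALPHABET[AA_ALPHABET != arr[p]]
        arr[p] = choices[rng.integers(len(choices))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def simulate_genotype(cfg: SimConfig, idx: int) -> GenotypeData:
    """Generate one genotype's full evidence set with planted truth.

    Deterministic for fixed (cfg.seed, idx).
    """
    rng = np.random.default_rng([cfg.seed, idx])
    gt = f"GT{idx:02d}"
    regime_name = cfg.regime_of(idx)
    regime = cfg.regime_params(regime_name)

    chroms = [f"Chr{i}" for i in range(1, cfg.n_chroms + 1)]
    chrom_lens = {c: cfg.chrom_len for c in chroms}
    if cfg.include_chr0:
        chrom_lens["Chr0"] = max(1_000_000, cfg.chrom_len // 5)

    weights = np.array(
        [cfg.nlr_bias_weight if c in cfg.nlr_bias_chroms else 1.0 for c in chroms]
    )
    weights /= weights.sum()

    gene_counter = [0]

    def new_id(prefix: str) -> str:
        gene_counter[0] += 1
        return f"{gt}_{prefix}{gene_counter[0]:05d}"

    # --- background genes (skipped in separated-locus mode, where only the
    # planted loci matter and background placement would be arbitrary)
    bg_by_chrom: dict[str, list[_Spec]] = {c: [] for c in chroms}
    if not cfg.separate_loci:
        counts = rng.multinomial(cfg.n_background_genes, np.full(len(chroms), 1 / len(chroms)))
        for c, n in zip(chroms, counts):
            for _ in range(n):
                kind = "decoy" if rng.random() < cfg.p_decoy else "background"
                bg_by_chrom[c].append(
                    _Spec(gene_id=new_id("g"), kind=kind, event_type=kind)
                )
    chr0_specs: list[_Spec] = []
    if cfg.include_chr0:
        for _ in range(5):
            chr0_specs.append(_Spec(gene_id=new_id("g"), kind="background"))

    # --- founders and their territories
    class_names = [c for c, _ in cfg.class_probs]
    class_p = np.array([p for _, p in cfg.class_probs])
    class_p /= class_p.sum()

    territories: list[dict] = []  # {"chrom", "items": [_Spec,...], "founder"}
    block_counter = [0]
    for f in range(cfg.n_nlr_founders):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        cls = class_names[rng.choice(len(class_names), p=class_p)]
        route = ("rx", "motif")[f % 2] if cls == "CNL" else None
        block_counter[0] += 1
        founder = _Spec(
            gene_id=new_id("nlr"),
            kind="nlr",
            family=f"{gt}_fam{f:03d}",
            steps=0,
            nlr_class=cls,
            event_type="founder",
            cnl_route=route,
            block=block_counter[0],
        )
        territories.append({"chrom": chrom, "items": [founder], "founder": founder})

    # --- duplication events
    pseudo_copies: list[dict] = []  # {"spec", "source", "chrom", "kill"}
    seg_blocks: list[dict] = []  # {"chrom", "items"} pending placement
    kill_reasons = [k for k, _ in cfg.kill_fractions]
    kill_probs = np.array([p for _, p in cfg.kill_fractions])
    event_names = ["tandem", "proximal", "dispersed", "segmental", "none"]
    event_p = np.array(
        [
            regime.p_tandem,
            regime.p_proximal,
            regime.p_dispersed,
            regime.p_segmental,
            max(0.0, 1.0 - regime.p_any),
        ]
    )
    event_p /= event_p.sum()

    for terr in territories:
        founder = terr["founder"]
        living = [founder]
        for _ in range(regime.events_per_founder):
            ev = event_names[rng.choice(len(event_names), p=event_p)]
            if ev == "none":
                continue
            if ev in ("tandem", "proximal"):
                # local copies arise next to a member of the home locus
                pool = [m for m in living if m in terr["items"]]
            else:
                pool = living
            source = pool[rng.integers(len(pool))]
            copy = _Spec(
                gene_id=new_id("nlr"),
                kind="nlr",
                family=founder.family,
                steps=source.steps + 1,
                nlr_class=founder.nlr_class,
                event_type=ev,
                cnl_route=founder.cnl_route,
                block=founder.block,
            )
            if ev in ("tandem", "proximal", "dispersed") and rng.random() < cfg.p_pseudogenize:
                kill = None
                if kill_probs.sum() > 0:
                    total = kill_probs.sum()
                    draw = rng.random()
                    if draw < total:
                        kill = kill_reasons[
                            int(np.searchsorted(np.cumsum(kill_probs), draw, side="right"))
                        ]
                pseudo_copies.append(
                    {"spec": copy, "source": source, "chrom": terr["chrom"], "kill": kill}
                )
                continue
            if ev == "tandem":
                pos = terr["items"].index(source)
                terr["items"].insert(pos + 1, copy)
                living.append(copy)
            elif ev == "proximal":
                d = int(rng.integers(2, 21))
                fillers = [
                    _Spec(gene_id=new_id("g"), kind="background", block=founder.block)
                    for _ in range(d - 1)
                ]
                terr["items"].extend(fillers + [copy])
                living.append(copy)
            elif ev == "dispersed":
                others = [c for c in chroms if c != terr["chrom"]]
                target = others[rng.integers(len(others))]
                copy.block = -1
                bg_by_chrom.setdefault(target, []).append(copy)
                living.append(copy)
            else:  # segmental: two parallel 5-gene runs on two chromosomes
                block_counter[0] += 1
                src_items, cpy_items = [], []
                for k in range(4):
                    a = _Spec(
                        gene_id=new_id("g"),
                        kind="background",
                        family=f"{founder.family}_seg{block_counter[0]}_{k}",
                        event_type="segmental",
                        block=block_counter[0],
                    )
                    b = replace(a, gene_id=new_id("g"))
                    src_items.append(a)
                    cpy_items.append(b)
                src_nlr = replace(
                    copy, gene_id=new_id("nlr"), event_type="segmental", block=block_counter[0]
                )
                cpy_nlr = _Spec(
                    gene_id=new_id("nlr"),
                    kind="nlr",
                    family=founder.family,
                    steps=src_nlr.steps + 1,
                    nlr_class=founder.nlr_class,
                    event_type="segmental",
                    cnl_route=founder.cnl_route,
                    block=block_counter[0],
                )
                src_items.append(src_nlr)
                cpy_items.append(cpy_nlr)
                others = [c for c in chroms if c != terr["chrom"]]
                target = others[rng.integers(len(others))]
                seg_blocks.append({"chrom": terr["chrom"], "items": src_items})
                seg_blocks.append({"chrom": target, "items": cpy_items})
                living.extend([src_nlr, cpy_nlr])

    # --- flatten chromosome gene orders
    order: dict[str, list[_Spec]] = {}
    locus_window: dict[str, tuple[str, int]] = {}
    if cfg.separate_loci:
        n_windows = cfg.chrom_len // cfg.window_size
        slots = [
            (c, w) for c in chroms for w in range(0, n_windows, 3)
        ]
        if len(territories) > len(slots):
            raise ValueError(
                "separate_loci: too many founders for the window grid; "
                "increase chrom_len or reduce n_nlr_founders"
            )
        order = {c: [] for c in chroms}
        pending: dict[str, list[tuple[int, list[_Spec]]]] = defaultdict(list)
        for terr, (c, w) in zip(territories, slots):
            pending[c].append((w, terr["items"]))
            for s in terr["items"]:
                locus_window[s.gene_id] = (c, w)
        for blk in seg_blocks:
            raise AssertionError("separate_loci requires p_segmental = 0")
        for c in chroms:
            for w, items in sorted(pending[c]):
                order[c].extend(items)
    else:
        for c in chroms:
            content: list[tuple[float, int, list[_Spec]]] = [
                (rng.random(), i, [s]) for i, s in enumerate(bg_by_chrom[c])
            ]
            blocks = [t["items"] for t in territories if t["chrom"] == c]
            blocks += [b["items"] for b in seg_blocks if b["chrom"] == c]
            for j, items in enumerate(blocks):
                content.append((rng.random(), 10_000 + j, items))
            content.sort(key=lambda x: (x[0], x[1]))
            order[c] = [s for _, _, grp in content for s in grp]
    if cfg.include_chr0:
        order["Chr0"] = chr0_specs

    # --- exon structures and coordinates
    genes: list[GeneModel] = []
    gene_by_id: dict[str, GeneModel] = {}
    free_gaps: dict[str, list[tuple[int, int]]] = defaultdict(list)
    all_intron_lens: list[int] = []

    def make_exons(spec_rng: np.random.Generator) -> tuple[list[tuple[int, int]], int]:
        n_ex = int(spec_rng.integers(2, 5))
        ex_lens = spec_rng.integers(150, 601, size=n_ex)
        in_lens = np.maximum(
            20, spec_rng.normal(cfg.mean_intron_len, cfg.intron_sd, size=n_ex - 1)
        ).astype(int)
        exons, off = [], 0
        for i, el in enumerate(ex_lens):
            exons.append((off, off + int(el) - 1))
            off += int(el)
            if i < len(in_lens):
                off += int(in_lens[i])
        all_intron_lens.extend(int(x) for x in in_lens)
        return exons, off

    for c, items in order.items():
        clen = chrom_lens[c]
        structures = [make_exons(rng) for _ in items]
        total_bp = sum(L for _, L in structures)
        # small gaps inside a planted block keep loci compact; the remaining
        # space is spread over the block boundaries
        small = [
            2000 + int(rng.integers(0, 3000))
            for _ in range(max(0, len(items) - 1))
        ]
        big_idx = [
            i
            for i in range(len(items) - 1)
            if items[i].block == -1
            or items[i].block != items[i + 1].block
        ]
        if cfg.separate_loci:
            # pin each locus to its window
            cursor = 1000
            cur_window: Optional[tuple[str, int]] = None
            prev_end = 0
            for (spec, (exons, length)) in zip(items, structures):
                w = locus_window.get(spec.gene_id)
                if w is not None and w != cur_window:
                    cur_window = w
                    target = w[1] * cfg.window_size + 1000
                    if target < cursor:
                        raise ValueError("separate_loci: window overflow")
                    cursor = target
                start = cursor
                end = start + length - 1
                if end > clen:
                    raise ValueError(
                        f"chromosome {c} full; increase chrom_len"
                    )
                if cur_window is not None and end > (cur_window[1] + 1) * cfg.window_size:
                    raise ValueError("separate_loci: locus exceeds its window")
                g = GeneModel(
                    gene_id=spec.gene_id,
                    genotype=gt,
                    chrom=c,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=[(start + s, start + e) for s, e in exons],
                    aed=round(float(np.clip(rng.normal(0.2, 0.05), 0, 1)), 2),
                )
                genes.append(g)
                gene_by_id[g.gene_id] = g
                if prev_end and start - prev_end > 1:
                    free_gaps[c].append((prev_end + 1, start - 1))
                prev_end = end
                cursor = end + 1 + 1500 + int(rng.integers(0, 1500))
            if prev_end < clen:
                free_gaps[c].append((prev_end + 1, clen))
        else:
            n_big = len(big_idx)
            reserve = total_bp + sum(small) + 2000
            free = clen - reserve
            if free < max(1, n_big) * 1000:
                raise ValueError(f"chromosome {c} full; increase chrom_len")
            if n_big:
                raw = rng.uniform(0.5, 1.5, size=n_big + 1)
                big_gaps = (raw / raw.sum() * free * 0.95).astype(int)
            else:
                big_gaps = np.array([int(free * 0.5)])
            cursor = 1 + int(big_gaps[0])
            big_used = 1
            prev_end = 0
            for i, (spec, (exons, length)) in enumerate(zip(items, structures)):
                start = cursor
                end = start + length - 1
                if end > clen:
                    raise ValueError(f"chromosome {c} full; increase chrom_len")
                g = GeneModel(
                    gene_id=spec.gene_id,
                    genotype=gt,
                    chrom=c,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=[(start + s, start + e) for s, e in exons],
                    aed=round(float(np.clip(rng.normal(0.2, 0.05), 0, 1)), 2),
                )
                genes.append(g)
                gene_by_id[g.gene_id] = g
                if prev_end and start - prev_end > 1:
                    free_gaps[c].append((prev_end + 1, start - 1))
                prev_end = end
                if i < len(items) - 1:
                    gap = small[i]
                    if i in big_idx and big_used < len(big_gaps):
                        gap = int(big_gaps[big_used])
                        big_used += 1
                    cursor = end + 1 + max(500, gap)
            if prev_end < clen:
                free_gaps[c].append((prev_end + 1, clen))

    q99 = float(np.quantile(all_intron_lens, 0.99)) if all_intron_lens else 1000.0

    # --- proteins
    specs = {s.gene_id: s for items in order.values() for s in items}
    for p in pseudo_copies:
        specs[p["spec"].gene_id] = p["spec"]
    proteome: dict[str, str] = {}
    founder_seq: dict[str, str] = {}
    # founders first, then copies by increasing decay depth
    for s in sorted(specs.values(), key=lambda s: (s.steps, s.gene_id)):
        if s.kind != "nlr":
            if s.gene_id in gene_by_id:
                proteome[s.gene_id] = "".join(
                    AA_ALPHABET[rng.integers(len(AA_ALPHABET), size=cfg.protein_len // 2)]
                )
            continue
        if s.steps == 0:
            seq = "".join(AA_ALPHABET[rng.integers(len(AA_ALPHABET), size=cfg.protein_len)])
            founder_seq[s.family] = seq
        else:
            base = founder_seq.get(s.family)
            seq = _mutate(rng, base, cfg.identity_decay * s.steps)
        if s.gene_id in gene_by_id:  # pseudogenized copies have no protein
            proteome[s.gene_id] = seq

    # --- domain / motif evidence
    pfam_hits, hmm_hits = [], []
    parser_cc: set[str] = set()
    coils_cc: set[str] = set()
    L = cfg.protein_len
    nbarc_span = (max(1, L // 4), max(2, L // 4 + L // 3))
    for s in specs.values():
        gid = s.gene_id
        if gid not in gene_by_id:
            continue
        if s.kind == "decoy":
            hmm_hits.append(
                DomainHit(gid, "custom_hmm", NBARC, _loguniform(rng, -3.9, -2.5), 10, 60)
            )
            continue
        if s.kind != "nlr":
            continue
        seed_ev = _loguniform(rng, -80, -61)
        pfam_hits.append(DomainHit(gid, "pfam_hmm", NBARC, seed_ev, *nbarc_span))
        pfam_hits.append(
            DomainHit(gid, "pfam_hmm", LRR, _loguniform(rng, -30, -15), L - L // 4, L)
        )
        hmm_hits.append(
            DomainHit(gid, "custom_hmm", NBARC, _loguniform(rng, -30, -10), *nbarc_span)
        )
        if s.nlr_class == "TNL":
            pfam_hits.append(
                DomainHit(gid, "pfam_hmm", TIR, _loguniform(rng, -60, -41), 1, L // 5)
            )
        elif s.nlr_class == "RNL":
            pfam_hits.append(
                DomainHit(gid, "pfam_hmm", RPW8, _loguniform(rng, -55, -41), 1, L // 5)
            )
        elif s.nlr_class == "CNL":
            if s.cnl_route == "rx":
                pfam_hits.append(
                    DomainHit(gid, "pfam_hmm", RX, _loguniform(rng, -35, -20), 1, L // 5)
                )
            else:
                parser_cc.add(gid)
                coils_cc.add(gid)

    # --- similarity hits (one direction per unordered pair)
    similarity: list[SimilarityHit] = []
    fam_members: dict[str, list[_Spec]] = defaultdict(list)
    for s in specs.values():
        if s.kind == "nlr" and s.gene_id in gene_by_id:
            fam_members[s.family].append(s)
    for fam, members in sorted(fam_members.items()):
        members.sort(key=lambda s: s.gene_id)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                pident = max(30.0, 100.0 - cfg.identity_decay * (a.steps + b.steps))
                similarity.append(
                    SimilarityHit(
                        query_id=a.gene_id,
                        subject_id=b.gene_id,
                        pct_identity=round(pident, 1),
                        align_len=cfg.protein_len,
                        evalue=_loguniform(rng, -80, -40),
                        q_start=1,
                        q_end=cfg.protein_len,
                        s_start=1,
                        s_end=cfg.protein_len,
                    )
                )
    # segmental background pairs
    seg_partners: dict[str, list[_Spec]] = defaultdict(list)
    for s in specs.values():
        if s.event_type == "segmental" and s.kind == "background":
            seg_partners[s.family].append(s)
    for fam, pair in sorted(seg_partners.items()):
        if len(pair) == 2 and all(p.gene_id in gene_by_id for p in pair):
            a, b = sorted(pair, key=lambda s: s.gene_id)
            similarity.append(
                SimilarityHit(
                    query_id=a.gene_id,
                    subject_id=b.gene_id,
                    pct_identity=round(95.0 - float(rng.uniform(0, 3)), 1),
                    align_len=cfg.protein_len // 2,
                    evalue=_loguniform(rng, -90, -60),
                    q_start=1,
                    q_end=cfg.protein_len // 2,
                    s_start=1,
                    s_end=cfg.protein_len // 2,
                )
            )

    # --- pseudoexon evidence
    pseudoexons: list[PseudoexonHit] = []
    repeat_hits: list[tuple[str, float]] = []
    translated: list[tuple[str, str]] = []
    pseudo_truth: list[PseudoTruth] = []
    for p in pseudo_copies:
        spec, source, chrom, kill = p["spec"], p["source"], p["chrom"], p["kill"]
        parent = source.gene_id
        if parent not in gene_by_id:
            parent = [
                m.gene_id for m in fam_members.get(spec.family, []) if m.gene_id in gene_by_id
            ]
            parent = parent[0] if parent else None
        if parent is None:
            continue
        n_frag = int(rng.integers(2, 5)) if kill == "gap" else int(rng.integers(1, 5))
        if kill == "short":
            aa_lens = rng.integers(10, 31, size=n_frag)
        else:
            aa_lens = rng.integers(40, 151, size=n_frag)
        if kill == "low_identity":
            idents = rng.uniform(20.0, 39.9, size=n_frag)
        else:
            base_ident = max(45.0, 100.0 - cfg.identity_decay * spec.steps - float(rng.uniform(0, 15)))
            idents = np.clip(rng.normal(base_ident, 3.0, size=n_frag), 41.0, 99.0)
        gaps = [int(rng.uniform(0.1, 0.8) * q99) for _ in range(n_frag - 1)]
        split_after = None
        if kill == "gap":
            split_after = int(rng.integers(0, n_frag - 1))
            gaps[split_after] = int(q99 * 1.5) + 10
        span = int(sum(aa_lens) * 3 + sum(gaps))
        # find a free intergenic interval big enough
        cands = [
            (c_lo, c_hi)
            for (c_lo, c_hi) in free_gaps[chrom]
            if c_hi - c_lo + 1 >= span + 2000
        ]
        if not cands:
            continue  # no room; copy silently not emitted (rare at desk scale)
        gi = int(rng.integers(len(cands)))
        g_lo, g_hi = cands[gi]
        free_gaps[chrom].remove((g_lo, g_hi))
        start = g_lo + 500
        frags: list[tuple[int, int]] = []
        pos = start
        for k in range(n_frag):
            f_start, f_end = pos, pos + int(aa_lens[k]) * 3 - 1
            frags.append((f_start, f_end))
            pos = f_end + 1 + (gaps[k] if k < n_frag - 1 else 0)
        if frags[-1][1] + 500 < g_hi:
            free_gaps[chrom].append((frags[-1][1] + 500, g_hi))
        for k, (f_start, f_end) in enumerate(frags):
            pseudoexons.append(
                PseudoexonHit(
                    parent_protein=parent,
                    genotype=gt,
                    chrom=chrom,
                    g_start=f_start,
                    g_end=f_end,
                    frame=int(rng.choice([-3, -2, -1, 1, 2, 3])),
                    pct_identity=round(float(idents[k]), 1),
                    aa_len=int(aa_lens[k]),
                    evalue=_loguniform(rng, -60, -21),
                )
            )
            if kill == "repeat":
                repeat_hits.append(
                    (f"{chrom}:{f_start}-{f_end}", _loguniform(rng, -10, -5.05))
                )
            elif kill is None and rng.random() < 0.1:
                # boundary exercise: repeat match exactly at the (strict) gate
                repeat_hits.append((f"{chrom}:{f_start}-{f_end}", 1e-5))
        # predicted downstream contigs and the 6-frame translation table
        if kill == "gap":
            first_starts = [frags[0][0], frags[split_after + 1][0]]
            expected = 2
        else:
            first_starts = [frags[0][0]]
            expected = 1
        contig_ids = [f"{gt}:{chrom}:{fs}:{parent}" for fs in first_starts]
        domain = KINASE if kill == "no_domain" else NBARC
        for cid in contig_ids:
            translated.append((cid, domain))
        if kill in ("short", "low_identity", "repeat", "no_domain"):
            expected = 0
        pseudo_truth.append(
            PseudoTruth(
                pseudo_id=spec.gene_id,
                parent=parent,
                genotype=gt,
                chrom=chrom,
                n_fragments=n_frag,
                kill=kill,
                expected_contigs=expected,
                contig_ids=contig_ids,
                fragments=frags,
            )
        )

    # --- rule-derived duplication truth (direct application of the
    # classification rules to the planted ranks, hits, and anchor blocks)
    gene_truth = _derive_dup_truth(order, specs, similarity, locus_window)

    ratings_pool = (
        ["susceptible", "moderately susceptible", "moderately resistant", "resistant", "tolerant"]
    )
    phenotype_ratings = [
        ratings_pool[int(rng.integers(len(ratings_pool)))] for _ in range(int(rng.integers(3, 7)))
    ]

    return GenotypeData(
        genotype=gt,
        regime=regime_name,
        genes=sorted(genes, key=lambda g: (g.chrom, g.start)),
        chrom_lens=chrom_lens,
        proteome=proteome,
        pfam_hits=pfam_hits,
        hmm_hits=hmm_hits,
        parser_cc=parser_cc,
        coils_cc=coils_cc,
        similarity=similarity,
        pseudoexons=pseudoexons,
        repeat_hits=repeat_hits,
        translated_domains=translated,
        phenotype_ratings=phenotype_ratings,
        truth=TruthTable(genes=gene_truth, pseudo=pseudo_truth, q99_intron=q99),
    )


def _derive_dup_truth(
    order: dict[str, list[_Spec]],
    specs: dict[str, _Spec],
    similarity: list[SimilarityHit],
    locus_window: dict[str, tuple[str, int]],
) -> dict[str, GeneTruth]:
    """Apply the duplicate-type rules directly to the planted layout.

    Independent of the pipeline's classifier: ranks come from the planted
    gene order, partners from the emitted similarity pairs, and anchors are
    the members of planted segmental blocks.
    """
    pos: dict[str, tuple[str, int]] = {}
    for c, items in order.items():
        for r, s in enumerate(items):
            pos[s.gene_id] = (c, r)
    partners: dict[str, set[str]] = defaultdict(set)
    for h in similarity:
        partners[h.query_id].add(h.subject_id)
        partners[h.subject_id].add(h.query_id)
    anchors = {
        gid for gid, s in specs.items() if s.event_type == "segmental" and gid in pos
    }
    truth: dict[str, GeneTruth] = {}
    for gid, (c, r) in pos.items():
        s = specs[gid]
        if gid in anchors:
            dup = "wgd_segmental"
        else:
            ps = partners.get(gid, set())
            dists = [abs(pos[q][1] - r) for q in ps if q in pos and pos[q][0] == c]
            if not ps:
                dup = "singleton"
            elif any(d == 1 for d in dists):
                dup = "tandem"
            elif any(2 <= d <= 20 for d in dists):
                dup = "proximal"
            else:
                dup = "dispersed"
        truth[gid] = GeneTruth(
            gene_id=gid,
            kind=s.kind,
            nlr_class=s.nlr_class,
            event_type=s.event_type,
            dup_truth=dup,
            family=s.family,
            steps=s.steps,
            locus_window=locus_window.get(gid),
        )
    return truth


def simulate_dataset(cfg: SimConfig) -> list[GenotypeData]:
    """All genotypes of one synthetic cohort."""
    return [simulate_genotype(cfg, i) for i in range(cfg.n_genotypes)]


# ---------------------------------------------------------------------------
# file emission (the exact dialects io_formats reads)
# ---------------------------------------------------------------------------


def write_genotype(data: GenotypeData, outdir: str | Path) -> dict[str, Path]:
    """Write one genotype's tables under outdir/<genotype>/; returns paths."""
    d = Path(outdir) / data.genotype
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gff"] = d / "annotation.gff3"
    write_gff3(data.genes, paths["gff"])

    paths["proteome"] = d / "proteome.faa"
    write_fasta(data.proteome, paths["proteome"])

    paths["chroms"] = d / "chroms.tsv"
    with open(paths["chroms"], "w") as fh:
        for c, ln in sorted(data.chrom_lens.items()):
            fh.write(f"{c}\t{ln}\n")

    paths["pfam"] = d / "interproscan.tsv"
    with open(paths["pfam"], "w") as fh:
        for h in data.pfam_hits:
            fh.write(
                f"{h.protein_id}\t-\t{len(data.proteome.get(h.protein_id, ''))}\tPfam\t"
                f"{h.accession}\tdomain\t{h.aa_start}\t{h.aa_end}\t{h.evalue:.3g}\n"
            )

    paths["hmm"] = d / "custom_hmm.tsv"
    with open(paths["hmm"], "w") as fh:
        for h in data.hmm_hits:
            fh.write(
                f"{h.protein_id}\t{h.accession}\t{h.evalue:.3g}\t{h.aa_start}\t{h.aa_end}\n"
            )

    paths["parser"] = d / "nlr_parser.tsv"
    with open(paths["parser"], "w") as fh:
        for pid in sorted(data.parser_cc):
            fh.write(f"{pid}\tCC\n")

    paths["coils"] = d / "coils.tsv"
    with open(paths["coils"], "w") as fh:
        for pid in sorted(data.coils_cc):
            fh.write(f"{pid}\tCC\n")

    def fmt12(q, s, pid, ln, qs, qe, ss, se, ev):
        return f"{q}\t{s}\t{pid}\t{ln}\t0\t0\t{qs}\t{qe}\t{ss}\t{se}\t{ev:.3g}\t100\n"

    paths["similarity"] = d / "blastp.tsv"
    with open(paths["similarity"], "w") as fh:
        ids = sorted(data.proteome)
        if ids:  # one self-hit row exercises the reader's drop logic
            fh.write(fmt12(ids[0], ids[0], 100.0, 100, 1, 100, 1, 100, 0.0))
        for h in data.similarity:
            fh.write(
                fmt12(
                    h.query_id, h.subject_id, h.pct_identity, h.align_len,
                    h.q_start, h.q_end, h.s_start, h.s_end, h.evalue,
                )
            )

    paths["pseudoexons"] = d / "tblastn.tsv"
    with open(paths["pseudoexons"], "w") as fh:
        for h in data.pseudoexons:
            ss, se = (h.g_start, h.g_end) if h.frame > 0 else (h.g_end, h.g_start)
            fh.write(
                fmt12(h.parent_protein, h.chrom, h.pct_identity, h.aa_len, 1, h.aa_len, ss, se, h.evalue)
            )

    paths["repeats"] = d / "repeats.tsv"
    with open(paths["repeats"], "w") as fh:
        for hid, ev in data.repeat_hits:
            fh.write(fmt12(hid, "repeat_consensus", 90.0, 50, 1, 50, 1, 150, ev))

    paths["translated"] = d / "translated_domains.tsv"
    with open(paths["translated"], "w") as fh:
        for cid, acc in data.translated_domains:
            fh.write(f"{cid}\t{acc}\n")

    paths["phenotype"] = d / "phenotype.csv"
    with open(paths["phenotype"], "w") as fh:
        fh.write("clone,disease,rating,evidence\n")
        for i, r in enumerate(data.phenotype_ratings):
            fh.write(f"{data.genotype},disease{i % 3},{r},inoculation\n")

    tdir = d / "truth"
    tdir.mkdir(exist_ok=True)
    with open(tdir / "genes.tsv", "w") as fh:
        fh.write(
            "gene_id\tkind\tnlr_class\tevent_type\tdup_truth\tfamily\tsteps\tlocus_chrom\tlocus_window\n"
        )
        for t in data.truth.genes.values():
            lc, lw = t.locus_window if t.locus_window else ("", "")
            fh.write(
                f"{t.gene_id}\t{t.kind}\t{t.nlr_class or ''}\t{t.event_type}\t"
                f"{t.dup_truth}\t{t.family or ''}\t{t.steps}\t{lc}\t{lw}\n"
            )
    with open(tdir / "pseudogenes.tsv", "w") as fh:
        fh.write(
            "pseudo_id\tparent\tchrom\tn_fragments\tkill\texpected_contigs\tcontig_ids\n"
        )
        for t in data.truth.pseudo:
            fh.write(
                f"{t.pseudo_id}\t{t.parent}\t{t.chrom}\t{t.n_fragments}\t"
                f"{t.kill or 'none'}\t{t.expected_contigs}\t{';'.join(t.contig_ids)}\n"
            )
    with open(tdir / "summary.tsv", "w") as fh:
        fh.write(f"genotype\t{data.genotype}\nregime\t{data.regime}\n")
        fh.write(f"q99_intron\t{data.truth.q99_intron}\n")
    return paths


def write_dataset(dataset: list[GenotypeData], outdir: str | Path) -> None:
    for data in dataset:
        write_genotype(data, outdir)
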