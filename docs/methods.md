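# Methods

This note documents the models, thresholds, numerical choices, and known
limitations of the `nlrcnv` pipeline. All genomic coordinates are 1-based
inclusive (GFF3 convention) throughout the in-memory model; half-open
arithmetic appears only inside individual operations (e.g. the BED writer
and interval-tree queries).

## NLR identification and architecture

NLR calling follows the standard two-tier evidence design for plant immune
receptors. Seed domains are taken from Pfam scans at stringent gates —
NB-ARC (PF00931) at e ≤ 1e-60, TIR (PF01582, PF13676) and RPW8 (PF05659) at
e ≤ 1e-40, both inclusive — and their amino-acid substrings are extracted
for profile-HMM construction. To remove redundancy before HMM building,
domain sequences are clustered greedily: sequences are processed in
decreasing length (ties by id), each joining the first centroid it matches
at ≥ 98% identity, else founding a new cluster. Identity is defined as
matches / alignment columns of a global alignment scored match +1,
mismatch 0, linear gap −1 — gaps count as columns. Tools like USEARCH use a
slightly different internal identity; at a 98% threshold on near-duplicate
domains the difference is immaterial, and the oracle tests pin this
definition. Profile-HMM search itself is external: the package emits
representative FASTA and consumes hit tables.

A protein is called an NLR if it has a custom-HMM hit to NB-ARC/TIR/RPW8 at
e ≤ 1e-4, or a CC motif call from an NLR-motif parser. A coiled-coil
prediction (COILS) alone is *not* sufficient. Architecture is assigned by
first matching rule, TIR → TNL, RPW8 → RNL, (Rx N-terminal PF18052, or
parser CC ∧ COILS CC) → CNL, else NL; proteins with both TIR and RPW8 are
logged and classed TNL. `complete` means canonical N-terminal + NB-ARC +
LRR. NB-ARC-only proteins fall through to NL with `complete=False` and
`has_lrr=False`, so they remain separable for the annotation-quality
checks. Interproscan-reported Pfam hits are treated as domain presence with
no further e-value gate (Interproscan pre-filters its matches); the 1e-4
gate applies to the NLR call itself.

Two choices here are ours rather than forced by convention: (i) multi-mRNA
genes are classified on the longest mRNA's protein (one protein per gene
matches per-gene counting); (ii) the NB-ARC "relative position" used as an
assembly-fragmentation diagnostic is defined as the distance of the gene's
genomic midpoint to the nearer scaffold end, normalised by scaffold length
(range [0, 0.5]) — a formula consistent with the prediction that fragmented
assemblies push NB-ARCs toward scaffold ends. Proteins with only a parser
CC call and no NB-ARC evidence are retained as NLRs but carry
`has_nbarc=False` so they can be reported separately.

## Duplication typing and collinear chaining

Genes of one genotype are sorted by (chromosome, start, end, id) and given
0-based ranks per chromosome. Similarity input is an all-vs-all protein
search filtered at e ≤ 1e-10 with self-hits removed.

Collinear blocks are found per chromosome pair by dynamic-programming
chaining over rank points: a point may extend a chain only if both rank
increments are positive (the second genome's consistently negative for
inverted blocks) and at most `max_gaps` (20); chain score is
`match_score·|anchors| + gap_penalty·Σ((Δr_a−1)+(|Δr_b|−1))` with
match_score 50 and gap_penalty −1; chains of ≥ `match_size` (5) anchors are
reported. Chains are extracted greedily by descending score and a hit
consumed by one block is not reused; ties break toward the
earliest-starting chain. Within-chromosome chains are allowed only when the
two rank intervals do not overlap — this also prevents tandem ladders
(a1→a2, a2→a3, …) from masquerading as blocks.

Each gene then receives exactly one duplication type with precedence
`wgd_segmental > tandem > proximal > dispersed > singleton`: block anchors
are WGD/segmental; otherwise a same-chromosome partner at rank distance 1
makes a tandem, at distance 2–20 a proximal (the bound is a parameter:
"≤ 20 genes away" is read as rank distance, and 21 is dispersed); any other
partner dispersed; none, singleton. The classifier is verified against a
direct-rule oracle on 1,000 random genomes per test run. MCScanX's
repeat-control parameters (repCut/repDiv) are not reimplemented; at the
scales analysed here tandem families are small and the precedence rule
handles them.

## NLR cluster detection

Windows of 1 Mbp tile each chromosome from coordinate 1. A gene is counted
in the window holding the majority (> 50%) of its span; an exact 50/50
split is assigned to the left window so every NLR is counted exactly once,
and genes longer than a window use the same largest-overlap rule. Merging
adjacent occupied windows to a fixpoint equals taking maximal runs of
consecutive occupied windows (the fixpoint is unique and order-independent;
tested against literal iterated pairwise merging). Runs with ≥ 3 NLRs are
clusters. Unplaced scaffolds ("Chr0") are excluded from clustering — window
adjacency is meaningless on unordered sequence — but Chr0 genes still count
in per-chromosome totals. No significance model is attached to clusters.

## Pseudogene identification

Candidate pseudoexons (protein-vs-genome hits of NLR proteins at e ≤ 1e-20)
pass four filters, applied in a fixed order with per-reason removal counts:
(a) no overlap with any annotated gene span (≥ 1 bp overlap removes);
(b) length > 30 aa (a 30-aa hit is removed); (c) identity > 40% (40.0% is
removed); (d) no repeat-library match at e < 1e-5 (exactly 1e-5 is kept —
the gate is strict). Filtering is a pure subset operation and relaxing (b)
or (c) can only grow the surviving set.

The intron-length distribution is pooled from **all** annotated genes of
the genotype (not NLRs only), with intron length = next exon start −
previous exon end − 1; the 99th percentile is the linearly interpolated
empirical quantile. "Inside the 99th percentile" is read inclusively:
fragments link when gap ≤ q99.

Linking operates per (genotype, chromosome, best-hit parent): the best-hit
parent of a locus is the lowest-e-value hit (ties by higher identity, then
lexicographic parent id); overlapping same-parent fragments are merged with
a logged message; sorted fragments chain transitively while gaps stay
within q99. A fragment of a *different* parent lying between two fragments
of the same parent does not break their chain — the criteria are parent
identity and gap only, which also matches the exhaustive
maximal-chain-partition oracle used in tests. Strand/frame concordance
across chained fragments is recorded but not enforced. Single-fragment
contigs count as pseudogenes (a one-exon parent can yield a one-exon
pseudogene); a `min_exons` parameter is exposed for stricter analyses.
Finally, contigs whose 6-frame translation (consumed as a table) lacks all
common NLR domains — LRR (PF00560/PF07725/PF12799/PF13855), NB-ARC
(PF00931), TIR (PF01582/PF13676), RPW8 (PF05659), CC (PF18052) — are
removed. The per-genotype pseudogene:parent ratio is n_pseudogenes /
n_distinct parents, displayed to one decimal.

## CNV statistics

High/Low CNV groups are *computed*, not hard-coded at any observed gap: an
exhaustive scan of the n−1 sorted cut points of total NLR counts minimises
within-group sum of squares (1-D 2-means), the larger-mean side is HighCNV,
and a gap statistic (between-cluster gap / total range) quantifies how
discrete the split is. Group summaries report mean, SEM = sd/√n, and
t-based 95% CIs (the CI method is our choice; single-member groups report
no SEM/CI).

The Mann–Whitney U test uses U = #{x>y} + ½#{x=y}. For combined n ≤ 12 the
two-sided p is exact — every C(n, n_x) assignment of pooled values is
enumerated and p = min(1, 2·min(P(U ≤ u), P(U ≥ u))); larger samples use
the normal approximation with tie correction (scipy). All-tied samples
return p = 1. The complete-vs-partial architecture comparison is a Pearson
chi-square with 1 df and no continuity correction (checked against the
exact conditional distribution over fixed margins in tests). Phenotype
ratings map susceptible/mod. susceptible/mod. resistant/tolerant/resistant
to 1/2/3/4/4; the mean classifies ≤ 2 susceptible, ≥ 3 resistant, between
unclassified; field-incidence and "intermediate" records are expected to be
removed upstream. Negative-binomial GLM
(`count ~ group * nlr_class`, α = 1) and a companion ANOVA are
library-delegated to statsmodels and reported as coefficient tables — they
are reporting, not part of the pipeline's computation.

## Synthetic cohorts

The generator emulates the *evidence tables* of a multi-genotype NLR
survey; it does not simulate nucleotide sequence, molecular evolution
(codon models, dN/dS), or transposable elements. Defaults describe a desk-
scale cohort: 5 genotypes (high/low duplication regimes in roughly 7:4
proportion), 10 chromosomes of 5 Mbp plus a 1-Mbp unplaced Chr0, 400
background genes and 30 NLR founder loci per genotype, founders
concentrated on Chr5/6/7/10 with 5:1 weight (≈ 77% of founders on the four
hotspot chromosomes). Regimes: high = 3 duplication events per founder with
type probabilities tandem .50 / proximal .30 / dispersed .15 /
segmental .05; low = 1 event with .05/.05/.20/.10 (40% of low-regime events
fire at all). These rates give ≥ 2-fold NLR-count separation between
regimes in essentially all seeds, echoing a bimodal CNV structure. Copy
identity decays linearly at 1.5% per duplication event — enough to exercise
the 98% representative-clustering threshold (first-generation copies merge
with their founder, deeper copies do not) while keeping all family pairs
well above similarity-search gates; this is a bookkeeping decay, not a
substitution model. Intron lengths are normal(400, 250) truncated at 20 bp,
giving a q99 near 1 kb. 5% of background genes are decoys carrying a
near-threshold (e ≈ 1e-3) custom-HMM hit to exercise the 1e-4 call gate.

Placement works at the gene-order level first (tandem copies inserted
adjacent to their source; proximal copies appended 2–20 ranks away behind
filler genes; dispersed copies moved to another chromosome; segmental
events emitting two parallel 5-gene runs on two chromosomes), then
coordinates are assigned: compact 2–5 kb gaps inside a planted locus, the
remaining space spread over locus boundaries. In `separate_loci` mode each
locus is pinned to a 1-Mbp window with ≥ 2 empty windows between loci
(background genes are omitted in this mode), so cluster recovery has an
exact planted answer.

With probability 0.15 a local/dispersed copy is emitted as 1–4 pseudoexon
fragments in intergenic space instead of a gene. By default ~30% of those
copies violate exactly one pseudogene criterion (6% each: all fragments
≤ 30 aa; all ≤ 40% identity; repeat hits at e < 1e-5 on every fragment; one
inter-fragment gap > q99, splitting the copy in two; only a non-NLR domain
in the translation table), making the filter chain testable criterion by
criterion. A tenth of surviving fragments receive a repeat hit at exactly
1e-5 to pin the strict `<` boundary.

Duplication-type truth is derived by applying the classification rules
directly to the planted layout (planted ranks, emitted similarity pairs,
planted anchor blocks) — an independent re-statement of the rules, not a
call into the classifier — alongside the raw planted event type. Everything
is deterministic for a fixed (seed, genotype-index) pair and every emitted
record is covered by the truth tables.

What passing on synthetic data does *not* show: robustness to annotation
noise (split/merged gene models), to similarity-search artefacts (partial
alignments, domain-only hits), to repeat-rich regions, or to real
intron-length distributions with heavy tails; the generator's families are
also small (≤ ~10 copies), so repeat-control behaviour of collinearity
tools on huge tandem arrays is out of scope.

## Problem sizes and determinism

Test and acceptance runs use desk-scale cohorts (hundreds of genes, dozens
of NLR families per genotype) — chosen so that exhaustive oracles
(all-pairs rules, full permutation enumeration, exhaustive chain search)
remain feasible alongside the pipeline. The pipeline is deterministic for
fixed inputs; stage outputs are plain TSV/GFF3 written before the next
stage starts, re-runs skip completed stages unless forced, and every report
number traces to a stage file. Floating-point output is formatted at fixed
precision so repeated runs produce byte-identical reports.
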