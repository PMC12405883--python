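# nlrcnv

Analysis pipeline for **NLR copy-number variation** across multiple genotypes
of a plant species.

Nucleotide-binding leucine-rich-repeat receptors (NLRs) are intracellular
plant immune receptors that evolve by birth-and-death: repeated duplication
followed by retention or pseudogenization. Comparing the NLR complements of
several de-novo-assembled genotypes of one species requires a chain of
annotation-level analyses, each with its own thresholds. This package
implements that chain as tested, composable modules, for anyone studying
gene-family expansion from per-genotype gene models and homology-evidence
tables:

1. **NLR identification and architecture** (`nlr_classify`) — seed-domain
   selection from Pfam scans (NB-ARC PF00931 at e ≤ 1e-60; TIR
   PF01582/PF13676 and RPW8 PF05659 at e ≤ 1e-40), greedy centroid
   clustering of domain sequences at ≥ 98% global-alignment identity to pick
   representatives for profile-HMM construction, the NLR call gate (custom-HMM
   hit at e ≤ 1e-4, or a motif-parser CC call), and architecture classes
   TNL / RNL / CNL / NL with precedence TIR > RPW8 > CC.
2. **Duplication typing** (`dup_classify`) — genes ranked by chromosomal
   position; dynamic-programming chaining of all-vs-all BLASTp hits
   (e ≤ 1e-10) into collinear blocks (match_score 50, gap_penalty −1,
   match_size 5, max_gaps 20); each gene assigned one of
   `wgd_segmental > tandem > proximal > dispersed > singleton`, where tandem
   means a same-chromosome partner at rank distance 1 and proximal at
   distance 2–20.
3. **NLR cluster detection** (`cluster_detect`) — NLRs counted in
   non-overlapping 1-Mbp windows (a gene must overlap a window by > 50% to be
   counted; an exact 50/50 split goes left), adjacent occupied windows merged
   to a fixpoint, merged runs with ≥ 3 NLRs called clusters.
4. **Pseudogene identification** (`pseudogene_id`) — tBLASTn-style hits of
   NLR proteins against the genome (e ≤ 1e-20) filtered to non-genic regions,
   > 30 aa, > 40% identity, and no repeat-library match at e < 1e-5;
   surviving pseudoexons of the same best-hit parent linked into contigs when
   the gap between fragments is inside the 99th percentile of the intron
   length distribution; contigs without a common NLR domain in 6-frame
   translation removed.
5. **CNV statistics** (`cnv_stats`) — per-genotype count matrix; High/Low CNV
   grouping by exhaustive 1-D 2-means over total NLR counts; group means,
   SEM, t-based 95% CIs; Mann–Whitney U with an exact-permutation branch for
   small cohorts; ordinal phenotype scoring (susceptible = 1 …
   tolerant = resistant = 4, mean ≤ 2 susceptible, ≥ 3 resistant); Pearson
   chi-square on complete-vs-partial architectures; negative-binomial
   GLM / ANOVA reporting via statsmodels.
6. **Synthetic cohorts** (`simulate`) — multi-genotype datasets with planted
   ground truth for every stage (duplication events, clusters, degraded
   copies with per-filter violations), so the whole pipeline is verifiable
   without any external data.

## Worked example

Generate a five-genotype synthetic cohort (three high-duplication, two
low-duplication regimes, 10 chromosomes × 5 Mbp + unplaced Chr0) and run the
analysis chain:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_classify_nlrs.py
python analysis/03_duplication_types.py
python analysis/04_clusters.py
python analysis/05_pseudogenes.py
python analysis/06_cnv_stats.py
```

Output of the chain (seed 1):

```
GT00 (high): 738 genes, 117 planted NLRs, 8 pseudogenized copies
GT03 (low):  501 genes,  45 planted NLRs, 1 pseudogenized copies
...
GT00: 117 NLRs (NL 58, CNL 40, TNL 19, RNL 0; 59 complete)
GT00: 117 NLRs, 89 tandem+proximal, 13 segmental, 5 collinear blocks
GT00: 8 clusters, mean size 14.0
GT00: 5 pseudogenes from 5 parents (ratio 1.0; q99 intron 1008 bp; ...)
group labels: {'GT04': 'LowCNV', 'GT03': 'LowCNV', 'GT01': 'HighCNV', ...}
High - Low mean NLR difference: 74.50
Mann-Whitney U = 6.0, p = 0.2
```

Reading this: classification recovers every planted NLR (117/117 for GT00)
and no decoys; most NLR duplicates in high-regime genotypes are tandem or
proximal, so NLRs concentrate into windowed clusters; the 2-means split
recovers the planted high/low regimes exactly, and the High−Low mean
difference quantifies the copy-number gap (the exact Mann–Whitney p of 0.2
reflects the tiny cohort: 2/C(5,2) labelings are as extreme).

The same chain is available as a CLI over real evidence tables
(`nlrcnv simulate | classify | duplicates | clusters | pseudogenes | stats |
run-all`, configured by YAML; see `nlrcnv --help`). Per-stage outputs are
plain TSV/GFF3/BED so any stage can be inspected or re-run standalone;
re-runs skip completed stages unless `--force` is given.

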