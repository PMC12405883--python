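"""Group-level CNV statistics, phenotype scoring, and sanity metrics.

Genotypes are split into High/Low CNV groups by an exhaustive 1-D 2-means
over total NLR counts (minimising within-group sum of squares over the
n-1 sorted cut points).  Group contrasts use a Mann-Whitney U test with an
exact permutation branch for small samples; the complete-vs-partial
architecture comparison uses a Pearson chi-square without continuity
correction.  Negative-binomial GLM and ANOVA fits are delegated to
statsmodels and reported, not reimplemented.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from nlrcnv.cluster_detect import NLRCluster, cluster_summary
from nlrcnv.nlr_classify import NLRRecord
from nlrcnv.pseudogene_id import PseudogeneContig, pseudogene_parent_ratio

logger = logging.getLogger(__name__)

NLR_CLASSES = ("NL", "CNL", "TNL", "RNL")
EXACT_MW_MAX_N = 12


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: Optional[float]
    ci95: Optional[tuple[float, float]]


@dataclass(frozen=True)
class PhenotypeScale:
    """ICGD-style ordinal disease ratings mapped to a 1-4 numeric scale."""

    mapping: tuple = (
        ("susceptible", 1.0),
        ("moderately susceptible", 2.0),
        ("moderately resistant", 3.0),
        ("tolerant", 4.0),
        ("resistant", 4.0),
    )
    susceptible_max: float = 2.0
    resistant_min: float = 3.0

    def score(self, rating: str) -> float:
        d = dict(self.mapping)
        key = rating.strip().lower()
        if key not in d:
            raise ValueError(f"unknown phenotype rating {rating!r}")
        return d[key]


# ---------------------------------------------------------------------------
# CNV matrix
# ---------------------------------------------------------------------------


def build_cnv_matrix(
    nlr_records: Iterable[NLRRecord],
    pseudogenes: Iterable[PseudogeneContig],
    clusters: Iterable[NLRCluster],
    genotypes: Optional[Sequence[str]] = None,
    gene_chroms: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-genotype table: class counts, total, pseudogenes, cluster count
    and mean size, and (when ``gene_chroms`` maps gene_id -> chromosome)
    per-chromosome NLR counts."""
    nlr_records = list(nlr_records)
    pseudogenes = list(pseudogenes)
    clusters = list(clusters)
    gts = set(r.genotype for r in nlr_records)
    gts |= {p.genotype for p in pseudogenes} | {c.genotype for c in clusters}
    if genotypes is not None:
        missing = gts - set(genotypes)
        if missing:
            raise ValueError(f"records for unlisted genotypes: {sorted(missing)}")
        gts = set(genotypes)
    rows = {}
    for gt in sorted(gts):
        rows[gt] = {c: 0 for c in NLR_CLASSES}
        rows[gt]["total"] = 0
        rows[gt]["pseudogenes"] = 0
    for r in nlr_records:
        rows[r.genotype][r.nlr_class] += 1
        rows[r.genotype]["total"] += 1
    for p in pseudogenes:
        rows[p.genotype]["pseudogenes"] += 1
    summ = cluster_summary(clusters)
    ratios = pseudogene_parent_ratio(pseudogenes)
    for gt in rows:
        n, mean_size = summ.get(gt, (0, None))
        rows[gt]["n_clusters"] = n
        rows[gt]["mean_cluster_size"] = np.nan if mean_size is None else mean_size
        _, _, ratio = ratios.get(gt, (0, 0, None))
        rows[gt]["pseudogene_parent_ratio"] = np.nan if ratio is None else ratio
    if gene_chroms:
        chroms = sorted(set(gene_chroms.values()))
        for gt in rows:
            for ch in chroms:
                rows[gt][f"n_{ch}"] = 0
        for r in nlr_records:
            ch = gene_chroms.get(r.gene_id)
            if ch is not None:
                rows[r.genotype][f"n_{ch}"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "genotype"
    return df


# ---------------------------------------------------------------------------
# CNV grouping
# ---------------------------------------------------------------------------


def assign_cnv_groups(totals: dict[str, float]) -> tuple[dict[str, str], float]:
    """Exhaustive 1-D 2-means on total NLR counts.

    Scans the n-1 cut points of the sorted totals, minimising within-group
    sum of squares; the larger-mean side is HighCNV.  Returns the labels
    and a gap statistic (between-cluster gap / total range) quantifying how
    discrete the split is.  All-equal totals yield a single LowCNV group
    and gap 0.
    """
    if len(totals) < 2:
        raise ValueError("need at least 2 genotypes")
    items = sorted(totals.items(), key=lambda kv: (kv[1], kv[0]))
    values = np.array([v for _, v in items], dtype=float)
    if np.all(values == values[0]):
        logger.warning("all totals equal; no CNV split")
        return {gt: "LowCNV" for gt, _ in items}, 0.0
    best_cut, best_wss = None, np.inf
    for cut in range(1, len(values)):
        lo, hi = values[:cut], values[cut:]
        wss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if wss < best_wss:
            best_wss, best_cut = wss, cut
    labels = {}
    for i, (gt, _) in enumerate(items):
        labels[gt] = "LowCNV" if i < best_cut else "HighCNV"
    gap = (values[best_cut] - values[best_cut - 1]) / (values[-1] - values[0])
    return labels, float(gap)


def group_summary(
    values_by_group: dict[str, Sequence[float]],
) -> tuple[dict[str, GroupSummary], float]:
    """Mean, SEM (sd/sqrt n), and t-based 95% CI per group, plus the
    High - Low mean difference."""
    out = {}
    for grp, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"empty group {grp}")
        mean = float(arr.mean())
        if arr.size == 1:
            out[grp] = GroupSummary(group=grp, n=1, mean=mean, sem=None, ci95=None)
        else:
            sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
            tcrit = stats.t.ppf(0.975, arr.size - 1)
            out[grp] = GroupSummary(
                group=grp,
                n=int(arr.size),
                mean=mean,
                sem=sem,
                ci95=(mean - tcrit * sem, mean + tcrit * sem),
            )
    diff = np.nan
    if "HighCNV" in out and "LowCNV" in out:
        diff = out["HighCNV"].mean - out["LowCNV"].mean
    return out, float(diff)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample x: #{x_i > y_j} + 0.5 #{x_i == y_j}."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For combined n <= 12 the p-value is exact, by enumerating every
    assignment of the pooled values to the two samples
    (p = 2 * min(P(U <= u), P(U >= u)), capped at 1); larger samples use
    the normal approximation with tie correction.  All-tied samples give
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return u, 1.0
    n = pooled.size
    if n <= EXACT_MW_MAX_N:
        us = np.array(
            [
                _u_statistic(pooled[list(idx)], np.delete(pooled, list(idx)))
                for idx in combinations(range(n), x.size)
            ]
        )
        p_le = float(np.mean(us <= u))
        p_ge = float(np.mean(us >= u))
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u, p


# ---------------------------------------------------------------------------
# phenotype scoring
# ---------------------------------------------------------------------------


def phenotype_score(
    ratings: Sequence[str], s: PhenotypeScale = PhenotypeScale()
) -> tuple[Optional[float], str]:
    """Average the numeric ratings; mean <= 2 is susceptible, >= 3
    resistant, in between unclassified; no ratings -> no_information."""
    if not ratings:
        return None, "no_information"
    mean = float(np.mean([s.score(r) for r in ratings]))
    if mean <= s.susceptible_max:
        cls = "susceptible"
    elif mean >= s.resistant_min:
        cls = "resistant"
    else:
        cls = "unclassified"
    return mean, cls


def read_phenotype_table(path) -> dict[str, list[str]]:
    """ICGD-style phenotype CSV (clone, disease, rating, evidence-type) ->
    ratings per clone.

    Field-incidence records and non-discernable ratings (e.g.
    "intermediate") are dropped, since incidence in the field depends on
    environment rather than genotype.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    known = {k for k, _ in PhenotypeScale().mapping}
    out: dict[str, list[str]] = defaultdict(list)
    for _, row in df.iterrows():
        if "evidence" in df.columns and "field" in str(row["evidence"]).lower():
            continue
        rating = str(row["rating"]).strip().lower()
        if rating not in known:
            continue
        out[str(row["clone"])].append(rating)
    return dict(out)


# ---------------------------------------------------------------------------
# complete-vs-partial table
# ---------------------------------------------------------------------------


def complete_partial_table(
    records_by_group: dict[str, Iterable[NLRRecord]],
) -> tuple[pd.DataFrame, Optional[float], Optional[float]]:
    """2x2 complete/partial counts per CNV group with a Pearson chi-square
    (1 df, no continuity correction).  Returns (table, chi2, p); the test is
    absent when any marginal is zero."""
    counts = {}
    for grp, recs in records_by_group.items():
        recs = list(recs)
        n_complete = sum(r.complete for r in recs)
        counts[grp] = {"complete": n_complete, "partial": len(recs) - n_complete}
    table = pd.DataFrame.from_dict(counts, orient="index")
    arr = table.to_numpy()
    if arr.shape != (2, 2) or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return table, None, None
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return table, float(chi2), float(p)


def pearson_chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# GLM / ANOVA reporting (library-delegated)
# ---------------------------------------------------------------------------


def report_glms(counts: pd.DataFrame) -> dict:
    """Fit the reporting models on a long-format count table with columns
    ``count``, ``group``, ``nlr_class``.

    Fits a negative-binomial GLM  count ~ group + nlr_class + group:nlr_class
    and a companion OLS/ANOVA on the same design; returns coefficient tables.
    Non-convergence is logged and yields a partial report.
    """
    import warnings

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if counts.empty:
        raise ValueError("empty count table")
    report: dict = {}
    formula = "count ~ C(group) * C(nlr_class)"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = smf.glm(formula, data=counts, family=sm.families.NegativeBinomial(alpha=1.0)).fit()
        report["nb_glm"] = {
            "params": nb.params.to_dict(),
            "pvalues": nb.pvalues.to_dict(),
            "converged": bool(nb.converged),
        }
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("negative-binomial GLM failed: %s", exc)
        report["nb_glm"] = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(formula, data=counts).fit()
            anova = sm.stats.anova_lm(ols, typ=2)
        report["anova"] = anova.to_dict()
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("ANOVA failed: %s", exc)
        report["anova"] = None
    return report
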