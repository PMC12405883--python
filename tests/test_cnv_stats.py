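"""CNV grouping, group summaries, Mann-Whitney, phenotype, chi-square, GLMs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nlrcnv.cnv_stats import (
    PhenotypeScale,
    assign_cnv_groups,
    build_cnv_matrix,
    complete_partial_table,
    group_summary,
    mann_whitney,
    pearson_chi2_2x2,
    phenotype_score,
    report_glms,
)
from nlrcnv.nlr_classify import NLRRecord


def rec(gt, cls="NL", complete=False, gid=None):
    return NLRRecord(
        gene_id=gid or f"{gt}_{cls}_{np.random.default_rng().integers(1 << 30)}",
        genotype=gt,
        nlr_class=cls,
        has_nbarc=True,
        has_lrr=True,
        has_tir=cls == "TNL",
        has_rpw8=cls == "RNL",
        has_cc=cls == "CNL",
        complete=complete,
    )


class TestCnvMatrix:
    def test_totals_and_conservation(self):
        records = [rec("A", "NL"), rec("A", "NL"), rec("A", "CNL"), rec("B", "TNL")]
        df = build_cnv_matrix(records, [], [])
        assert df.loc["A", "total"] == 3 and df.loc["A", "NL"] == 2
        assert df.loc["B", "total"] == 1
        assert (df[["NL", "CNL", "TNL", "RNL"]].sum(axis=1) == df["total"]).all()

    def test_per_chromosome_counts_sum_to_total(self, small_cohort):
        _, dataset = small_cohort
        records = []
        chroms = {}
        for d in dataset:
            for t in d.truth.genes.values():
                if t.kind == "nlr":
                    records.append(rec(d.genotype, t.nlr_class, gid=t.gene_id))
            for g in d.genes:
                chroms[g.gene_id] = g.chrom
        df = build_cnv_matrix(records, [], [], gene_chroms=chroms)
        chrom_cols = [c for c in df.columns if c.startswith("n_Chr")]
        assert (df[chrom_cols].sum(axis=1) == df["total"]).all()

    def test_unlisted_genotype_is_error(self):
        with pytest.raises(ValueError):
            build_cnv_matrix([rec("A")], [], [], genotypes=["B"])


class TestCnvGroups:
    def test_derived_two_cluster_split(self):
        totals = {"a": 80, "b": 85, "c": 95, "d": 300, "e": 310}
        labels, gap = assign_cnv_groups(totals)
        assert {g for g, l in labels.items() if l == "HighCNV"} == {"d", "e"}
        assert gap == pytest.approx((300 - 95) / (310 - 80))

    def test_two_values_one_each(self):
        labels, _ = assign_cnv_groups({"a": 100, "b": 200})
        assert labels == {"a": "LowCNV", "b": "HighCNV"}

    def test_identical_totals_no_split(self):
        labels, gap = assign_cnv_groups({"a": 5, "b": 5, "c": 5})
        assert set(labels.values()) == {"LowCNV"} and gap == 0.0

    def test_equals_bruteforce_partition(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(2, 10))
            totals = {f"g{i}": float(rng.integers(0, 400)) for i in range(n)}
            if len(set(totals.values())) == 1:
                continue
            labels, _ = assign_cnv_groups(totals)
            vals = np.array(sorted(totals.values()))
            best = min(
                range(1, n),
                key=lambda c: ((vals[:c] - vals[:c].mean()) ** 2).sum()
                + ((vals[c:] - vals[c:].mean()) ** 2).sum(),
            )
            thr = vals[best]
            assert all(
                (l == "HighCNV") == (totals[g] >= thr) for g, l in labels.items()
            )


class TestGroupSummary:
    def test_printed_means_reproduce_difference(self):
        # group means equal to the published ones by construction
        out, diff = group_summary(
            {"HighCNV": [314.86] * 7, "LowCNV": [89.75] * 4}
        )
        assert diff == pytest.approx(225.11)

    def test_sem_and_ci(self):
        out, _ = group_summary({"HighCNV": [1, 2, 3], "LowCNV": [1]})
        s = out["HighCNV"]
        assert s.mean == 2 and s.sem == pytest.approx(1 / math.sqrt(3))
        assert s.ci95[0] < 2 < s.ci95[1]
        assert out["LowCNV"].sem is None


class TestMannWhitney:
    def test_complete_separation_small(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)  # 2/20 labelings

    def test_identical_samples_p1(self):
        _, p = mann_whitney([2, 2], [2, 2])
        assert p == 1.0

    def test_seven_vs_four_separation(self):
        u, p = mann_whitney(list(range(101, 108)), [1, 2, 3, 4])
        assert u == 28
        assert p == pytest.approx(2 / 330)

    def test_exact_branch_equals_full_enumeration_all_small_partitions(self):
        """Independent enumeration oracle for every n <= 8 split."""
        rng = np.random.default_rng(21)
        for n in range(2, 9):
            pooled = rng.integers(0, 6, size=n).astype(float)  # ties included
            for k in range(1, n):
                x, y = pooled[:k], pooled[k:]
                u, p = mann_whitney(x, y)
                us = []
                for idx in itertools.combinations(range(n), k):
                    xs = pooled[list(idx)]
                    ys = np.delete(pooled, list(idx))
                    us.append(
                        (xs[:, None] > ys[None, :]).sum()
                        + 0.5 * (xs[:, None] == ys[None, :]).sum()
                    )
                us = np.array(us)
                if np.all(pooled == pooled[0]):
                    expected = 1.0
                else:
                    expected = min(
                        1.0, 2 * min((us <= u).mean(), (us >= u).mean())
                    )
                assert p == pytest.approx(expected)

    def test_large_sample_uses_normal_approximation(self):
        x = list(range(20))
        y = list(range(10, 30))
        _, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)


class TestPhenotype:
    @pytest.mark.parametrize(
        "ratings,mean,cls",
        [
            (["susceptible", "susceptible"], 1.0, "susceptible"),
            (["moderately resistant", "resistant"], 3.5, "resistant"),
            (["moderately susceptible", "moderately resistant"], 2.5, "unclassified"),
            (["tolerant"], 4.0, "resistant"),
            (["moderately susceptible"], 2.0, "susceptible"),  # <=2 boundary
            ([], None, "no_information"),
        ],
    )
    def test_scoring(self, ratings, mean, cls):
        m, c = phenotype_score(ratings)
        assert c == cls
        if mean is None:
            assert m is None
        else:
            assert m == pytest.approx(mean)

    def test_unknown_rating_rejected(self):
        with pytest.raises(ValueError):
            phenotype_score(["intermediate"])

    def test_phenotype_table_drops_field_incidence_and_intermediate(self, tmp_path):
        from nlrcnv.cnv_stats import read_phenotype_table

        p = tmp_path / "ph.csv"
        p.write_text(
            "clone,disease,rating,evidence\n"
            "A,wilt,susceptible,inoculation\n"
            "A,wilt,resistant,field incidence\n"
            "A,wilt,intermediate,inoculation\n"
            "B,rot,tolerant,inoculation\n"
        )
        table = read_phenotype_table(p)
        assert table == {"A": ["susceptible"], "B": ["tolerant"]}
        assert phenotype_score(table["A"]) == (1.0, "susceptible")

    def test_scale_invariant(self):
        s = PhenotypeScale()
        assert s.susceptible_max < s.resistant_min


class TestCompletePartial:
    def test_published_proportions_and_chi2(self):
        groups = {
            "LowCNV": [rec("L", complete=i < 24) for i in range(335)],
            "HighCNV": [rec("H", complete=i < 103) for i in range(2101)],
        }
        table, chi2, p = complete_partial_table(groups)
        assert table.loc["LowCNV", "complete"] == 24
        assert table.loc["LowCNV"].sum() == 335
        prop_low = table.loc["LowCNV", "complete"] / table.loc["LowCNV"].sum()
        prop_high = table.loc["HighCNV", "complete"] / table.loc["HighCNV"].sum()
        assert prop_low == pytest.approx(0.0716, abs=1e-4)
        assert prop_high == pytest.approx(0.0490, abs=1e-4)
        assert p > 0.05  # published conclusion: not significant

    def test_identical_proportions_statistic_zero(self):
        groups = {
            "LowCNV": [rec("L", complete=i < 5) for i in range(50)],
            "HighCNV": [rec("H", complete=i < 10) for i in range(100)],
        }
        _, chi2, _ = complete_partial_table(groups)
        assert chi2 == pytest.approx(0.0)

    def test_zero_marginal_no_test(self):
        groups = {
            "LowCNV": [rec("L", complete=False) for _ in range(10)],
            "HighCNV": [rec("H", complete=False) for _ in range(10)],
        }
        _, chi2, p = complete_partial_table(groups)
        assert chi2 is None and p is None

    def test_chi2_matches_exact_conditional_enumeration(self):
        """Pearson chi-square p vs the exact conditional distribution over all
        2x2 tables with the observed margins (hypergeometric oracle)."""
        observed = np.array([[8, 22], [3, 37]])
        chi2_obs, p = pearson_chi2_2x2(observed)
        row0, col0 = observed[0].sum(), observed[:, 0].sum()
        n = observed.sum()
        rv = stats.hypergeom(n, row0, col0)
        p_exact = 0.0
        for a in range(max(0, row0 + col0 - n), min(row0, col0) + 1):
            t = np.array([[a, row0 - a], [col0 - a, n - row0 - col0 + a]])
            chi2_t, _ = pearson_chi2_2x2(t)
            if chi2_t >= chi2_obs - 1e-12:
                p_exact += rv.pmf(a)
        # asymptotic vs exact agree to ~0.02 at these counts
        assert p == pytest.approx(p_exact, abs=0.03)


class TestGlms:
    def test_planted_group_effect_recovered(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(8):
            grp = "HighCNV" if i < 4 else "LowCNV"
            for cls in ("NL", "CNL", "TNL", "RNL"):
                lam = {"NL": 40, "CNL": 30, "TNL": 10, "RNL": 3}[cls]
                if grp == "HighCNV":
                    lam *= 3
                rows.append(
                    {
                        "genotype": f"g{i}",
                        "group": grp,
                        "nlr_class": cls,
                        "count": int(rng.poisson(lam)),
                    }
                )
        report = report_glms(pd.DataFrame(rows))
        params = report["nb_glm"]["params"]
        # baseline level is HighCNV (alphabetical); LowCNV coefficient < 0
        low_key = [k for k in params if "LowCNV" in k and ":" not in k][0]
        assert params[low_key] < 0
        assert report["nb_glm"]["converged"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            report_glms(pd.DataFrame())
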