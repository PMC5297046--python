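"""SNP-based allele partitioning, sufficiency filtering and allelic tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridhist.allelic import (ReadObs, allelic_level_test, allelic_ratio_test,
                                allelic_summary, filter_sufficient,
                                partition_by_allele)
from hybridhist.intervals import GeneAnnotation, GenomicInterval


def gene(gene_id, start, end, chrom="chr1"):
    return GeneAnnotation(GenomicInterval(chrom, start, end, "+", gene_id), gene_id)


SNPS = pd.DataFrame(
    {
        "chrom": ["chr1", "chr1", "chr1"],
        "pos": [100, 150, 500],
        "allele_P1": ["A", "G", "T"],
        "allele_P2": ["C", "T", "A"],
        "gene_id": ["G1", "G1", "G2"],
    }
)
GENES = [gene("G1", 50, 300), gene("G2", 400, 700)]


class TestPartition:
    def test_single_snp_assigns_to_matching_allele(self):
        reads = [ReadObs("chr1", 80, 140, {100: "A"})]
        out = partition_by_allele(reads, SNPS, GENES).set_index("gene_id")
        assert out.loc["G1", "count_P1"] == 1
        assert out.loc["G1", "count_P2"] == 0

    def test_conflicting_snps_are_unassigned(self):
        reads = [ReadObs("chr1", 80, 200, {100: "A", 150: "T"})]  # P1 then P2 base
        out = partition_by_allele(reads, SNPS, GENES).set_index("gene_id")
        assert out.loc["G1", "count_P1"] == 0
        assert out.loc["G1", "count_P2"] == 0
        assert out.loc["G1", "unassigned_count"] == 1

    def test_read_matching_neither_allele_unassigned(self):
        reads = [ReadObs("chr1", 80, 140, {100: "G"})]
        out = partition_by_allele(reads, SNPS, GENES).set_index("gene_id")
        assert out.loc["G1", "unassigned_count"] == 1

    def test_read_without_snp_not_counted(self):
        reads = [ReadObs("chr1", 200, 260, {})]
        out = partition_by_allele(reads, SNPS, GENES).set_index("gene_id")
        assert out.loc["G1"].drop("n_informative_snps").sum() == 0

    def test_conservation_invariant(self, rng):
        reads = []
        for _ in range(300):
            s = int(rng.integers(0, 700))
            bases = {}
            for pos, a1, a2 in zip(SNPS["pos"], SNPS["allele_P1"], SNPS["allele_P2"]):
                if s <= pos < s + 60:
                    bases[pos] = str(rng.choice([a1, a2, "N"]))
            reads.append(ReadObs("chr1", s, s + 60, bases))
        out = partition_by_allele(reads, SNPS, GENES).set_index("gene_id")
        for g in GENES:
            pos = SNPS[SNPS["gene_id"] == g.gene_id]["pos"]
            informative = [
                r for r in reads
                if any(r.start <= p < r.end for p in pos)
            ]
            total = out.loc[g.gene_id, ["count_P1", "count_P2", "unassigned_count"]].sum()
            assert total == len(informative)

    def test_snp_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            partition_by_allele([], SNPS, GENES, chrom_sizes={"chr1": 400})

    def test_snp_counts_reported_per_gene(self):
        out = partition_by_allele([], SNPS, GENES).set_index("gene_id")
        assert out["n_informative_snps"].to_dict() == {"G1": 2, "G2": 1}


class TestFilterSufficient:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "sample_id", "count_P1", "count_P2",
                     "n_informative_snps", "unassigned_count"],
        )

    def test_no_snps_excluded(self):
        t = self._table([("G1", "s1", 50, 50, 0, 0)])
        assert filter_sufficient(t) == []

    def test_meeting_minima_in_all_samples_included(self):
        t = self._table([("G1", "s1", 6, 6, 3, 0), ("G1", "s2", 5, 5, 3, 0)])
        assert filter_sufficient(t) == ["G1"]

    def test_one_failing_sample_excludes_gene(self):
        t = self._table([("G1", "s1", 6, 6, 3, 0), ("G1", "s2", 2, 2, 3, 0)])
        assert filter_sufficient(t) == []

    def test_synthetic_fraction_matches_recount(self, simdata):
        sub = simdata.allelic[simdata.allelic["mark"] == "K4me3"]
        got = set(filter_sufficient(sub, 2, 10))
        # independent recount
        expected = set()
        for gid, grp in sub.groupby("gene_id"):
            ok = ((grp["n_informative_snps"] >= 2)
                  & (grp["count_P1"] + grp["count_P2"] >= 10)).all()
            if ok:
                expected.add(gid)
        assert got == expected
        assert len(got) > 0
        # genes with < 2 SNPs exist by construction and are filtered out
        low = sub[sub["n_informative_snps"] < 2]["gene_id"].unique()
        assert len(low) > 0 and not (set(low) & got)


class TestRatioTest:
    def _parents(self, levels):
        return pd.DataFrame(levels, columns=["P1", "P2"],
                            index=[f"G{i+1}" for i in range(len(levels))])

    def _allelic(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "sample_id", "count_P1", "count_P2",
                           "n_informative_snps", "unassigned_count"],
        )

    def test_half_parental_split_is_null(self):
        tab = self._allelic([("G1", "s1", 50, 100, 5, 0)])
        res = allelic_ratio_test(tab, self._parents([[100.0, 200.0]]))
        assert res.loc["G1", "pval"] >= 0.99

    def test_equal_parents_skewed_hybrid_matches_binomial_oracle(self):
        tab = self._allelic([("G1", "s1", 90, 10, 5, 0)])
        res = allelic_ratio_test(tab, self._parents([[100.0, 100.0]]))
        # oracle: exact two-sided binomial tail at 0.5
        expected = stats.binomtest(90, 100, 0.5, alternative="two-sided").pvalue
        assert res.loc["G1", "pval"] == pytest.approx(expected, rel=1e-12)
        assert res.loc["G1", "direction"] == "P1_up"

    def test_degenerate_expectation_flagged_not_tested(self):
        tab = self._allelic([("G1", "s1", 5, 5, 5, 0)])
        res = allelic_ratio_test(tab, self._parents([[100.0, 0.0]]))
        assert res.loc["G1", "direction"] == "untestable"
        assert not res.loc["G1", "testable"]

    def test_replicates_are_pooled(self):
        tab = self._allelic([("G1", "s1", 30, 10, 5, 0), ("G1", "s2", 30, 10, 5, 0)])
        res = allelic_ratio_test(tab, self._parents([[100.0, 100.0]]))
        assert res.loc["G1", "count_P1"] == 60


class TestLevelTestAndSummary:
    def _setup_archetype(self):
        """A gene whose P2 allele exceeds half-parental in both crosses while
        the P1 allele sits at expectation (elevated hybrid total carried by
        one allele)."""
        parents = {
            "P1": pd.DataFrame({"r1": [100.0], "r2": [100.0]}, index=["G1"]),
            "P2": pd.DataFrame({"r1": [100.0], "r2": [100.0]}, index=["G1"]),
        }
        disp = pd.Series({"G1": 0.02})
        tests = {}
        for cross in ("P1xP2", "P2xP1"):
            tab = pd.DataFrame(
                {
                    "gene_id": ["G1", "G1"],
                    "sample_id": [f"{cross}_r1", f"{cross}_r2"],
                    "count_P1": [50, 50],       # at expectation (half of 100)
                    "count_P2": [105, 100],     # roughly double the expectation
                    "n_informative_snps": [6, 6],
                    "unassigned_count": [0, 0],
                }
            )
            tests[cross] = allelic_level_test(tab, parents, disp, ["G1"])
        return tests

    def test_allele_specific_increase_detected_in_both_crosses(self):
        tests = self._setup_archetype()
        for cross, df in tests.items():
            p2 = df[df["allele"] == "P2"].iloc[0]
            p1 = df[df["allele"] == "P1"].iloc[0]
            assert p2["significant"] and p2["log2fc_vs_expected"] > 0
            assert not p1["significant"]

    def test_summary_labels_concordant_allelic_change(self):
        summary = allelic_summary(self._setup_archetype())
        assert summary.loc["G1", "classification"] == (
            "P2-allele up, concordant across crosses"
        )

    def test_recovery_of_injected_bias(self, simdata):
        """Genes with |allele bias| >= 1 log2 and enough assigned reads are
        detected by the pooled binomial ratio test at alpha = 0.05. The
        expected fractions come from the true parental means, so the check
        isolates the ratio test itself."""
        hits, n = 0, 0
        for mark in ("K4me3", "K9ac"):
            sub = simdata.allelic[simdata.allelic["mark"] == mark]
            cm = simdata.counts[mark]
            tm = simdata.truth.marks.query("mark == @mark").set_index("gene_id")
            parents = pd.DataFrame({"P1": tm["mu_P1"], "P2": tm["mu_P2"]})
            for cross in ("P1xP2", "P2xP1"):
                samples = [s for s in cm.counts.columns if s.startswith(cross)]
                csub = sub[sub["sample_id"].isin(samples)]
                res = allelic_ratio_test(csub, parents)
                pooled = csub.groupby("gene_id")[["count_P1", "count_P2"]].sum().sum(axis=1)
                biased = tm.index[tm["allele_biased"] & (tm["allele_bias_log2"].abs() >= 1)]
                for g in biased:
                    if g in res.index and pooled.get(g, 0) >= 50 and res.loc[g, "testable"]:
                        n += 1
                        hits += res.loc[g, "pval"] <= 0.05
        assert n >= 20
        assert hits / n >= 0.8

    def test_null_calibration_of_ratio_test(self, genome):
        from hybridhist.simulate import default_design, generate_counts
        from tests.test_simulate import null_effects

        data = generate_counts(genome, null_effects(), default_design(), seed=21)
        sub = data.allelic[data.allelic["mark"] == "K4me3"]
        tm = data.truth.marks.query("mark == 'K4me3'").set_index("gene_id")
        parents = pd.DataFrame({"P1": tm["mu_P1"], "P2": tm["mu_P2"]})
        samples = [s for s in sub["sample_id"].unique() if s.startswith("P1xP2")]
        res = allelic_ratio_test(sub[sub["sample_id"].isin(samples)], parents)
        res = res[res["testable"] & (res["count_P1"] + res["count_P2"] >= 20)]
        rate = (res["pval"] <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert rate <= 0.05 + 3 * se + 0.01
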