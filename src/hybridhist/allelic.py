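"""Allele-specific histone-modification analysis in F1 hybrids.

Hybrid reads are split between the two parental alleles using the SNPs that
distinguish the accessions: a read overlapping at least one informative SNP
is assigned to the allele its observed base(s) match; reads whose SNPs vote
for both alleles (or match neither) are left unassigned. Genes qualify for
allelic analysis only with enough informative SNPs and enough assigned
reads in every hybrid sample.

Two questions are asked per qualifying gene: does the allelic ratio in the
hybrid deviate from the ratio of the parental levels (exact binomial test),
and does each allele's level deviate from its expectation of half the
matching parent's level (NB test at the hybrid-contrast thresholds)? The
half-parental expectation always uses the parent of the allele's accession,
regardless of cross direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import ContrastSpec, nb_exact_pvalue
from .intervals import GeneAnnotation

MIN_SNPS = 2
MIN_READS = 10


@dataclass
class ReadObs:
    """A hybrid read interval with its observed bases at SNP positions."""

    chrom: str
    start: int
    end: int
    bases: dict[int, str] = field(default_factory=dict)  # pos (0-based) -> base


def partition_by_allele(
    reads: list[ReadObs],
    snps: pd.DataFrame,
    genes: list[GeneAnnotation],
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Tally per-gene allele-specific read counts for one hybrid sample.

    A read enters a gene's tally when it overlaps at least one of the gene's
    informative SNP positions; it is assigned to P1 or P2 when all its
    informative bases agree, and counted as unassigned on conflict or when
    no base matches either allele. Returns one row per gene with columns
    gene_id, count_P1, count_P2, n_informative_snps, unassigned_count.
    """
    if chrom_sizes is not None:
        bad = snps[~snps["chrom"].isin(chrom_sizes)]
        if len(bad):
            pos = bad.iloc[0]
            raise ValueError(f"SNP at {pos['chrom']}:{pos['pos']} outside any chromosome")
        over = snps[snps["pos"] >= snps["chrom"].map(chrom_sizes)]
        if len(over):
            pos = over.iloc[0]
            raise ValueError(f"SNP at {pos['chrom']}:{pos['pos']} outside any chromosome")

    by_chrom = {}
    for chrom, sub in snps.groupby("chrom"):
        sub = sub.sort_values("pos")
        by_chrom[chrom] = (
            sub["pos"].to_numpy(),
            sub["allele_P1"].to_numpy(),
            sub["allele_P2"].to_numpy(),
        )

    gene_order = [g.gene_id for g in genes]
    tallies = {g: [0, 0, 0] for g in gene_order}  # P1, P2, unassigned
    gene_by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom, []).append(g)

    for read in reads:
        entry = by_chrom.get(read.chrom)
        if entry is None:
            continue
        pos, a1, a2 = entry
        lo = np.searchsorted(pos, read.start, side="left")
        hi = np.searchsorted(pos, read.end, side="left")
        if hi <= lo:
            continue  # no informative SNP under the read
        votes = set()
        for i in range(lo, hi):
            base = read.bases.get(int(pos[i]))
            if base is None:
                continue
            if base == a1[i]:
                votes.add("P1")
            elif base == a2[i]:
                votes.add("P2")
        slot = {frozenset({"P1"}): 0, frozenset({"P2"}): 1}.get(frozenset(votes), 2)
        for g in gene_by_chrom.get(read.chrom, []):
            # the read must overlap an informative SNP inside this gene
            glo = np.searchsorted(pos, max(read.start, g.interval.start), side="left")
            ghi = np.searchsorted(pos, min(read.end, g.interval.end), side="left")
            if ghi > glo:
                tallies[g.gene_id][slot] += 1

    n_snps = snps.groupby("gene_id").size() if "gene_id" in snps else pd.Series(dtype=int)
    rows = []
    for g in genes:
        p1, p2, un = tallies[g.gene_id]
        ns = int(n_snps.get(g.gene_id, 0)) if len(n_snps) else _snps_in(snps, g)
        rows.append((g.gene_id, p1, p2, ns, un))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "count_P1", "count_P2", "n_informative_snps", "unassigned_count"],
    )


def _snps_in(snps: pd.DataFrame, gene: GeneAnnotation) -> int:
    sub = snps[snps["chrom"] == gene.chrom]
    return int(((sub["pos"] >= gene.interval.start) & (sub["pos"] < gene.interval.end)).sum())


def filter_sufficient(
    allelic: pd.DataFrame,
    min_snps: int = MIN_SNPS,
    min_reads: int = MIN_READS,
) -> list[str]:
    """Genes with enough informative SNPs and assigned reads in every sample.

    ``allelic`` holds one row per (gene, hybrid sample). The defaults
    (>=2 SNPs, >=10 assigned reads per sample) are declared conventions for
    the unstated 'sufficient SNPs' criterion, surfaced here so they are
    explicit in every output.
    """
    df = allelic.copy()
    df["assigned"] = df["count_P1"] + df["count_P2"]
    ok = (df["n_informative_snps"] >= min_snps) & (df["assigned"] >= min_reads)
    passing = ok.groupby(df["gene_id"]).all()
    return sorted(passing.index[passing])


def allelic_ratio_test(
    allelic: pd.DataFrame,
    parent_levels: pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Test hybrid allelic ratios against the parental ratio per gene.

    ``allelic`` rows are (gene, sample) tallies for the hybrid samples of
    one cross (replicates are pooled); ``parent_levels`` has columns
    ``P1`` and ``P2`` with normalized parental gene levels. The expected P1
    fraction is P1/(P1+P2); the p-value is the exact two-sided binomial
    tail. Genes whose expected fraction is 0 or 1 while the opposite allele
    has reads are flagged (``testable`` False), not tested.
    """
    pooled = allelic.groupby("gene_id")[["count_P1", "count_P2"]].sum()
    if genes is not None:
        pooled = pooled.loc[[g for g in genes if g in pooled.index]]
    rows = []
    for gene_id, row in pooled.iterrows():
        c1, c2 = int(row["count_P1"]), int(row["count_P2"])
        n = c1 + c2
        if gene_id not in parent_levels.index:
            continue
        l1, l2 = parent_levels.loc[gene_id, ["P1", "P2"]]
        tot = l1 + l2
        expected = float(l1 / tot) if tot > 0 else np.nan
        testable = n > 0 and np.isfinite(expected) and 0 < expected < 1
        if testable:
            p = stats.binomtest(c1, n, expected, alternative="two-sided").pvalue
            frac = c1 / n
            direction = "P1_up" if frac > expected else ("P1_down" if frac < expected else "none")
        else:
            p, direction = np.nan, "untestable"
        rows.append((gene_id, c1, c2, expected, p, direction, testable))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "count_P1", "count_P2", "expected_fraction",
                 "pval", "direction", "testable"],
    ).set_index("gene_id")


def allelic_level_test(
    allelic: pd.DataFrame,
    parent_norm: dict[str, pd.DataFrame],
    dispersions: pd.Series,
    genes: list[str],
    contrast_type: str = "hybrid_vs_MPV",
) -> pd.DataFrame:
    """Contrast each hybrid allele with half the matching parent's level.

    The expectation for the P1 allele is half the P1 parent's normalized
    level (and symmetrically for P2), scaled by the gene's SNP-assignable
    fraction so assigned allele reads are compared on a like-for-like scale.
    Uses the exact NB test at the hybrid thresholds (FC >= 1.25, p <= 0.05).
    """
    spec = ContrastSpec(contrast_type=contrast_type)
    df = allelic[allelic["gene_id"].isin(genes)].copy()
    df["assigned"] = df["count_P1"] + df["count_P2"]
    tot = df.groupby("gene_id")[["assigned", "unassigned_count"]].sum()
    q = tot["assigned"] / (tot["assigned"] + tot["unassigned_count"]).clip(lower=1)

    per_gene = df.groupby("gene_id")[["count_P1", "count_P2"]].sum()
    n_reps = df.groupby("gene_id").size()
    rows = []
    for allele in ("P1", "P2"):
        pn = parent_norm[allele]
        for gene_id in per_gene.index:
            if gene_id not in pn.index:
                continue
            k_obs = int(per_gene.loc[gene_id, f"count_{allele}"])
            n_h = int(n_reps[gene_id])
            expect_reps = 0.5 * q[gene_id] * pn.loc[gene_id].to_numpy(float)
            k_exp = int(np.rint(expect_reps.sum()))
            n_p = len(expect_reps)
            alpha = float(dispersions.get(gene_id, 0.05))
            p = nb_exact_pvalue(k_obs, k_exp, n_h, n_p, alpha)
            obs_mean = k_obs / n_h
            exp_mean = k_exp / n_p if n_p else np.nan
            log2fc = np.log2((obs_mean + 0.5) / (exp_mean + 0.5))
            sig = (2.0 ** abs(log2fc) >= spec.fc_threshold) and (p <= spec.p_threshold)
            rows.append((gene_id, allele, obs_mean, exp_mean, log2fc, p, sig))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "allele", "observed_mean", "expected_mean",
                 "log2fc_vs_expected", "pval", "significant"],
    )


def allelic_summary(level_tests: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Classify genes by allelic behaviour across the reciprocal crosses.

    ``level_tests`` maps cross direction (e.g. 'P1xP2') to the output of
    :func:`allelic_level_test`. A gene is e.g. 'P2-allele up, concordant
    across crosses' when the P2 allele is significantly above its
    half-parental expectation in both crosses while the P1 allele is not
    significant in either.
    """
    crosses = sorted(level_tests)
    merged = []
    for cross, df in level_tests.items():
        d = df.set_index(["gene_id", "allele"])[["significant", "log2fc_vs_expected"]]
        d.columns = pd.MultiIndex.from_product([[cross], d.columns])
        merged.append(d)
    wide = pd.concat(merged, axis=1)
    rows = []
    for gene_id in wide.index.get_level_values(0).unique():
        labels = []
        for allele in ("P1", "P2"):
            if (gene_id, allele) not in wide.index:
                continue
            row = wide.loc[(gene_id, allele)]
            sig = [bool(row[(c, "significant")]) for c in crosses]
            lfc = [float(row[(c, "log2fc_vs_expected")]) for c in crosses]
            if all(sig) and all(f > 0 for f in lfc):
                labels.append(f"{allele}-allele up, concordant across crosses")
            elif all(sig) and all(f < 0 for f in lfc):
                labels.append(f"{allele}-allele down, concordant across crosses")
            elif any(sig):
                labels.append(f"{allele}-allele changed in one cross")
        rows.append((gene_id, "; ".join(labels) if labels else "no allelic change"))
    return pd.DataFrame(rows, columns=["gene_id", "classification"]).set_index("gene_id")
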