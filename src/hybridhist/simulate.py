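"""Synthetic parent/hybrid ChIP-seq and RNA-seq data with known ground truth.

Emulates a two-accession design: two inbred parents (P1, P2) and their
reciprocal F1 hybrids (P1xP2, P2xP1), each with replicated ChIP samples for
four histone marks (H3K4me3, H3K9ac, H3K27me3, H3K9me2), an input control,
and RNA counts. The generator produces

* a toy genome: genes and transposable elements packed without overlap on a
  few chromosomes, TEs concentrated in a central pericentromeric span, and a
  biallelic SNP table distinguishing the parental haplotypes;
* gene-level count matrices drawn from a negative-binomial model
  (variance = mu + alpha * mu^2) whose group means encode injected parental
  differences, hybrid deviations from the mid-parent value (MPV) and
  allele-specific biases;
* per-base coverage tracks realising mark-specific spatial templates
  (active marks peak just 3' of the TSS, H3K27me3 covers gene bodies of a
  minority of genes, H3K9me2 covers TEs and the pericentromere);
* a truth table recording every injected effect, for recovery testing.

Hybrid means equal the mid-parent mean except where a non-additive effect is
injected; allele-level counts in hybrids split binomially at the parental
ratio except where an allelic bias is injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import CountMatrix, GeneAnnotation, GenomicInterval

MARKS = ("K4me3", "K9ac", "K27me3", "K9me2")
ACTIVE_MARKS = ("K4me3", "K9ac")
#: expected sign of the mark -> expression association
MARK_SIGN = {"K4me3": 1, "K9ac": 1, "K27me3": -1, "K9me2": -1}
HYBRIDS = ("P1xP2", "P2xP1")
GENOTYPES = ("P1", "P2") + HYBRIDS
ASSAYS = MARKS + ("input", "RNA")

LONG_TE_BP = 1500  # length cutoff separating long from short TEs


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------


@dataclass
class GenomeModel:
    """Layout of the toy genome."""

    n_chromosomes: int = 2
    chrom_length: int = 600_000
    pericentromere_frac: float = 0.25  # central span of each chromosome
    n_genes: int = 300
    n_tes: int = 120
    te_long_frac: float = 0.40  # mass of the length mixture at >= LONG_TE_BP
    te_short_range: tuple[int, int] = (200, 1400)
    te_long_range: tuple[int, int] = (1500, 5000)
    gene_length_range: tuple[int, int] = (600, 4000)  # log-uniform
    te_pericentromere_prob: float = 0.70
    snp_per_kb: float = 5.0  # SNP density within genes

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1000:
            raise ValueError("need >=1 chromosome of >=1 kb")
        if not 0 <= self.pericentromere_frac < 1:
            raise ValueError("pericentromere_frac must be in [0, 1)")
        for lo, hi in (self.te_short_range, self.te_long_range, self.gene_length_range):
            if not 0 < lo <= hi:
                raise ValueError("length ranges must satisfy 0 < lo <= hi")
        if not 0 <= self.te_long_frac <= 1 or not 0 <= self.te_pericentromere_prob <= 1:
            raise ValueError("fractions must be in [0, 1]")

    def pericentromere(self, chrom_index: int) -> tuple[int, int]:
        half = int(self.chrom_length * self.pericentromere_frac / 2)
        mid = self.chrom_length // 2
        return mid - half, mid + half


def _per_mark(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {m: float(value[m]) for m in MARKS}
    return {m: float(value) for m in MARKS}


@dataclass
class EffectModel:
    """Injected effect structure and noise model.

    Proportions of differentially modified genes default to the study
    conditions: ~6% of marked genes for the active marks, 14% for H3K27me3
    and 20% for H3K9me2 between the parents; ~20% of protein-coding genes
    carry H3K27me3. Hybrid non-additive fractions are configurable per cross
    direction (the reciprocal hybrids need not be symmetric; H3K27me3 is
    asymmetric by default, strongly non-additive in P1xP2).
    """

    frac_k27_target_genes: float = 0.20
    frac_k9me2_genes: float = 0.08  # protein-coding genes carrying K9me2
    frac_parental_dmg: dict = field(
        default_factory=lambda: {"K4me3": 0.06, "K9ac": 0.06, "K27me3": 0.14, "K9me2": 0.20}
    )
    parental_log2fc: float | tuple[float, float] = (1.0, 2.5)
    frac_hybrid_nonadditive: dict = field(
        default_factory=lambda: {
            "K4me3": {"P1xP2": 0.017, "P2xP1": 0.008},
            "K9ac": {"P1xP2": 0.017, "P2xP1": 0.008},
            "K27me3": {"P1xP2": 0.165, "P2xP1": 0.05},
            "K9me2": {"P1xP2": 0.008, "P2xP1": 0.017},
        }
    )
    hybrid_mpv_log2fc: float | tuple[float, float] = (1.0, 2.0)
    #: probability an injected non-additive effect lies above the MPV
    frac_above_mpv: dict = field(
        default_factory=lambda: {"K4me3": 0.9, "K9ac": 0.9, "K27me3": 0.85, "K9me2": 0.2}
    )
    frac_allele_biased: float = 0.10
    allele_bias_log2: float | tuple[float, float] = (1.0, 2.0)
    #: probability a mark effect propagates to expression (with the mark's sign)
    expression_coupling: float = 0.7
    frac_expression_dmg: float = 0.05  # mark-independent expression effects
    dispersion: dict = field(default_factory=lambda: {"chip": 0.05, "rna": 0.05})
    depth: float = 60.0  # mean reads per marked feature per sample
    #: RNA-seq runs deeper per gene than ChIP per peak; scales the RNA means
    rna_depth_factor: float = 4.0
    #: fraction of hybrid reads of a gene that carry an informative SNP, per SNP
    snp_capture_rate: float = 0.15
    background_level: float = 0.05  # unmarked-gene mean, as a fraction of depth
    #: guarantee one strongly K27me3-marked gene with below-MPV modification
    #: and above-MPV expression in both hybrids (FLC-style archetype)
    ensure_flc_like: bool = True

    def validate(self) -> None:
        fracs = [self.frac_k27_target_genes, self.frac_k9me2_genes,
                 self.frac_allele_biased, self.expression_coupling,
                 self.frac_expression_dmg]
        fracs += list(_per_mark(self.frac_parental_dmg).values())
        for mark in MARKS:
            fracs += list(self.frac_hybrid_nonadditive[mark].values())
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all proportions must lie in [0, 1]")
        if any(a < 0 for a in self.dispersion.values()):
            raise ValueError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class Genome:
    model: GenomeModel
    genes: list[GeneAnnotation]
    tes: list[GeneAnnotation]
    snps: pd.DataFrame  # chrom, pos, allele_P1, allele_P2, gene_id

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.model.chrom_length
            for i in range(self.model.n_chromosomes)
        }

    def snps_per_gene(self) -> pd.Series:
        counts = self.snps.groupby("gene_id").size() if len(self.snps) else pd.Series(dtype=int)
        return counts.reindex([g.gene_id for g in self.genes], fill_value=0)


@dataclass
class SyntheticTruth:
    """Ground truth of every injected effect.

    ``marks`` has one row per (gene_id, mark) for marked genes; ``expression``
    one row per protein-coding gene. Signed log2 effects use + for
    higher-in-P1 (parental), above-MPV (hybrid) and toward-the-P1-allele
    (allelic).
    """

    marks: pd.DataFrame
    expression: pd.DataFrame


@dataclass
class SimulatedData:
    genome: Genome
    counts: dict[str, CountMatrix]  # one per mark plus "RNA"
    allelic: pd.DataFrame  # gene_id, sample_id, mark, count_P1, count_P2, ...
    coverage: "CoverageSet"
    truth: SyntheticTruth
    design: pd.DataFrame


# --------------------------------------------------------------------------
# genome generation
# --------------------------------------------------------------------------


def _pack_region(rng, chrom: str, region: tuple[int, int], lengths: np.ndarray):
    """Place features of the given lengths in the region without overlap."""
    n = len(lengths)
    if n == 0:
        return np.zeros(0, dtype=int)
    free = (region[1] - region[0]) - int(lengths.sum())
    if free < 0:
        raise ValueError(
            f"infeasible packing on {chrom}: {int(lengths.sum())} bp of features "
            f"exceed the {region[1] - region[0]} bp region [{region[0]}, {region[1]})"
        )
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    starts = region[0] + np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return starts.astype(int)


def _sample_te_lengths(rng, model: GenomeModel, n: int) -> np.ndarray:
    long = rng.random(n) < model.te_long_frac
    lo_s, hi_s = model.te_short_range
    lo_l, hi_l = model.te_long_range
    out = rng.integers(lo_s, hi_s + 1, n)
    out[long] = rng.integers(lo_l, hi_l + 1, long.sum())
    return out


def generate_genome(model: GenomeModel, seed: int) -> Genome:
    """Lay out genes and TEs on the toy genome and draw parental SNPs.

    Genes occupy the chromosome arms; each TE falls in the pericentromeric
    span with probability ``te_pericentromere_prob``. Annotations are 0-based
    half-open with random strands. SNPs are drawn within genes at
    ``snp_per_kb`` expected density with distinct parental alleles.
    """
    model.validate()
    rng = np.random.default_rng([int(seed), 11])
    n_chr = model.n_chromosomes

    genes_per_chr = np.full(n_chr, model.n_genes // n_chr)
    genes_per_chr[: model.n_genes % n_chr] += 1
    tes_per_chr = np.full(n_chr, model.n_tes // n_chr)
    tes_per_chr[: model.n_tes % n_chr] += 1

    genes: list[GeneAnnotation] = []
    tes: list[GeneAnnotation] = []
    snp_rows = []
    bases = np.array(list("ACGT"))
    gid = tid = 0

    for ci in range(n_chr):
        chrom = f"chr{ci + 1}"
        peri = model.pericentromere(ci)
        lo, hi = model.gene_length_range
        glens = np.exp(rng.uniform(np.log(lo), np.log(hi), genes_per_chr[ci])).astype(int)
        tlens = _sample_te_lengths(rng, model, tes_per_chr[ci])
        in_peri = rng.random(len(tlens)) < model.te_pericentromere_prob

        # pericentromere: TEs only
        peri_starts = _pack_region(rng, chrom, peri, tlens[in_peri])
        # arms: genes plus the remaining TEs, interleaved
        arm_lens = np.concatenate([glens, tlens[~in_peri]])
        is_gene = np.concatenate(
            [np.ones(len(glens), bool), np.zeros((~in_peri).sum(), bool)]
        )
        order = rng.permutation(len(arm_lens))
        arm_lens, is_gene = arm_lens[order], is_gene[order]
        # split between the two arms proportionally to arm length
        arms = [(0, peri[0]), (peri[1], model.chrom_length)]
        arm_sizes = np.array([a[1] - a[0] for a in arms], float)
        which = rng.choice(2, len(arm_lens), p=arm_sizes / arm_sizes.sum())
        starts = np.empty(len(arm_lens), dtype=int)
        for a in (0, 1):
            sel = which == a
            starts[sel] = _pack_region(rng, chrom, arms[a], arm_lens[sel])

        for s, L, g in zip(starts, arm_lens, is_gene):
            strand = "+" if rng.random() < 0.5 else "-"
            if g:
                gid += 1
                name = f"G{gid:05d}"
                genes.append(
                    GeneAnnotation(
                        GenomicInterval(chrom, int(s), int(s + L), strand, name),
                        gene_id=name,
                        feature_class="protein_coding",
                    )
                )
            else:
                tid += 1
                name = f"TE{tid:05d}"
                tes.append(
                    GeneAnnotation(
                        GenomicInterval(chrom, int(s), int(s + L), strand, name),
                        gene_id=name,
                        feature_class="TE",
                    )
                )
        for s, L in zip(peri_starts, tlens[in_peri]):
            tid += 1
            name = f"TE{tid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            tes.append(
                GeneAnnotation(
                    GenomicInterval(chrom, int(s), int(s + L), strand, name),
                    gene_id=name,
                    feature_class="TE",
                )
            )

    for g in genes:
        n_snp = rng.poisson(model.snp_per_kb * g.length / 1000.0)
        n_snp = min(n_snp, g.length)
        pos = np.sort(rng.choice(g.length, n_snp, replace=False)) + g.interval.start
        a1 = rng.integers(0, 4, n_snp)
        a2 = (a1 + rng.integers(1, 4, n_snp)) % 4
        for p, i1, i2 in zip(pos, a1, a2):
            snp_rows.append((g.chrom, int(p), bases[i1], bases[i2], g.gene_id))

    snps = pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "allele_P1", "allele_P2", "gene_id"]
    )
    genes.sort(key=lambda g: (g.chrom, g.interval.start))
    tes.sort(key=lambda t: (t.chrom, t.interval.start))
    return Genome(model=model, genes=genes, tes=tes, snps=snps)


# --------------------------------------------------------------------------
# design and counts
# --------------------------------------------------------------------------


def default_design(n_replicates: int = 2) -> pd.DataFrame:
    """Sample sheet: 4 genotypes x replicates x (4 marks + input + RNA)."""
    rows = []
    for genotype in GENOTYPES:
        for assay in ASSAYS:
            for rep in range(1, n_replicates + 1):
                sid = f"{genotype}_{assay}_r{rep}"
                rows.append((sid, genotype, assay, rep))
    df = pd.DataFrame(rows, columns=["sample_id", "genotype", "assay", "replicate"])
    return df.set_index("sample_id")


def _draw_magnitude(rng, spec, n: int) -> np.ndarray:
    if isinstance(spec, (tuple, list)):
        return rng.uniform(spec[0], spec[1], n)
    return np.full(n, float(spec))


def nb_sample(rng, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mu + alpha*mu^2 (gamma-Poisson)."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / alpha, mu * alpha)
    return rng.poisson(lam)


def _validate_design(design: pd.DataFrame) -> None:
    for col in ("genotype", "assay", "replicate"):
        if col not in design.columns:
            raise ValueError(f"design is missing column {col!r}")
    present = set(map(tuple, design[["genotype", "assay"]].drop_duplicates().values))
    for genotype in GENOTYPES:
        for assay in ASSAYS:
            if (genotype, assay) not in present:
                raise ValueError(f"design is missing assay {assay!r} for {genotype!r}")
        for assay in ASSAYS:
            n = ((design["genotype"] == genotype) & (design["assay"] == assay)).sum()
            if n < 2 and assay != "input":
                raise ValueError(
                    f"need >=2 replicates of {genotype}/{assay}, found {n}"
                )


def _mark_base_levels(rng, genome: Genome, effects: EffectModel):
    """Base (parent-average) mean level per gene per mark, plus target sets.

    A shared per-gene 'activity' drives both active marks and expression so
    that expression correlates positively with H3K4me3/H3K9ac. H3K27me3
    targets get high K27 levels, attenuated (x0.2, not zero) active marks,
    and expression decreasing in the K27 level.
    """
    n = len(genome.genes)
    depth = effects.depth
    activity = np.exp(rng.normal(0.0, 0.8, n))
    activity /= activity.mean()
    k27_target = rng.random(n) < effects.frac_k27_target_genes
    k9me2_gene = rng.random(n) < effects.frac_k9me2_genes
    k27_level = np.exp(rng.normal(0.0, 0.5, n))  # relative, targets only

    bg = effects.background_level
    atten = np.where(k27_target | k9me2_gene, 0.2, 1.0)
    base = {
        "K4me3": depth * activity * atten,
        "K9ac": depth * activity * np.exp(rng.normal(0.0, 0.3, n)) * atten,
        "K27me3": np.where(k27_target, depth * k27_level, depth * bg),
        "K9me2": np.where(k9me2_gene, depth * np.exp(rng.normal(0.0, 0.5, n)), depth * bg),
    }
    marked = {
        "K4me3": ~k9me2_gene,
        "K9ac": ~k9me2_gene,
        "K27me3": k27_target,
        "K9me2": k9me2_gene,
    }
    # expression: follows activity; decreases with K27 level on K27 targets
    expr = effects.rna_depth_factor * depth * activity * np.exp(rng.normal(0.0, 0.3, n))
    expr = np.where(k27_target, expr * k27_level ** -0.7, expr)
    return base, marked, expr, k27_target


def generate_counts(
    genome: Genome,
    effects: EffectModel,
    design: pd.DataFrame,
    seed: int,
) -> SimulatedData:
    """Draw count matrices, allelic counts and coverage, with a truth table.

    Group means: parents differ by the injected parental log2 fold-change at
    flagged genes; each hybrid mean equals the mid-parent mean except at
    genes flagged non-additive for that cross, where it is scaled by
    2**(signed hybrid effect). Counts are NB(mean, dispersion); hybrid
    allele-level counts split binomially at the parental ratio, with the
    odds scaled by 2**bias at allele-biased genes.
    """
    effects.validate()
    _validate_design(design)
    rng = np.random.default_rng([int(seed), 23])
    gene_ids = [g.gene_id for g in genome.genes]
    n = len(gene_ids)

    base, marked, expr_base, k27_target = _mark_base_levels(rng, genome, effects)
    snps_per_gene = genome.snps_per_gene().to_numpy()

    depth_factor = pd.Series(
        rng.uniform(0.85, 1.2, len(design)), index=design.index, name="depth_factor"
    )

    parental_frac = _per_mark(effects.frac_parental_dmg)
    mark_rows = []
    mu = {}  # (mark, genotype) -> array over genes
    expr_plfc = np.zeros(n)
    expr_hlfc = {h: np.zeros(n) for h in HYBRIDS}

    for mark in MARKS:
        m = marked[mark]
        is_dmg = (rng.random(n) < parental_frac[mark]) & m
        pdir = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        plfc = np.where(is_dmg, pdir * _draw_magnitude(rng, effects.parental_log2fc, n), 0.0)
        mu_p1 = base[mark] * 2.0 ** (plfc / 2.0)
        mu_p2 = base[mark] * 2.0 ** (-plfc / 2.0)
        mpv = 0.5 * (mu_p1 + mu_p2)

        na = {}
        hlfc = {}
        for cross in HYBRIDS:
            frac = effects.frac_hybrid_nonadditive[mark][cross]
            na[cross] = (rng.random(n) < frac) & m
            hdir = np.where(rng.random(n) < effects.frac_above_mpv[mark], 1.0, -1.0)
            hlfc[cross] = np.where(
                na[cross], hdir * _draw_magnitude(rng, effects.hybrid_mpv_log2fc, n), 0.0
            )
        biased = (rng.random(n) < effects.frac_allele_biased) & m
        bdir = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        bias = np.where(biased, bdir * _draw_magnitude(rng, effects.allele_bias_log2, n), 0.0)

        coupled_p = (rng.random(n) < effects.expression_coupling) & is_dmg
        expr_plfc += np.where(coupled_p, MARK_SIGN[mark] * plfc * 0.7, 0.0)
        coupled_h = {}
        for cross in HYBRIDS:
            coupled_h[cross] = (rng.random(n) < effects.expression_coupling) & na[cross]
            # coupled genes carry the mark deviation into expression at full
            # magnitude, signed by the mark's regulatory role
            expr_hlfc[cross] += np.where(
                coupled_h[cross], MARK_SIGN[mark] * hlfc[cross], 0.0
            )

        if mark == "K27me3" and effects.ensure_flc_like and m.any():
            # FLC-style archetype: the strongest K27 target loses K27me3
            # relative to MPV in both hybrids and gains expression.
            arch = int(np.argmax(np.where(m, base[mark], -np.inf)))
            is_dmg[arch] = False
            plfc[arch] = 0.0
            mu_p1[arch] = mu_p2[arch] = base[mark][arch]
            mpv[arch] = base[mark][arch]
            for cross in HYBRIDS:
                na[cross][arch] = True
                hlfc[cross][arch] = -1.2
                coupled_h[cross][arch] = True
                expr_hlfc[cross][arch] += 1.2
            # the archetype gene is well expressed, as FLC is in C24
            expr_base[arch] = max(
                expr_base[arch], effects.depth * effects.rna_depth_factor
            )

        mu[(mark, "P1")] = mu_p1
        mu[(mark, "P2")] = mu_p2
        for cross in HYBRIDS:
            mu[(mark, cross)] = mpv * 2.0 ** hlfc[cross]

        df = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "mark": mark,
                "marked": m,
                "base_mean": base[mark],
                "is_parental_dmg": is_dmg,
                "parental_log2fc": plfc,
                "is_nonadditive_P1xP2": na["P1xP2"],
                "nonadditive_log2fc_P1xP2": hlfc["P1xP2"],
                "is_nonadditive_P2xP1": na["P2xP1"],
                "nonadditive_log2fc_P2xP1": hlfc["P2xP1"],
                "allele_biased": biased,
                "allele_bias_log2": bias,
                "expr_coupled_parental": coupled_p,
                "expr_coupled_P1xP2": coupled_h["P1xP2"],
                "expr_coupled_P2xP1": coupled_h["P2xP1"],
                "n_snps": snps_per_gene,
                "mu_P1": mu_p1,
                "mu_P2": mu_p2,
                "mu_P1xP2": mu[(mark, "P1xP2")],
                "mu_P2xP1": mu[(mark, "P2xP1")],
            }
        )
        mark_rows.append(df[df["marked"]].drop(columns="marked"))

    # expression means: mark-coupled effects plus independent ones
    indep = rng.random(n) < effects.frac_expression_dmg
    expr_plfc += np.where(
        indep, np.sign(rng.random(n) - 0.5) * rng.uniform(0.6, 1.5, n), 0.0
    )
    mu_e1 = expr_base * 2.0 ** (expr_plfc / 2.0)
    mu_e2 = expr_base * 2.0 ** (-expr_plfc / 2.0)
    mpv_e = 0.5 * (mu_e1 + mu_e2)
    mu[("RNA", "P1")], mu[("RNA", "P2")] = mu_e1, mu_e2
    for cross in HYBRIDS:
        mu[("RNA", cross)] = mpv_e * 2.0 ** expr_hlfc[cross]

    truth = SyntheticTruth(
        marks=pd.concat(mark_rows, ignore_index=True),
        expression=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "base_mean": expr_base,
                "k27_target": k27_target,
                "parental_log2fc": expr_plfc,
                "nonadditive_log2fc_P1xP2": expr_hlfc["P1xP2"],
                "nonadditive_log2fc_P2xP1": expr_hlfc["P2xP1"],
                "mu_P1": mu_e1,
                "mu_P2": mu_e2,
                "mu_P1xP2": mu[("RNA", "P1xP2")],
                "mu_P2xP1": mu[("RNA", "P2xP1")],
            }
        ),
    )

    # draw counts per assay
    counts: dict[str, CountMatrix] = {}
    alpha = {m: effects.dispersion["chip"] for m in MARKS}
    alpha["RNA"] = effects.dispersion["rna"]
    for assay in MARKS + ("RNA",):
        if assay == "RNA":
            feats = gene_ids
            sel = np.ones(n, bool)
        else:
            sel = marked[assay]
            feats = [g for g, s in zip(gene_ids, sel) if s]
        cols = {}
        samples = design[design["assay"] == assay]
        for sid, row in samples.iterrows():
            mu_s = mu[(assay, row["genotype"])][sel] * depth_factor[sid]
            cols[sid] = nb_sample(rng, mu_s, alpha[assay])
        counts[assay] = CountMatrix(
            counts=pd.DataFrame(cols, index=pd.Index(feats, name="gene_id")),
            samples=design.loc[list(cols)].assign(
                depth_factor=depth_factor[list(cols)]
            ),
        )

    allelic = _draw_allelic(rng, effects, counts, truth, snps_per_gene, gene_ids)
    coverage = CoverageSet(genome, effects, mu, marked, depth_factor, int(seed))
    return SimulatedData(
        genome=genome,
        counts=counts,
        allelic=allelic,
        coverage=coverage,
        truth=truth,
        design=design,
    )


def _draw_allelic(rng, effects, counts, truth, snps_per_gene, gene_ids):
    """Split hybrid ChIP counts into parental alleles.

    Each read carries an informative SNP with probability
    min(0.9, snp_capture_rate * n_snps); assigned reads split binomially
    with P1 probability = mu_P1/(mu_P1+mu_P2), odds scaled by 2**bias at
    allele-biased genes.
    """
    snp_lookup = dict(zip(gene_ids, snps_per_gene))
    rows = []
    for mark in MARKS:
        cm = counts[mark]
        tm = truth.marks[truth.marks["mark"] == mark].set_index("gene_id")
        hyb_samples = cm.samples[cm.samples["genotype"].isin(HYBRIDS)]
        feats = cm.feature_ids
        mu1 = tm.loc[feats, "mu_P1"].to_numpy()
        mu2 = tm.loc[feats, "mu_P2"].to_numpy()
        bias = tm.loc[feats, "allele_bias_log2"].to_numpy()
        p1 = mu1 / (mu1 + mu2)
        odds = p1 / (1 - p1) * 2.0 ** bias
        p1b = odds / (1 + odds)
        nsnp = np.array([snp_lookup[g] for g in feats])
        q = np.minimum(0.9, effects.snp_capture_rate * nsnp)
        for sid in hyb_samples.index:
            total = cm.counts[sid].to_numpy()
            assigned = rng.binomial(total, q)
            c1 = rng.binomial(assigned, p1b)
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": feats,
                        "sample_id": sid,
                        "mark": mark,
                        "count_P1": c1,
                        "count_P2": assigned - c1,
                        "n_informative_snps": nsnp,
                        "unassigned_count": total - assigned,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# coverage tracks
# --------------------------------------------------------------------------

BACKGROUND_RATE = 0.01  # reads per bp outside enriched features


class CoverageSet:
    """Lazily generated per-base coverage tracks, one per (sample, assay).

    Tracks are Poisson realisations of mark-specific spatial templates whose
    per-gene total reads equal the same group means that drive the count
    matrices. Generation is deterministic in (seed, sample, assay).
    """

    def __init__(self, genome, effects, mu, marked, depth_factor, seed):
        self._genome = genome
        self._effects = effects
        self._mu = mu
        self._marked = marked
        self._depth = depth_factor
        self._seed = seed
        self._order = {s: i for i, s in enumerate(sorted(depth_factor.index))}

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self._genome.chrom_sizes

    def expected(self, genotype: str, assay: str, factor: float = 1.0):
        """Noise-free expected per-base track for a sample group."""
        sizes = self.chrom_sizes
        exp = {c: np.full(sz, BACKGROUND_RATE * factor) for c, sz in sizes.items()}
        if assay == "input":
            return exp
        gene_ids = [g.gene_id for g in self._genome.genes]
        levels = dict(zip(gene_ids, self._mu[(assay, genotype)]))
        marked = dict(zip(gene_ids, self._marked[assay]))
        for g in self._genome.genes:
            if not marked[g.gene_id]:
                continue
            total = levels[g.gene_id] * factor
            _add_template(exp[g.chrom], g, assay, total)
        if assay == "K9me2":
            depth = self._effects.depth * factor
            # per-bp K9me2 density: long TEs ~4x the short-TE density
            for te in self._genome.tes:
                density = depth / LONG_TE_BP if te.length >= LONG_TE_BP else 0.25 * depth / LONG_TE_BP
                _add_template(exp[te.chrom], te, "K9me2", density * te.length)
            for ci in range(self._genome.model.n_chromosomes):
                lo, hi = self._genome.model.pericentromere(ci)
                exp[f"chr{ci + 1}"][lo:hi] += 2 * BACKGROUND_RATE * factor
        return exp

    def track(self, sample_id: str, assay: str | None = None):
        """Realised integer coverage for one sample."""
        if assay is None:
            genotype, assay, _rep = sample_id.rsplit("_", 2)
        else:
            genotype = sample_id.rsplit("_", 2)[0]
        rng = np.random.default_rng(
            [self._seed, 101, self._order[sample_id], ASSAYS.index(assay)]
        )
        exp = self.expected(genotype, assay, factor=float(self._depth[sample_id]))
        return {c: rng.poisson(e).astype(np.int32) for c, e in exp.items()}


def simulate_allelic_reads(
    genome: Genome,
    truth: SyntheticTruth,
    mark: str,
    genotype: str,
    seed: int,
    read_length: int = 75,
):
    """Read-level hybrid data for SNP-based allele partitioning.

    For each marked gene, Poisson(mu) reads are placed uniformly within the
    gene; each read's allele of origin is Bernoulli with P1 probability
    mu_P1/(mu_P1+mu_P2) (odds scaled by the injected bias where flagged), and
    the read reports that allele's base at every SNP it covers. Returns a
    list of :class:`hybridhist.allelic.ReadObs`.
    """
    from .allelic import ReadObs

    if genotype not in HYBRIDS:
        raise ValueError(f"allelic reads are defined for hybrids, got {genotype!r}")
    rng = np.random.default_rng([int(seed), 57, HYBRIDS.index(genotype), MARKS.index(mark)])
    tm = truth.marks[truth.marks["mark"] == mark].set_index("gene_id")
    genes = {g.gene_id: g for g in genome.genes}
    snps_by_gene = {
        gid: sub.sort_values("pos") for gid, sub in genome.snps.groupby("gene_id")
    }
    reads: list[ReadObs] = []
    for gene_id, row in tm.iterrows():
        g = genes[gene_id]
        mu1, mu2 = row["mu_P1"], row["mu_P2"]
        odds = (mu1 / mu2) * 2.0 ** row["allele_bias_log2"]
        p1 = odds / (1 + odds)
        n_reads = rng.poisson(row[f"mu_{genotype}"])
        if n_reads == 0:
            continue
        starts = rng.integers(g.interval.start, max(g.interval.end - read_length, g.interval.start) + 1, n_reads)
        from_p1 = rng.random(n_reads) < p1
        snp = snps_by_gene.get(gene_id)
        for s, isp1 in zip(starts, from_p1):
            e = s + read_length
            bases = {}
            if snp is not None:
                cov = snp[(snp["pos"] >= s) & (snp["pos"] < e)]
                col = "allele_P1" if isp1 else "allele_P2"
                bases = dict(zip(cov["pos"].astype(int), cov[col]))
            reads.append(ReadObs(g.chrom, int(s), int(e), bases))
    return reads


def _add_template(track: np.ndarray, feat: GeneAnnotation, assay: str, total: float):
    """Distribute ``total`` expected reads over the feature's template shape."""
    s, e = feat.interval.start, feat.interval.end
    L = e - s
    if assay in ACTIVE_MARKS:
        # bump just 3' of the TSS: gamma-shaped in distance from TSS
        d = np.arange(L, dtype=float)
        scale = 0.10 * L + 50.0
        w = (d + 30.0) * np.exp(-d / scale)
        w /= w.sum()
        if feat.strand == "-":
            w = w[::-1]
        track[s:e] += total * w
    else:
        track[s:e] += total / L
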