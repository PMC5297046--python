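# Methods

This note records the statistical models, the synthetic-data design, the
numerical choices, and the known limitations of `hybridhist`.

## Count model and differential testing

All ChIP and RNA counts are modelled as negative binomial with
Var = &mu; + &alpha;&mu;² (gamma–Poisson). Per-sample sequencing depth is
normalized with median-of-ratios size factors: factor_j = median over
features of count_ij / geometric-mean_i, over features nonzero in every
sample, then rescaled to geometric mean exactly 1. The exact-1 rescaling is
deliberate: it pins the common scale of the normalized counts, so a change
of one library's depth moves only that library's factor. No ratio-based
estimator can make downstream count tests *exactly* invariant to rescaling
one sample — the geometric-mean reference itself shifts by c^(1/n) — so the
invariance contract is: given factors that absorb the scaling, results are
bit-identical (tested), and the estimator recovers the injected factor
ratio (tested).

Dispersion is estimated per feature by pooled method-of-moments across
replicate groups, &alpha;&#770; = (s² − &mu;)/&mu;² weighted by group df,
clipped at 0, then floored by a fitted mean-trend a₀ + a₁/&mu;
(nonnegative least squares on the per-feature estimates, trimmed at the
95th percentile). The final value max(&alpha;&#770;, trend) is
deliberately conservative: with two replicates per group the per-feature
estimate alone has ~2 df and would otherwise produce anti-conservative
tests.

The two-group test is an exact conditional NB test on normalized group
sums rounded to integers. Conditioning on the total k_A + k_B with a
common per-replicate mean q₀ = (k_A + k_B)/(n_A + n_B), the group sums are
NB with means n·q₀ and dispersions &alpha;/n; the two-sided p-value sums
the probabilities of all splits no more likely than the observed one.
Mid-parent values enter as pseudo-replicates (normalized P1 rep r +
normalized P2 rep r)/2, paired by sorted replicate index, carrying unit
size factors. Pseudo-replicates have roughly half the biological variance
of a real sample; using the pooled dispersion for them is conservative
for the hybrid-vs-MPV contrast (its measured null DMG rate is ~0.01 at
nominal 0.05).

Thresholds: parental DMGs at fold-change ≥ 1.5 and raw p ≤ 0.05; hybrid
non-additivity at fold-change ≥ 1.25 and raw p ≤ 0.05; expression
significance at fold-change ≥ 1.3 and p ≤ 0.01. Fold-changes use a
pseudo-count of 0.5 on normalized group means. No multiple-testing
correction is applied by default — calls filter on the raw p-value —
with Benjamini–Hochberg available behind a flag. A consequence worth
stating: at raw p ≤ 0.05, an observed FDR below 0.2 requires the true
effect prevalence to exceed roughly 12%; recovery experiments therefore
use the repressive marks, whose default injected prevalences (14% and 20%
parental, 16.5% non-additive for H3K27me3 in P1xP2) support that regime.
For the active marks at 6% prevalence, raw-p calling cannot keep FDR
under 0.2 no matter how the test is tuned; users who need FDR control
should switch on the BH option.

## Peak caller

The genome is tiled into fixed windows (200 bp narrow / 1000 bp broad).
Each window's treatment count is tested against Poisson(&lambda;) with
&lambda; = depth-scale × max(genome-wide control rate, 10-kb-flank control
rate). The depth scale is a trimmed ratio — treatment windows above the
99th percentile are excluded from both sums — because a total-count ratio
is inflated by the enrichment itself and measurably costs sensitivity.
Significant windows (p ≤ 10⁻⁶ narrow, ≤ 10⁻² broad) are stitched:
touching windows in narrow mode, windows within the 1 kb broad gap in
broad mode; peaks shorter than 150 bp are dropped. Window p-values are
left uncorrected by design: the thresholds are interpreted as raw caller
thresholds. There is no fragment-shift model and no summit calling.

## Gene assignment

Window rules (K4me3/K9ac: 1.5 kb upstream of the TSS; K9me2: 1 kb up- and
downstream) are strand-aware — for a '−' gene the TSS is the higher
coordinate and "upstream" extends to higher coordinates — with ≥ 1 bp
overlap counting, and windows clipped at the chromosome start. The
literal upstream-window rule means a peak sitting only on the gene body
does not target the gene; a config flag (`include_gene_body`) widens the
window to include the body, off by default. H3K27me3 uses the reciprocal
rule: a peak targets a gene iff ≥ 50% of the peak and ≥ 50% of the gene
body overlap mutually. Gene counts aggregate all qualifying peaks; a peak
shared by k genes contributes fully to each (documented double-count —
exclusive assignment would silently drop shared regulatory signal).

A real interaction worth knowing: broad domains of *adjacent* H3K27me3
target genes merge across the broad gap, and the merged domain then fails
the peak-fraction half of the reciprocal rule for both genes. On the
densely packed toy genome this drops a noticeable fraction of K27me3
targets from the peak-level testing route; the pipeline therefore supports
both testing orders (`test_level: peaks`, the default, tests unified peak
counts and maps significant peaks to genes; `test_level: genes` tests
gene-aggregated counts directly).

## Allele-specific analysis

A hybrid read overlapping ≥ 1 informative SNP is assigned to the allele
all its informative bases agree on; reads with conflicting votes or bases
matching neither allele are counted as unassigned rather than
majority-voted. Genes qualify with ≥ 2 informative SNPs and ≥ 10 assigned
reads in every hybrid sample — declared conventions, surfaced in config,
for a criterion the source material leaves unstated. The allelic ratio is
tested by exact binomial against the expected P1 fraction
P1/(P1 + P2) from normalized parental levels (replicates pooled);
expectations of exactly 0 or 1 are flagged untestable. Each allele's level
is separately compared to half the matching parent's level — matched by
accession, not by cross direction — scaled by the gene's SNP-assignable
read fraction, using the exact NB test at the hybrid thresholds.

## Synthetic data

The generator emulates the study design: genotypes P1, P2, P1xP2, P2xP1 ×
2 replicates × (4 marks + input + RNA). Defaults define the study
conditions:

* Genome: 2 chromosomes × 600 kb; 300 genes (log-uniform 0.6–4 kb) on the
  arms; 120 TEs (40% long ≥ 1.5 kb, up to 5 kb) of which 70% sit in the
  central 25% pericentromere; SNPs at 5/kb within genes, so genes under
  2 SNPs exist by construction and exercise the sufficiency filter.
* Marks: all genes carry the active marks, attenuated ×0.2 (not zeroed) on
  the 20% H3K27me3-target genes and the 8% K9me2-marked genes; K27me3
  covers target gene bodies; K9me2 covers TEs (long TEs at 4× the per-bp
  density of short ones) and the pericentromere.
* Effects: parental DMGs at 6% (active marks), 14% (K27me3), 20% (K9me2)
  of marked genes with |log2FC| ~ U(1, 2.5) split symmetrically across the
  parents; hybrid non-additivity per cross with the K27me3 asymmetry
  (16.5% in P1xP2 vs 5% in P2xP1) and mostly-above-MPV directions except
  K9me2; |log2FC| ~ U(1, 2); allelic bias at 10% with |log2 odds| ~ U(1, 2).
* Depth 60 reads/marked feature/sample for ChIP with NB dispersion 0.05;
  RNA at 4× that depth (RNA-seq gene counts run several-fold deeper than
  ChIP peak counts; at equal depth the expression arm of coupled effects
  would sit below the p ≤ 0.01 detection floor of a 2-replicate design,
  i.e. the simulated study could not support its own concordance
  analysis). Per-sample library-size factors ~ U(0.85, 1.2) exercise
  normalization.
* Expression: a shared per-gene activity drives both active marks and
  expression (positive correlation); on K27me3 targets expression
  decreases with the K27me3 level. Mark effects propagate to expression
  with probability 0.7 at full log2 magnitude, signed by the mark's role
  (+ for active marks, − for repressive); 5% of genes get independent
  expression effects.
* FLC-style archetype (`ensure_flc_like`, on by default): the strongest
  K27me3 target deterministically loses K27me3 relative to MPV (log2
  −1.2) in both crosses with coupled expression gain and a well-expressed
  baseline, so the flagship below-MPV-mark / expression-up concordance
  pattern exists on every seed rather than with ~50% probability.
* Coverage tracks are Poisson realisations of per-bp templates whose
  per-gene totals equal the count-matrix means: active marks follow a
  gamma-shaped bump peaking ~10% into the gene body 3′ of the TSS;
  K27me3/K9me2 are uniform over the feature. Tracks and count matrices
  are *independent* realisations of the same means; counts derived from
  coverage (the peak route) agree in expectation, not per-draw.

What the generator does **not** emulate: read-level sequencing (no FASTQ,
no error model), mappability and GC biases, fragment-length effects,
duplicate reads (assumed removed upstream), chromatin-state
autocorrelation along the genome beyond the per-gene templates, and any
genome-wide trans effects in hybrids. Passing recovery tests therefore
demonstrates the statistical machinery under the stated noise model, not
robustness to real-data artefacts.

## Problem sizes used in validation

Oracle checks run on 500 randomized interval/assignment fixtures, all NB
count splits with totals ≤ 60, and all 2×2 tables with row margins ≤ 30
(≤ 20 in the faster script variant). Null calibration uses ~10⁴ null
features for the hybrid-vs-MPV contrast and 10⁵ null windows for the
caller. Recovery uses a 6,000-gene genome; qualitative patterns use the
default 300-gene genome. These sizes keep the whole validation within a
few CPU-minutes while holding binomial standard errors on the measured
rates to a few per mille.

## Numerical choices and degenerate inputs

Ties in the exact tests include splits within a 1 + 10⁻⁸ relative factor
of the observed probability, protecting two-sided tail sums from float
round-off. Totals of zero give p = 1. Empty control tracks, mixed-mark
peak unification, non-disjoint count regions, all-singleton replicate
groups, and features exceeding chromosome capacity raise errors naming
the offending input; flank windows past the chromosome start are clipped
(logged, not an error); metagene bins fully off-chromosome are averaged
out as missing. Heat-map ordering breaks ties by gene id for bit-exact
reproducibility; all generator randomness derives from
`numpy.random.default_rng` seeded by (user seed, stage constant), so
identical seeds give byte-identical outputs.

## Known limitations

* The caller's window grid quantizes peak boundaries (±1 window), which
  interacts with the reciprocal 50% rule for short genes (see above).
* The exact test on rounded normalized sums discards within-group
  variance information beyond the dispersion estimate; with 2 replicates
  this is close to the information limit anyway.
* Allelic counts are compared against *estimated* parental ratios; noise
  in the parental estimate slightly deflates power near the decision
  boundary (recovery checks use the true ratios to isolate the test).
* The reciprocal-hybrid Fisher comparison treats genes as independent,
  as does the source methodology.
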