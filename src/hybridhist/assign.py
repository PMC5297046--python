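"""Mark-specific assignment of enrichment regions to genes.

Active promoter marks use a TSS-anchored window rule: a gene is targeted by
H3K4me3/H3K9ac when a peak overlaps the 1.5 kb window upstream of its TSS,
and by H3K9me2 when a peak overlaps the 1 kb windows upstream *or*
downstream of the TSS. H3K27me3, a gene-body mark, uses a reciprocal-overlap
rule instead: a peak targets a gene only when at least 50% of the peak and
at least 50% of the gene body overlap each other.

"Upstream" is strand-aware: for '-'-strand genes the TSS is the higher
coordinate and upstream extends to still higher coordinates. Windows that
would extend past the chromosome start are clipped at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import CountMatrix, GeneAnnotation, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class AssignmentRule:
    """Spatial rule mapping peaks of one mark to genes.

    Exactly one of the window rule (``upstream_window``/``downstream_window``)
    and the reciprocal rule (``reciprocal_overlap_frac``) is active.
    ``include_gene_body`` optionally extends the window rule to also accept
    peaks overlapping the gene body itself (off by default: the literal
    upstream-window rule is applied).
    """

    mark: str
    upstream_window: int = 0
    downstream_window: int = 0
    reciprocal_overlap_frac: float | None = None
    include_gene_body: bool = False

    def __post_init__(self):
        window_active = self.upstream_window > 0 or self.downstream_window > 0
        reciprocal_active = self.reciprocal_overlap_frac is not None
        if window_active == reciprocal_active:
            raise ValueError(
                "exactly one of the window rule and the reciprocal rule must be active"
            )
        if reciprocal_active and not 0 < self.reciprocal_overlap_frac <= 1:
            raise ValueError("reciprocal_overlap_frac must lie in (0, 1]")

    @classmethod
    def default_for(cls, mark: str) -> "AssignmentRule":
        if mark in ("K4me3", "K9ac"):
            return cls(mark=mark, upstream_window=1500)
        if mark == "K9me2":
            return cls(mark=mark, upstream_window=1000, downstream_window=1000)
        if mark == "K27me3":
            return cls(mark=mark, reciprocal_overlap_frac=0.5)
        raise ValueError(f"no default assignment rule for mark {mark!r}")


def _tss_window(gene: GeneAnnotation, rule: AssignmentRule) -> GenomicInterval | None:
    """Strand-aware window around the TSS, clipped to the chromosome start."""
    up, down = rule.upstream_window, rule.downstream_window
    if gene.strand == "-":
        # TSS at end-1; upstream extends to higher coordinates
        start = gene.tss + 1 - down
        end = gene.tss + 1 + up
    else:
        start = gene.tss - up
        end = gene.tss + down
    if start < 0:
        logger.debug("window for %s clipped at chromosome start", gene.gene_id)
        start = 0
    if rule.include_gene_body:
        start = min(start, gene.interval.start)
        end = max(end, gene.interval.end)
    if end <= start:  # window fully off the chromosome start
        return None
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def assign(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneAnnotation],
    rule: AssignmentRule,
) -> pd.DataFrame:
    """Map peaks to target genes under the rule.

    Returns a tidy frame with one row per qualifying (gene, peak) pair:
    columns gene_id, peak_index, peak_id. A peak may target several genes
    and a gene may collect several peaks.
    """
    rows = []
    for gene in genes:
        if rule.reciprocal_overlap_frac is not None:
            frac = rule.reciprocal_overlap_frac
            for pi, peak in enumerate(peaks):
                ov = peak.overlap_length(gene.interval)
                if ov >= frac * len(peak) and ov >= frac * gene.length:
                    rows.append((gene.gene_id, pi, peak.name))
        else:
            window = _tss_window(gene, rule)
            if window is None:
                continue
            for pi, peak in enumerate(peaks):
                if window.overlaps(peak):
                    rows.append((gene.gene_id, pi, peak.name))
    return pd.DataFrame(rows, columns=["gene_id", "peak_index", "peak_id"])


def gene_counts(mapping: pd.DataFrame, peak_counts: CountMatrix) -> CountMatrix:
    """Aggregate peak counts to gene level.

    A gene's count per sample is the sum over its qualifying peaks; a peak
    shared by k genes contributes its full count to each of them (a
    deliberate, documented double-count — exclusive assignment would drop
    signal from shared regulatory regions).
    """
    if mapping.empty:
        empty = pd.DataFrame(
            columns=peak_counts.counts.columns, index=pd.Index([], name="gene_id"),
            dtype=np.int64,
        )
        return CountMatrix(counts=empty, samples=peak_counts.samples)
    mat = peak_counts.counts.to_numpy()
    gene_ids = sorted(mapping["gene_id"].unique())
    gidx = {g: i for i, g in enumerate(gene_ids)}
    out = np.zeros((len(gene_ids), mat.shape[1]), dtype=np.int64)
    for gene_id, pi in zip(mapping["gene_id"], mapping["peak_index"]):
        out[gidx[gene_id]] += mat[pi]
    return CountMatrix(
        counts=pd.DataFrame(
            out, index=pd.Index(gene_ids, name="gene_id"), columns=peak_counts.counts.columns
        ),
        samples=peak_counts.samples,
    )
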