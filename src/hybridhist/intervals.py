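"""Genomic interval types and interval algebra.

All coordinates are 0-based half-open ([start, end)), the BED convention.
GFF3's 1-based closed coordinates are converted at the I/O boundary
(:mod:`hybridhist.io`), never inside the algebra.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.name or ''} "
                f"{self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene or transposable-element annotation.

    The transcription start site (TSS) is the 5' end in the strand's
    orientation: ``start`` for '+' features and ``end - 1`` for '-' features;
    the termination site (TTS) is the 3' end, symmetrically.
    """

    interval: GenomicInterval
    gene_id: str
    feature_class: str = "protein_coding"  # protein_coding | TE | TE_gene

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand != "-" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand != "-" else self.interval.start

    @property
    def length(self) -> int:
        return len(self.interval)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals into disjoint unions.

    Output is sorted by (chrom, start); touching intervals (end == next
    start) are merged, matching ``bedtools merge`` defaults. Strand is
    ignored; merged intervals are reported unstranded.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def intersect_count(
    regions: Sequence[GenomicInterval],
    reads: Sequence[GenomicInterval],
) -> np.ndarray:
    """Count reads overlapping each region by >= 1 bp.

    ``regions`` must be pairwise disjoint. Reads on chromosomes absent from
    the regions simply contribute nothing. Counting is additive over a
    partition of a region because each read overlaps exactly one part of a
    disjoint partition at its leftmost overlapping base -- here a read
    overlapping several disjoint regions is counted once per region, which
    is the ``bedtools intersect -c`` semantic.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, idx))
    for chrom, regs in by_chrom.items():
        regs.sort()
        starts = np.array([r[0] for r in regs])
        ends = np.array([r[1] for r in regs])
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"regions on {chrom} are not disjoint")
    ends_by_chrom = {c: [r[1] for r in regs] for c, regs in by_chrom.items()}
    for read in reads:
        regs = by_chrom.get(read.chrom)
        if regs is None:
            continue
        # first region whose end > read.start, then scan while region.start < read.end
        i = bisect.bisect_right(ends_by_chrom[read.chrom], read.start)
        while i < len(regs) and regs[i][0] < read.end:
            counts[regs[i][2]] += 1
            i += 1
    return counts


def coverage_sum(
    regions: Sequence[GenomicInterval],
    coverage: dict[str, np.ndarray],
) -> np.ndarray:
    """Sum a per-base coverage track over each region.

    Regions beyond a track's end are clipped; regions on chromosomes
    missing from ``coverage`` get 0.
    """
    out = np.zeros(len(regions), dtype=float)
    for i, r in enumerate(regions):
        track = coverage.get(r.chrom)
        if track is None:
            continue
        out[i] = float(track[r.start : min(r.end, len(track))].sum())
    return out


@dataclass
class CountMatrix:
    """Integer counts for features x samples plus sample metadata.

    ``counts`` is a DataFrame indexed by feature id with one column per
    sample; ``samples`` is indexed by sample id with at least columns
    ``genotype`` (P1, P2, P1xP2, P2xP1), ``replicate`` and ``assay``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    def group_columns(self, genotype: str) -> list[str]:
        sel = self.samples.index[self.samples["genotype"] == genotype]
        return sorted(sel, key=lambda s: self.samples.loc[s, "replicate"])

    def subset_features(self, ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[ids], self.samples.copy())
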