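"""Windowed-Poisson enrichment-region calling and cross-sample unification.

A simplified narrow/broad caller in the MACS2 mould: the genome is tiled
into fixed windows; each window's treatment count is tested against a
Poisson rate estimated from a depth-scaled input/background track, using a
local lambda of max(genome-wide control rate, 10 kb flank control rate).
Significant windows are stitched into peaks — touching windows in narrow
mode, windows within ``broad_gap`` in broad mode — and short peaks dropped.
Window-level p-values are deliberately left uncorrected; significance is
filtered on the raw threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import CountMatrix, GenomicInterval, coverage_sum, merge_intervals

logger = logging.getLogger(__name__)

LOCAL_LAMBDA_FLANK = 10_000  # bp of flanking control used for the local rate

_DEFAULTS = {
    "K4me3": dict(mode="narrow", p_threshold=1e-6, window=200),
    "K9ac": dict(mode="narrow", p_threshold=1e-6, window=200),
    "K27me3": dict(mode="broad", p_threshold=1e-2, window=1000),
    "K9me2": dict(mode="broad", p_threshold=1e-2, window=1000),
}


@dataclass
class PeakCallConfig:
    """Per-mark calling parameters.

    Active marks (H3K4me3, H3K9ac) default to narrow mode at p <= 1e-6;
    the broad marks (H3K27me3, H3K9me2) to broad mode at p <= 1e-2 with
    gap-merging, mirroring how such marks form wide continuous domains.
    """

    mark: str
    mode: str = ""
    p_threshold: float = 0.0
    window: int = 0
    broad_gap: int = 1000
    min_peak_len: int = 150

    def __post_init__(self):
        if self.mark not in _DEFAULTS:
            raise ValueError(f"unknown mark {self.mark!r}")
        d = _DEFAULTS[self.mark]
        if not self.mode:
            self.mode = d["mode"]
        if not self.p_threshold:
            self.p_threshold = d["p_threshold"]
        if not self.window:
            self.window = d["window"]
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.window <= 0 or self.min_peak_len < 0 or self.broad_gap < 0:
            raise ValueError("window/broad_gap/min_peak_len must be positive")
        if self.mode not in ("narrow", "broad"):
            raise ValueError(f"mode must be narrow or broad, got {self.mode!r}")


@dataclass
class PeakSet:
    mark: str
    sample_id: str
    intervals: list[GenomicInterval]
    scores: np.ndarray  # fold enrichment over local lambda
    pvalues: np.ndarray  # best window p-value within the peak


def _window_sums(track: np.ndarray, window: int) -> np.ndarray:
    n_win = int(np.ceil(len(track) / window))
    padded = np.zeros(n_win * window, dtype=float)
    padded[: len(track)] = track
    return padded.reshape(n_win, window).sum(axis=1)


def window_pvalues(
    treatment: np.ndarray, control: np.ndarray, window: int, flank: int = LOCAL_LAMBDA_FLANK
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window Poisson upper-tail p-values for one chromosome.

    Returns (pvalues, treatment window counts, lambda per window). The
    control is scaled to the treatment depth; lambda per window is
    max(genome-wide control rate, local flank rate), both depth-scaled.
    """
    c_sum = float(control.sum())
    if c_sum <= 0:
        raise ValueError("control track is empty")
    tw = _window_sums(treatment, window)
    cw = _window_sums(control, window)
    # depth ratio from the bulk of windows: trimming the top 1% of treatment
    # windows keeps enriched regions from inflating the background estimate
    bulk = tw <= np.quantile(tw, 0.99)
    t_bulk, c_bulk = float(tw[bulk].sum()), float(cw[bulk].sum())
    scale = t_bulk / c_bulk if t_bulk > 0 and c_bulk > 0 else 1.0
    genome_rate = c_sum / len(control) * window
    half = max(1, flank // (2 * window))
    kernel = np.ones(2 * half + 1)
    local = np.convolve(cw, kernel, mode="same")
    n_contrib = np.convolve(np.ones_like(cw), kernel, mode="same")
    local_rate = local / n_contrib
    lam = scale * np.maximum(genome_rate, local_rate)
    pvals = stats.poisson.sf(tw - 1, lam)  # P(X >= observed)
    return pvals, tw, lam


def call_peaks(
    treatment: dict[str, np.ndarray],
    control: dict[str, np.ndarray],
    config: PeakCallConfig,
    sample_id: str = "",
) -> PeakSet:
    """Call enrichment regions of one sample against its input track."""
    if set(treatment) != set(control):
        raise ValueError(
            f"genome mismatch: treatment has {sorted(treatment)}, control {sorted(control)}"
        )
    if sum(float(np.sum(c)) for c in control.values()) <= 0:
        raise ValueError("control track is empty")
    intervals, scores, pvalues = [], [], []
    gap_windows = config.broad_gap // config.window if config.mode == "broad" else 0
    for chrom in sorted(treatment):
        t, c = np.asarray(treatment[chrom], float), np.asarray(control[chrom], float)
        if len(t) != len(c):
            raise ValueError(f"genome mismatch on {chrom}: track lengths differ")
        pvals, tw, lam = window_pvalues(t, c, config.window)
        sig = np.flatnonzero(pvals <= config.p_threshold)
        if sig.size == 0:
            continue
        # stitch windows: touching (narrow) or within broad_gap (broad)
        breaks = np.flatnonzero(np.diff(sig) > gap_windows + 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [sig.size - 1]])
        for si, ei in zip(starts, ends):
            lo = int(sig[si]) * config.window
            hi = min((int(sig[ei]) + 1) * config.window, len(t))
            if hi - lo < config.min_peak_len:
                continue
            block = slice(sig[si], sig[ei] + 1)
            intervals.append(GenomicInterval(chrom, lo, hi))
            scores.append(float(np.max(tw[block] / np.maximum(lam[block], 1e-12))))
            pvalues.append(float(np.min(pvals[block])))
    return PeakSet(
        mark=config.mark,
        sample_id=sample_id,
        intervals=intervals,
        scores=np.asarray(scores),
        pvalues=np.asarray(pvalues),
    )


def unify_peaks(peaksets: list[PeakSet]) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """Merge peak coordinates across samples of the same mark.

    Returns the merged regions (named ``<mark>_peak_<i>``) and a table of
    contributing samples per region.
    """
    marks = {ps.mark for ps in peaksets}
    if len(marks) > 1:
        raise ValueError(f"cannot unify peaks of mixed marks: {sorted(marks)}")
    mark = marks.pop() if marks else ""
    merged = merge_intervals(iv for ps in peaksets for iv in ps.intervals)
    merged = [
        GenomicInterval(r.chrom, r.start, r.end, ".", f"{mark}_peak_{i + 1}")
        for i, r in enumerate(merged)
    ]
    rows = []
    for i, region in enumerate(merged):
        contrib = sorted(
            ps.sample_id
            for ps in peaksets
            if any(region.overlaps(iv) for iv in ps.intervals)
        )
        rows.append((region.name, region.chrom, region.start, region.end, ",".join(contrib)))
    table = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end", "samples"])
    return merged, table


def count_matrix(
    regions: list[GenomicInterval],
    coverages: dict[str, dict[str, np.ndarray]],
    samples: pd.DataFrame,
) -> CountMatrix:
    """Sum each sample's coverage over the unified regions."""
    missing = [s for s in samples.index if s not in coverages]
    if missing:
        raise ValueError(f"samples missing coverage: {missing}")
    names = [r.name or f"region_{i + 1}" for i, r in enumerate(regions)]
    cols = {}
    for sid in samples.index:
        cols[sid] = np.rint(coverage_sum(regions, coverages[sid])).astype(np.int64)
        logger.info("counted %d reads in %d regions for %s", cols[sid].sum(), len(regions), sid)
    return CountMatrix(
        counts=pd.DataFrame(cols, index=pd.Index(names, name="peak_id")),
        samples=samples,
    )
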