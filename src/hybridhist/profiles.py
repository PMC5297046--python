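"""Descriptive summaries: metagene profiles, ordered heat-map matrices, and
mark-expression correlation/concordance.

Metagene profiles average coverage over a length-normalized gene body
(fixed bin count) plus fixed-width +/-3 kb flanks, with '-'-strand features
reversed so every profile runs 5'->3'. Concordance asks whether histone-mark
changes and expression changes move together with the mark's expected sign:
positive for the active marks (H3K4me3, H3K9ac), negative for the repressive
ones (H3K27me3, H3K9me2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneAnnotation
from .simulate import MARK_SIGN

logger = logging.getLogger(__name__)

FLANK_BP = 3000
BODY_BINS = 100
FLANK_BIN_BP = 50

EXPR_FC = 1.3
EXPR_P = 0.01


@dataclass
class MetageneProfile:
    mark: str
    sample: str
    upstream: np.ndarray  # mean signal per flank bin, 5' flank
    body: np.ndarray  # mean signal per scaled gene-body bin
    downstream: np.ndarray
    n_features: int

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def _body_bins(vals: np.ndarray, n_bins: int) -> np.ndarray:
    """Rescale a per-base body signal to n_bins by mean-within-bin.

    Features shorter than the bin count are linearly interpolated instead
    (both operations are linear in the input signal).
    """
    L = len(vals)
    if L >= n_bins:
        edges = np.linspace(0, L, n_bins + 1).astype(int)
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        widths = np.diff(edges)
        return (csum[edges[1:]] - csum[edges[:-1]]) / np.maximum(widths, 1)
    logger.debug("feature of %d bp shorter than %d bins; interpolating", L, n_bins)
    x = np.arange(L)
    grid = np.linspace(0, L - 1, n_bins)
    return np.interp(grid, x, vals)


def metagene(
    coverage: dict[str, np.ndarray],
    features: list[GeneAnnotation],
    flank: int = FLANK_BP,
    body_bins: int = BODY_BINS,
    flank_bin: int = FLANK_BIN_BP,
    mark: str = "",
    sample: str = "",
) -> MetageneProfile:
    """Average coverage over scaled feature bodies and fixed flanks.

    Flank regions extending past chromosome bounds contribute NaN and are
    averaged out per bin. The profile is oriented 5'->3' for every feature.
    """
    n_flank_bins = flank // flank_bin
    up_acc = np.zeros((len(features), n_flank_bins))
    body_acc = np.zeros((len(features), body_bins))
    down_acc = np.zeros((len(features), n_flank_bins))
    up_acc[:] = body_acc[:] = down_acc[:] = np.nan

    for fi, feat in enumerate(features):
        track = coverage.get(feat.chrom)
        if track is None:
            continue
        s, e = feat.interval.start, feat.interval.end
        body = track[s:e].astype(float)
        left = _flank_values(track, s - flank, s)
        right = _flank_values(track, e, e + flank)
        if feat.strand == "-":
            body = body[::-1]
            left, right = right[::-1], left[::-1]
        up_acc[fi] = _flank_bin_means(left, n_flank_bins)
        body_acc[fi] = _body_bins(body, body_bins)
        down_acc[fi] = _flank_bin_means(right, n_flank_bins)

    with warnings.catch_warnings():
        # bins fully off-chromosome in every feature are legitimately empty
        warnings.simplefilter("ignore", RuntimeWarning)
        return MetageneProfile(
            mark=mark,
            sample=sample,
            upstream=np.nanmean(up_acc, axis=0),
            body=np.nanmean(body_acc, axis=0),
            downstream=np.nanmean(down_acc, axis=0),
            n_features=len(features),
        )


def _flank_values(track: np.ndarray, start: int, end: int) -> np.ndarray:
    out = np.full(end - start, np.nan)
    lo, hi = max(start, 0), min(end, len(track))
    if hi > lo:
        out[lo - start : hi - start] = track[lo:hi]
    return out


def _flank_bin_means(vals: np.ndarray, n_bins: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(vals.reshape(n_bins, -1), axis=1)


def stratify_te_lengths(
    tes: list[GeneAnnotation], cutoff: int = 1500
) -> tuple[list[GeneAnnotation], list[GeneAnnotation]]:
    """Split TEs at the length cutoff into (long >= cutoff, short < cutoff)."""
    long = [t for t in tes if t.length >= cutoff]
    short = [t for t in tes if t.length < cutoff]
    return long, short


def heatmap_matrix(signals: pd.DataFrame, order_by: str) -> pd.DataFrame:
    """Genes x marks matrix with rows sorted by decreasing ``order_by`` level.

    Ties are broken by gene id so the ordering is deterministic.
    """
    if order_by not in signals.columns:
        raise ValueError(f"no column {order_by!r} to order by")
    key = signals[order_by]
    order = sorted(signals.index, key=lambda g: (-key[g], g))
    return signals.loc[order]


def expression_correlation(
    mark_levels: pd.Series, expression: pd.Series, n_quantiles: int = 10
) -> dict:
    """Monotone association between gene-level mark signal and expression.

    Returns the Spearman correlation across the shared gene universe plus
    the mean mark level per expression quantile. Constant expression makes
    the correlation undefined; it is reported as NaN.
    """
    shared = mark_levels.index.intersection(expression.index)
    x, y = expression[shared], mark_levels[shared]
    if x.nunique() <= 1 or y.nunique() <= 1:
        return {"spearman_rho": np.nan, "pvalue": np.nan, "quantile_means": None,
                "n_genes": len(shared)}
    rho, pval = stats.spearmanr(x, y)
    qlab = pd.qcut(x.rank(method="first"), n_quantiles, labels=False)
    qmeans = y.groupby(qlab).mean()
    return {
        "spearman_rho": float(rho),
        "pvalue": float(pval),
        "quantile_means": qmeans,
        "n_genes": len(shared),
    }


def concordance(
    parental_mark: pd.DataFrame,
    parental_expr: pd.DataFrame,
    hybrid_mark: pd.DataFrame,
    hybrid_expr: pd.DataFrame,
    mark: str,
    expr_fc: float = EXPR_FC,
    expr_p: float = EXPR_P,
) -> tuple[pd.DataFrame, dict]:
    """Cross mark and expression changes, parental and hybrid-vs-MPV.

    All four inputs are differential-result frames (log2fc, pval, is_dmg)
    on a shared gene universe. Expression changes are significant at
    fold-change >= ``expr_fc`` and p <= ``expr_p``. A gene is parentally
    concordant when it is a parental DMG and the parental expression change
    is significant with the mark's expected sign; hybrid-concordant when it
    is a hybrid-vs-MPV DMG and the hybrid expression deviation from MPV is
    significant with the matching sign.
    """
    sign = MARK_SIGN[mark]
    genes = parental_mark.index.intersection(parental_expr.index)
    genes = genes.intersection(hybrid_mark.index).intersection(hybrid_expr.index)

    def expr_sig(df):
        fc = 2.0 ** df["log2fc"].abs()
        return (fc >= expr_fc) & (df["pval"] <= expr_p)

    pm, pe = parental_mark.loc[genes], parental_expr.loc[genes]
    hm, he = hybrid_mark.loc[genes], hybrid_expr.loc[genes]

    parental_match = np.sign(pe["log2fc"]) == sign * np.sign(pm["log2fc"])
    parental_conc = pm["is_dmg"] & expr_sig(pe) & parental_match
    hybrid_match = np.sign(he["log2fc"]) == sign * np.sign(hm["log2fc"])
    hybrid_conc = hm["is_dmg"] & expr_sig(he) & hybrid_match

    table = pd.DataFrame(
        {
            "mark": mark,
            "parental_mark_log2fc": pm["log2fc"],
            "parental_expr_log2fc": pe["log2fc"],
            "hybrid_mark_log2fc": hm["log2fc"],
            "hybrid_expr_log2fc": he["log2fc"],
            "parental_mark_dmg": pm["is_dmg"],
            "hybrid_mark_dmg": hm["is_dmg"],
            "parental_concordant": parental_conc,
            "hybrid_concordant": hybrid_conc,
        },
        index=genes,
    )
    counts = {
        "mark": mark,
        "n_genes": int(len(genes)),
        "parental_concordant": int(parental_conc.sum()),
        "hybrid_concordant": int(hybrid_conc.sum()),
    }
    return table, counts


def gene_report(
    gene_id: str,
    mark_norm: pd.DataFrame,
    expr_norm: pd.DataFrame,
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-genotype mark and expression levels for one gene, plus the
    parental average (the additivity reference), in the style of a
    single-locus report."""
    rows = []
    for label, cols in groups.items():
        rows.append(
            (label,
             float(mark_norm.loc[gene_id, cols].mean()) if gene_id in mark_norm.index else np.nan,
             float(expr_norm.loc[gene_id, cols].mean()) if gene_id in expr_norm.index else np.nan)
        )
    mark_avg = np.mean([r[1] for r in rows if r[0] in ("P1", "P2")])
    expr_avg = np.mean([r[2] for r in rows if r[0] in ("P1", "P2")])
    rows.append(("parental_average", mark_avg, expr_avg))
    return pd.DataFrame(rows, columns=["group", "mark_level", "expression_level"])


def plot_metagene(profiles: list[MetageneProfile], path) -> None:
    """Render metagene curves to a file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for prof in profiles:
        n_up = len(prof.upstream)
        x = np.arange(len(prof.values))
        ax.plot(x, prof.values, label=f"{prof.mark} {prof.sample}".strip())
        ax.axvline(n_up, color="grey", lw=0.5)
        ax.axvline(n_up + len(prof.body), color="grey", lw=0.5)
    ax.set_xlabel("5' flank | scaled body (TSS->TTS) | 3' flank")
    ax.set_ylabel("mean coverage")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
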