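"""Negative-binomial differential testing of histone-modification counts.

The workflow mirrors the classic count-based differential pipeline:
median-of-ratios size factors, per-feature method-of-moments dispersion with
a conservative mean-trend floor, and an exact conditional NB test comparing
two groups of replicates. Two contrasts matter for the parent/hybrid design:

* parent vs parent, calling differentially modified genes (DMGs) at
  fold-change >= 1.5 and p <= 0.05;
* hybrid vs mid-parent value (MPV), calling non-additive genes at
  fold-change >= 1.25 and p <= 0.05, where the MPV is represented as
  pseudo-replicates (normalized P1 rep r + normalized P2 rep r) / 2.

P-values are raw by default (calls filter on p <= 0.05 directly);
Benjamini-Hochberg adjustment is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNT = 0.5  # added to normalized group means before fold-changes

PARENTAL_FC = 1.5
HYBRID_FC = 1.25
P_THRESHOLD = 0.05


@dataclass
class ContrastSpec:
    """Which samples to compare and at which thresholds to call DMGs."""

    contrast_type: str  # parent_vs_parent | hybrid_vs_MPV | hybrid_vs_hybrid
    group_A: list = field(default_factory=list)
    group_B: list = field(default_factory=list)
    fc_threshold: float = 0.0
    p_threshold: float = P_THRESHOLD

    def __post_init__(self):
        if not self.fc_threshold:
            self.fc_threshold = (
                PARENTAL_FC if self.contrast_type == "parent_vs_parent" else HYBRID_FC
            )
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if set(self.group_A) & set(self.group_B):
            raise ValueError("groups must be disjoint")

    @property
    def directions(self) -> tuple[str, str]:
        """(label when A is higher, label when B is higher)."""
        if self.contrast_type == "parent_vs_parent":
            return "higher_in_P1", "higher_in_P2"
        if self.contrast_type == "hybrid_vs_MPV":
            return "above_MPV", "below_MPV"
        return "higher_in_A", "higher_in_B"


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over features of count_ij / geometric_mean_i, taken
    over features whose geometric mean is nonzero (i.e. nonzero in every
    sample). Factors are rescaled to geometric mean exactly 1, so rescaling
    any one sample is absorbed without shifting the common scale.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(mat).mean(axis=1)
    ok = np.isfinite(loggeo)
    if not ok.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; "
            "size factors need more features"
        )
    ratios = mat[ok] / np.exp(loggeo[ok])[:, None]
    sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


# --------------------------------------------------------------------------
# dispersion
# --------------------------------------------------------------------------


def estimate_dispersion(
    normalized: pd.DataFrame, groups: list[list[str]]
) -> pd.DataFrame:
    """Per-feature NB dispersion (variance = mu + alpha*mu^2).

    Method-of-moments alpha_hat = (s^2 - mu)/mu^2 pooled across replicate
    groups (weighted by group df), then floored by a fitted mean-dispersion
    trend a0 + a1/mu: final alpha = max(alpha_hat, trend). The floor is the
    conservative choice for designs with very few replicates, where
    per-feature estimates alone are unstable.
    """
    groups = [g for g in groups if len(g) >= 2]
    if not groups:
        raise ValueError("dispersion estimation needs a group with >=2 replicates")
    num = np.zeros(len(normalized))
    den = np.zeros(len(normalized))
    base_mean = np.zeros(len(normalized))
    wsum = 0.0
    for g in groups:
        sub = normalized[g].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(g) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += w * np.clip(a, 0.0, None)
        den += w
        base_mean += w * m
        wsum += w
    alpha_hat = num / den
    base_mean /= wsum

    trend = _dispersion_trend(base_mean, alpha_hat)
    final = np.maximum(alpha_hat, trend)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "alpha_mom": alpha_hat,
            "alpha_trend": trend,
            "alpha": final,
        },
        index=normalized.index,
    )


def _dispersion_trend(mean: np.ndarray, alpha_hat: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mean with nonnegative coefficients."""
    ok = mean > 0
    if ok.sum() < 3:
        return np.full_like(mean, 1e-8)
    a = np.clip(alpha_hat[ok], 0, np.quantile(alpha_hat[ok], 0.95))
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(x, a, rcond=None)
    coef = np.clip(coef, 0.0, None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(mean, 1e-300)
    return np.where(mean > 0, np.maximum(trend, 1e-8), 1e-8)


# --------------------------------------------------------------------------
# mid-parent pseudo-replicates
# --------------------------------------------------------------------------


def build_mpv(
    normalized: pd.DataFrame,
    parent1_cols: list[str],
    parent2_cols: list[str],
) -> pd.DataFrame:
    """Mid-parent pseudo-replicates from normalized parental counts.

    Pseudo-replicate r = (P1 rep r + P2 rep r)/2, pairing replicates by
    sorted index and truncating to the shorter parent. The result is on the
    normalized scale and carries unit size factors by construction.
    """
    p1, p2 = sorted(parent1_cols), sorted(parent2_cols)
    k = min(len(p1), len(p2))
    out = {}
    for r in range(k):
        out[f"MPV_r{r + 1}"] = 0.5 * (
            normalized[p1[r]].to_numpy(float) + normalized[p2[r]].to_numpy(float)
        )
    return pd.DataFrame(out, index=normalized.index)


# --------------------------------------------------------------------------
# exact NB test
# --------------------------------------------------------------------------


def nb_exact_pvalue(k_a: int, k_b: int, n_a: int, n_b: int, alpha: float) -> float:
    """Exact conditional NB test for two group sums.

    Conditions on the total k_a + k_b: under the null of a common mean
    q0 = (k_a + k_b)/(n_a + n_b) per replicate, the group sums are NB with
    means n_a*q0 and n_b*q0 and dispersions alpha/n_a and alpha/n_b. The
    two-sided p-value sums the probabilities of all splits (a, total - a)
    no more likely than the observed one, normalized by the total.
    """
    if min(k_a, k_b) < 0 or n_a < 1 or n_b < 1:
        raise ValueError("counts must be nonnegative and group sizes positive")
    total = k_a + k_b
    if total == 0:
        return 1.0
    q0 = total / (n_a + n_b)
    a = np.arange(total + 1)
    pa = _nb_pmf(a, n_a * q0, alpha / n_a)
    pb = _nb_pmf(total - a, n_b * q0, alpha / n_b)
    f = pa * pb
    f_obs = f[k_a]
    denom = f.sum()
    if denom <= 0 or not np.isfinite(denom):
        return 1.0
    p = f[f <= f_obs * (1 + 1e-8)].sum() / denom
    return float(min(p, 1.0))


def _nb_pmf(k: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    if mu <= 0:
        return np.where(k == 0, 1.0, 0.0)
    if alpha <= 1e-12:
        return stats.poisson.pmf(k, mu)
    r = 1.0 / alpha
    return stats.nbinom.pmf(k, r, r / (r + mu))


def nb_test(
    norm_a: pd.DataFrame,
    norm_b: pd.DataFrame,
    dispersions: pd.Series,
    contrast: ContrastSpec,
) -> pd.DataFrame:
    """Per-feature exact NB test of group A vs group B on normalized counts.

    Fold-change is the ratio of normalized group means with a pseudo-count
    of 0.5; the DMG flag requires fold-change >= fc_threshold (in either
    direction) and p <= p_threshold.
    """
    if norm_a.shape[1] == 0 or norm_b.shape[1] == 0:
        raise ValueError("both groups must contain at least one sample")
    feats = norm_a.index
    if not feats.equals(norm_b.index):
        raise ValueError("groups must share the same feature index")
    mean_a = norm_a.mean(axis=1).to_numpy()
    mean_b = norm_b.mean(axis=1).to_numpy()
    k_a = np.rint(norm_a.sum(axis=1).to_numpy()).astype(np.int64)
    k_b = np.rint(norm_b.sum(axis=1).to_numpy()).astype(np.int64)
    alphas = dispersions.reindex(feats).to_numpy(dtype=float)
    n_a, n_b = norm_a.shape[1], norm_b.shape[1]

    pvals = np.ones(len(feats))
    for i in range(len(feats)):
        pvals[i] = nb_exact_pvalue(int(k_a[i]), int(k_b[i]), n_a, n_b, float(alphas[i]))

    log2fc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))
    fc = 2.0 ** np.abs(log2fc)
    is_dmg = (fc >= contrast.fc_threshold) & (pvals <= contrast.p_threshold)
    up, down = contrast.directions
    direction = np.where(log2fc >= 0, up, down)
    res = pd.DataFrame(
        {
            "baseMean_A": mean_a,
            "baseMean_B": mean_b,
            "log2fc": log2fc,
            "pval": pvals,
            "is_dmg": is_dmg,
            "direction": direction,
        },
        index=feats,
    )
    return res


def adjust_bh(pvals: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    p = pvals.to_numpy(dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return pd.Series(out, index=pvals.index, name="padj")


# --------------------------------------------------------------------------
# reciprocal comparison and additivity classes
# --------------------------------------------------------------------------


def compare_reciprocal(
    dmg_counts_a: tuple[int, int], dmg_counts_b: tuple[int, int]
) -> float:
    """Two-sided Fisher's exact test on DMG counts in the reciprocal hybrids.

    Each argument is (number of DMGs, number of tested genes) for one cross
    direction; the test compares the DMG proportions.
    """
    (dmg_a, tested_a), (dmg_b, tested_b) = dmg_counts_a, dmg_counts_b
    if tested_a <= 0 or tested_b <= 0:
        raise ValueError("both crosses need at least one tested gene")
    if dmg_a > tested_a or dmg_b > tested_b:
        raise ValueError("DMG count cannot exceed tested count")
    table = [[dmg_a, tested_a - dmg_a], [dmg_b, tested_b - dmg_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def classify_additivity(
    hybrid_norm: pd.DataFrame,
    parent1_norm: pd.DataFrame,
    parent2_norm: pd.DataFrame,
    parental_result: pd.DataFrame,
    hybrid_result: pd.DataFrame,
) -> pd.DataFrame:
    """Express hybrid levels relative to the mid-parent value (MPV = 1).

    Restricted to parental DMGs. Reports the hybrid/MPV ratio, whether the
    hybrid sits at/above the high parent, between the parents, or at/below
    the low parent, and the additivity class: 'additive' unless the
    hybrid-vs-MPV test flagged the gene, else above_MPV/below_MPV.
    """
    feats = parental_result.index[parental_result["is_dmg"]]
    m1 = parent1_norm.loc[feats].mean(axis=1)
    m2 = parent2_norm.loc[feats].mean(axis=1)
    mh = hybrid_norm.loc[feats].mean(axis=1)
    mpv = 0.5 * (m1 + m2)
    hp = np.maximum(m1, m2)
    lp = np.minimum(m1, m2)
    ratio = (mh + PSEUDOCOUNT) / (mpv + PSEUDOCOUNT)
    level = np.where(mh >= hp, "at_or_above_high_parent",
                     np.where(mh <= lp, "at_or_below_low_parent", "between_parents"))
    hyb = hybrid_result.loc[feats]
    additivity = np.where(
        hyb["is_dmg"],
        np.where(hyb["log2fc"] >= 0, "above_MPV", "below_MPV"),
        "additive",
    )
    return pd.DataFrame(
        {
            "ratio_to_mpv": ratio,
            "level_class": level,
            "additivity": additivity,
            "high_parent_mean": hp,
            "low_parent_mean": lp,
        },
        index=feats,
    )
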