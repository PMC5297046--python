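"""Normalization, dispersion, exact NB test and additivity classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from hybridhist.differential import (ContrastSpec, adjust_bh, build_mpv,
                                     classify_additivity, compare_reciprocal,
                                     estimate_dispersion, nb_exact_pvalue,
                                     nb_test, normalize, size_factors)


# ----------------------------------------------------------------- oracles


def nb_logpmf(k, mu, alpha):
    """Reference NB log-pmf (variance mu + alpha*mu^2) via gamma functions."""
    k = np.asarray(k, dtype=float)
    if alpha <= 1e-12:
        return k * np.log(mu) - mu - gammaln(k + 1)
    r = 1.0 / alpha
    p = r / (r + mu)
    return (
        gammaln(k + r) - gammaln(r) - gammaln(k + 1) + r * np.log(p) + k * np.log1p(-p)
    )


def oracle_exact_nb(k_a, k_b, n_a, n_b, alpha):
    """Brute-force summation of the conditional NB distribution over splits."""
    total = k_a + k_b
    if total == 0:
        return 1.0
    q0 = total / (n_a + n_b)
    a = np.arange(total + 1)
    logf = nb_logpmf(a, n_a * q0, alpha / n_a) + nb_logpmf(total - a, n_b * q0, alpha / n_b)
    f = np.exp(logf - logf.max())
    return float(f[f <= f[k_a] * (1 + 1e-8)].sum() / f.sum())


def oracle_fisher(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logp(x):
        return (
            gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
            + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - (c1 - x) + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    xs = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = np.exp([logp(int(x)) for x in xs])
    p_obs = np.exp(logp(a))
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


# ------------------------------------------------------------- size factors


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_gives_factor_ratio_two(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_random_matrix_matches_direct_formula(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(200, 5)), columns=list("abcde"))
        sf = size_factors(counts)
        # independent recomputation
        mat = counts.to_numpy(float)
        geo = np.exp(np.log(mat).mean(axis=1))
        keep = geo > 0
        raw = np.array([np.median(mat[keep, j] / geo[keep]) for j in range(5)])
        raw /= np.exp(np.mean(np.log(raw)))  # geometric mean fixed at 1
        for j, col in enumerate("abcde"):
            assert sf[col] == pytest.approx(raw[j])
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_all_zero_features_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="more features"):
            size_factors(counts)


class TestDispersion:
    def _groups(self, cols):
        return [list(cols[:2]), list(cols[2:])]

    def test_poisson_data_yields_small_alpha(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, size=(2000, 4)), columns=list("abcd"), dtype=float
        )
        disp = estimate_dispersion(counts, self._groups("abcd"))
        assert disp["alpha"].median() < 0.05

    def test_nb_simulation_recovers_alpha(self, rng):
        alpha = 0.1
        mu = 200.0
        lam = rng.gamma(1 / alpha, mu * alpha, size=(2000, 4))
        counts = pd.DataFrame(rng.poisson(lam), columns=list("abcd"), dtype=float)
        disp = estimate_dispersion(counts, self._groups("abcd"))
        assert 0.05 <= disp["alpha_mom"].median() <= 0.2

    def test_constant_counts_give_zero_mom(self):
        counts = pd.DataFrame({"a": [5.0, 9], "b": [5.0, 9], "c": [7.0, 2], "d": [7.0, 2]})
        disp = estimate_dispersion(counts, self._groups("abcd"))
        assert (disp["alpha_mom"] == 0).all()

    def test_no_replicated_group_rejected(self):
        counts = pd.DataFrame({"a": [5.0], "b": [7.0]})
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(counts, [["a"], ["b"]])


class TestBuildMPV:
    def test_equal_parents_give_parent_values(self):
        norm = pd.DataFrame({"P1_r1": [10.0], "P1_r2": [20.0],
                             "P2_r1": [10.0], "P2_r2": [20.0]})
        mpv = build_mpv(norm, ["P1_r1", "P1_r2"], ["P2_r1", "P2_r2"])
        assert mpv.iloc[0].tolist() == [10.0, 20.0]

    def test_arithmetic_mean(self):
        norm = pd.DataFrame({"P1_r1": [100.0], "P2_r1": [200.0]})
        mpv = build_mpv(norm, ["P1_r1"], ["P2_r1"])
        assert mpv.iloc[0, 0] == 150.0

    def test_random_matrix_matches_formula(self, rng):
        norm = pd.DataFrame(rng.uniform(0, 100, size=(50, 4)),
                            columns=["P1_r1", "P1_r2", "P2_r1", "P2_r2"])
        mpv = build_mpv(norm, ["P1_r1", "P1_r2"], ["P2_r1", "P2_r2"])
        np.testing.assert_allclose(
            mpv["MPV_r1"], 0.5 * (norm["P1_r1"] + norm["P2_r1"])
        )
        np.testing.assert_allclose(
            mpv["MPV_r2"], 0.5 * (norm["P1_r2"] + norm["P2_r2"])
        )

    def test_unequal_replicates_truncate(self):
        norm = pd.DataFrame({"P1_r1": [4.0], "P1_r2": [6.0], "P2_r1": [8.0]})
        mpv = build_mpv(norm, ["P1_r1", "P1_r2"], ["P2_r1"])
        assert mpv.shape[1] == 1 and mpv.iloc[0, 0] == 6.0


class TestExactNB:
    def test_balanced_null_is_not_significant(self):
        norm_a = pd.DataFrame({"a1": [10.0], "a2": [10.0]})
        norm_b = pd.DataFrame({"b1": [10.0], "b2": [10.0]})
        spec = ContrastSpec("parent_vs_parent")
        res = nb_test(norm_a, norm_b, pd.Series([0.05]), spec)
        assert res["log2fc"].iloc[0] == 0.0
        assert res["pval"].iloc[0] >= 0.99
        assert not res["is_dmg"].iloc[0]

    def test_threshold_semantics_hybrid_vs_parental(self):
        # a clear 1.4-fold change passes the hybrid threshold (1.25) but
        # not the parental one (1.5)
        norm_a = pd.DataFrame({"a1": [1400.0], "a2": [1400.0]})
        norm_b = pd.DataFrame({"b1": [1000.0], "b2": [1000.0]})
        disp = pd.Series([0.001])
        hybrid = nb_test(norm_a, norm_b, disp, ContrastSpec("hybrid_vs_MPV"))
        parental = nb_test(norm_a, norm_b, disp, ContrastSpec("parent_vs_parent"))
        assert hybrid["pval"].iloc[0] <= 0.01
        assert hybrid["is_dmg"].iloc[0]
        assert not parental["is_dmg"].iloc[0]

    @pytest.mark.parametrize(
        "k_a,k_b,n_a,n_b,alpha",
        [(12, 55, 2, 2, 0.1), (5, 7, 1, 1, 0.1), (25, 30, 2, 3, 0.05),
         (0, 9, 2, 2, 0.2), (40, 40, 2, 2, 0.0)],
    )
    def test_matches_enumeration_oracle(self, k_a, k_b, n_a, n_b, alpha):
        got = nb_exact_pvalue(k_a, k_b, n_a, n_b, alpha)
        assert got == pytest.approx(oracle_exact_nb(k_a, k_b, n_a, n_b, alpha), abs=1e-10)

    def test_symmetry_under_group_swap(self, rng):
        counts_a = pd.DataFrame(rng.poisson(60, size=(40, 2)), dtype=float,
                                columns=["a1", "a2"])
        counts_b = pd.DataFrame(rng.poisson(90, size=(40, 2)), dtype=float,
                                columns=["b1", "b2"])
        disp = pd.Series(np.full(40, 0.05))
        spec = ContrastSpec("hybrid_vs_hybrid")
        fwd = nb_test(counts_a, counts_b, disp, spec)
        rev = nb_test(counts_b, counts_a, disp, spec)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["pval"], rev["pval"], atol=1e-12)

    def test_scaling_absorbed_by_size_factors(self, rng):
        counts = pd.DataFrame(rng.poisson(500, size=(300, 4)),
                              columns=["a1", "a2", "b1", "b2"])
        scaled = counts.copy()
        scaled["b2"] = scaled["b2"] * 4
        spec = ContrastSpec("parent_vs_parent")
        disp = pd.Series(np.full(300, 0.02), index=counts.index)

        sf = size_factors(counts)
        sf_scaled = sf.copy()
        sf_scaled["b2"] *= 4  # the factor absorbs the scaling exactly
        norm1 = normalize(counts, sf)
        norm2 = normalize(scaled, sf_scaled)
        r1 = nb_test(norm1[["a1", "a2"]], norm1[["b1", "b2"]], disp, spec)
        r2 = nb_test(norm2[["a1", "a2"]], norm2[["b1", "b2"]], disp, spec)
        assert (r1["is_dmg"] == r2["is_dmg"]).all()
        np.testing.assert_allclose(r1["pval"], r2["pval"], atol=1e-6)
        # and the estimator itself recovers the 4x ratio for the scaled sample
        est = size_factors(scaled)
        assert est["b2"] / est["b1"] == pytest.approx(
            4 * sf["b2"] / sf["b1"], rel=0.02
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least one sample"):
            nb_test(pd.DataFrame(index=[0]), pd.DataFrame({"b": [1.0]}),
                    pd.Series([0.1]), ContrastSpec("parent_vs_parent"))


class TestCompareReciprocal:
    def test_equal_proportions_give_p_one(self):
        assert compare_reciprocal((50, 1000), (50, 1000)) == pytest.approx(1.0)

    def test_diagonal_table_matches_closed_form(self):
        # table [[10,0],[0,10]]: two-sided p = 2 / C(20,10)
        from math import comb

        p = compare_reciprocal((10, 10), (0, 10))
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_random_tables_match_hypergeometric_enumeration(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 25, 4)
            if a + b == 0 or c + d == 0:
                continue
            got = compare_reciprocal((int(a), int(a + b)), (int(c), int(c + d)))
            assert got == pytest.approx(oracle_fisher(int(a), int(b), int(c), int(d)),
                                        abs=1e-9)

    def test_zero_tested_rejected(self):
        with pytest.raises(ValueError, match="tested"):
            compare_reciprocal((0, 0), (5, 10))


class TestAdditivity:
    def _frames(self, hybrid, p1, p2):
        idx = pd.Index([f"g{i}" for i in range(len(hybrid))])
        mk = lambda v: pd.DataFrame({"r1": v, "r2": v}, index=idx, dtype=float)
        return mk(hybrid), mk(p1), mk(p2)

    def test_hybrid_at_mpv_is_additive(self):
        hyb, p1, p2 = self._frames([150], [100], [200])
        parental = pd.DataFrame({"is_dmg": [True], "log2fc": [-1.0]}, index=hyb.index)
        hybres = pd.DataFrame({"is_dmg": [False], "log2fc": [0.0]}, index=hyb.index)
        out = classify_additivity(hyb, p1, p2, parental, hybres)
        assert out["additivity"].iloc[0] == "additive"
        assert out["ratio_to_mpv"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_hybrid_at_high_parent_ratio_four_thirds(self):
        hyb, p1, p2 = self._frames([200], [100], [200])
        parental = pd.DataFrame({"is_dmg": [True], "log2fc": [-1.0]}, index=hyb.index)
        hybres = pd.DataFrame({"is_dmg": [True], "log2fc": [np.log2(4 / 3)]}, index=hyb.index)
        out = classify_additivity(hyb, p1, p2, parental, hybres)
        assert out["ratio_to_mpv"].iloc[0] == pytest.approx(4 / 3, abs=0.01)
        assert out["level_class"].iloc[0] == "at_or_above_high_parent"
        assert out["additivity"].iloc[0] == "above_MPV"

    def test_injected_above_mpv_effects_have_ratio_above_one(self, simdata):
        from hybridhist.pipeline import differential_suite

        cm = simdata.counts["K27me3"]
        res = differential_suite(cm.counts, cm.samples)
        tm = simdata.truth.marks.query("mark == 'K27me3'").set_index("gene_id")
        hyb = res["contrasts"]["P1xP2_vs_MPV"]
        flagged = hyb.index[hyb["is_dmg"] & (hyb["log2fc"] > 0)]
        truth_up = tm.index[tm["nonadditive_log2fc_P1xP2"] > 0]
        called_up = [g for g in flagged if g in truth_up]
        if called_up:
            add = res["additivity"]["P1xP2"]
            have = [g for g in called_up if g in add.index]
            ratios = add.loc[have, "ratio_to_mpv"] if have else pd.Series(dtype=float)
            if len(ratios):
                assert (ratios > 1).mean() >= 0.9


def test_bh_adjustment_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = pd.Series(rng.uniform(0, 1, 200) ** 2)
    ours = adjust_bh(p)
    ref = multipletests(p.to_numpy(), method="fdr_bh")[1]
    np.testing.assert_allclose(ours, ref, atol=1e-12)
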