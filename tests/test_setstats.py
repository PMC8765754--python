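import numpy as np
import pandas as pd
import pytest
from hypothesis import strategies as st
from scipy import stats

from splicewave.setstats import (
    background_subtract_polya,
    delta_psi_concordance,
    diff_enrichment,
    overlap_or,
    overlap_or_many,
    subsampled_wilcoxon,
)


def hypergeom_two_sided_p(both, a_only, b_only, neither):
    """Oracle: exhaustive two-sided Fisher p by hypergeometric enumeration."""
    n_a = both + a_only
    n_b = both + b_only
    N = both + a_only + b_only + neither
    rv = stats.hypergeom(N, n_a, n_b)
    kmin = max(0, n_a + n_b - N)
    kmax = min(n_a, n_b)
    p_obs = rv.pmf(both)
    return sum(
        rv.pmf(k) for k in range(kmin, kmax + 1) if rv.pmf(k) <= p_obs * (1 + 1e-9)
    )


class TestOverlapOr:
    def test_sample_odds_ratio_arithmetic(self):
        U = [f"x{i}" for i in range(1000)]
        A = set(U[:100])
        B = set(U[:30]) | set(U[100:120])
        r = overlap_or(A, B, U)
        assert r.n_both == 30
        assert r.odds_ratio == pytest.approx(18.857, abs=1e-3)
        assert r.log2_odds_ratio == pytest.approx(np.log2(18.857142857), abs=1e-4)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(40)
        for _ in range(20):
            N = int(rng.integers(10, 51))
            U = list(range(N))
            A = set(rng.choice(U, size=rng.integers(1, N), replace=False).tolist())
            B = set(rng.choice(U, size=rng.integers(1, N), replace=False).tolist())
            r = overlap_or(A, B, U)
            expected = hypergeom_two_sided_p(
                len(A & B), len(A - B), len(B - A), N - len(A | B)
            )
            assert r.p == pytest.approx(expected, rel=1e-7)

    def test_independent_sets_log2_or_near_zero(self):
        rng = np.random.default_rng(41)
        U = list(range(400))
        vals = []
        for _ in range(200):
            A = set(rng.choice(U, 80, replace=False).tolist())
            B = set(rng.choice(U, 80, replace=False).tolist())
            vals.append(overlap_or(A, B, U).log2_odds_ratio)
        assert abs(np.mean(vals)) < 0.2

    def test_symmetry_and_complement_invariance(self):
        U = set(range(100))
        A = set(range(30))
        B = set(range(20, 60))
        r1 = overlap_or(A, B, U)
        r2 = overlap_or(B, A, U)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio)
        r3 = overlap_or(U - A, U - B, U)
        assert r3.odds_ratio == pytest.approx(r1.odds_ratio)

    def test_universe_must_contain_sets(self):
        with pytest.raises(ValueError):
            overlap_or({1, 2}, {2, 3}, {1, 2})

    def test_zero_cell_haldane_correction(self):
        U = set(range(50))
        A = set(range(10))
        B = set(range(10, 20))  # no overlap: zero cell
        r = overlap_or(A, B, U)
        assert r.odds_ratio > 0
        assert np.isfinite(r.log2_odds_ratio)

    def test_bh_family_is_the_call(self):
        U = set(range(200))
        pairs = {
            "ab": (set(range(50)), set(range(25, 75))),
            "cd": (set(range(100, 110)), set(range(150, 160))),
        }
        df = overlap_or_many(pairs, U)
        assert (df["q"] >= df["p"] - 1e-12).all()


class TestConcordance:
    def test_identical_tables(self):
        d = pd.Series([0.1, -0.2, 0.3, 0.05, -0.4] * 2, index=[f"e{i}" for i in range(10)])
        res = delta_psi_concordance(d, d)
        assert res["rho"] == pytest.approx(1.0)
        assert res["sign_agreement"] == 1.0

    def test_negated_tables(self):
        d = pd.Series(np.linspace(-0.5, 0.5, 12), index=[f"e{i}" for i in range(12)])
        res = delta_psi_concordance(d, -d)
        assert res["rho"] == pytest.approx(-1.0)
        assert res["sign_agreement"] <= 1 / 12  # only the zero-crossing can agree

    def test_shared_latent_signal_detected(self):
        rng = np.random.default_rng(42)
        latent = rng.normal(0, 0.2, 300)
        a = pd.Series(latent + rng.normal(0, 0.1, 300))
        b = pd.Series(latent + rng.normal(0, 0.1, 300))
        res = delta_psi_concordance(a, b)
        assert res["rho"] > 0.6

    def test_constant_input_rejected(self):
        a = pd.Series(np.zeros(20))
        with pytest.raises(ValueError):
            delta_psi_concordance(a, a)


class TestSubsampledWilcoxon:
    def test_null_median_p_near_half(self):
        rng = np.random.default_rng(43)
        pool = rng.normal(0, 1, 2000)
        subset = rng.normal(0, 1, 100)
        med_p, ps = subsampled_wilcoxon(subset, pool, n_rep=1000, seed=7)
        assert 0.35 <= med_p <= 0.65

    def test_shifted_subset_detected(self):
        rng = np.random.default_rng(44)
        pool = rng.normal(0, 1, 2000)
        subset = rng.normal(2.0, 1, 100)
        med_p, _ = subsampled_wilcoxon(subset, pool, n_rep=200, seed=8)
        assert med_p < 1e-4

    def test_single_rep_deterministic(self):
        rng = np.random.default_rng(45)
        pool = rng.normal(0, 1, 500)
        subset = pool[:50]
        p1, _ = subsampled_wilcoxon(subset, pool, n_rep=1, seed=9)
        p2, _ = subsampled_wilcoxon(subset, pool, n_rep=1, seed=9)
        assert p1 == p2

    def test_tiny_subset_rejected(self):
        with pytest.raises(ValueError):
            subsampled_wilcoxon([1.0, 2.0], np.arange(100.0))


class TestDiffEnrichment:
    def test_identical_groups_null(self):
        mat = pd.DataFrame(
            {"a1": [1.0, 2.0], "a2": [2.0, 3.0], "a3": [3.0, 4.0],
             "b1": [1.0, 2.0], "b2": [2.0, 3.0], "b3": [3.0, 4.0]},
            index=["p1", "p2"],
        )
        res = diff_enrichment(mat, ["a1", "a2", "a3"], ["b1", "b2", "b3"],
                              log2_transform=False, normalize=False)
        assert (res["log2fc"] == 0).all()
        assert (res["p"] == 1.0).all()

    def test_welch_worked_example(self):
        mat = pd.DataFrame(
            {"a1": [1.0], "a2": [2.0], "a3": [3.0], "b1": [4.0], "b2": [5.0], "b3": [6.0]},
            index=["p"],
        )
        res = diff_enrichment(mat, ["a1", "a2", "a3"], ["b1", "b2", "b3"],
                              log2_transform=False, normalize=False)
        # oracle: hand-computed Welch statistic and df
        se = np.sqrt(1 / 3 + 1 / 3)
        t_expected = (2.0 - 5.0) / se
        df_expected = (1 / 3 + 1 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (1 / 3) ** 2 / 2)
        p_expected = 2 * stats.t.sf(abs(t_expected), df_expected)
        assert res.loc["p", "t"] == pytest.approx(t_expected, abs=1e-3)
        assert res.loc["p", "t"] == pytest.approx(-3.674, abs=1e-3)
        assert res.loc["p", "df"] == pytest.approx(4.0, abs=1e-9)
        assert res.loc["p", "p"] == pytest.approx(p_expected, rel=1e-9)
        assert res.loc["p", "p"] == pytest.approx(0.0214, abs=5e-4)

    def test_missing_values_flagged_not_imputed(self):
        mat = pd.DataFrame(
            {"a1": [1.0, np.nan], "a2": [2.0, 2.0], "b1": [3.0, 3.0], "b2": [4.0, 4.0]},
            index=["ok", "bad"],
        )
        res = diff_enrichment(mat, ["a1", "a2"], ["b1", "b2"],
                              log2_transform=False, normalize=False)
        assert res.loc["bad", "flag"] == "nonpositive_or_missing"
        assert np.isnan(res.loc["bad", "p"])

    def test_planted_fold_change_detected(self):
        rng = np.random.default_rng(46)
        n = 200
        base = rng.normal(20, 0.5, (n, 6))
        # 4-fold (2 log2 units) on a 10% minority, so per-sample mean-centering
        # leaves the planted effect nearly intact
        base[: n // 10, 3:] += 2.0
        mat = pd.DataFrame(
            2.0 ** base, columns=["a1", "a2", "a3", "b1", "b2", "b3"],
            index=[f"p{i}" for i in range(n)],
        )
        res = diff_enrichment(mat, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        planted = res.iloc[: n // 10]
        assert (planted["p"] < 0.05).mean() > 0.5
        assert planted["log2fc"].mean() == pytest.approx(-1.8, abs=0.3)


class TestBackgroundSubtract:
    def test_control_equal_to_enriched_drops_everything(self):
        mat = pd.DataFrame({"r1": [5.0, 6.0], "r2": [7.0, 8.0]}, index=["p1", "p2"])
        corrected, flags = background_subtract_polya(mat, mat.copy())
        assert corrected.empty

    def test_zero_control_leaves_matrix_unchanged(self):
        mat = pd.DataFrame({"r1": [5.0, 6.0], "r2": [7.0, 8.0]}, index=["p1", "p2"])
        ctrl = mat * 0.0
        corrected, _ = background_subtract_polya(mat, ctrl)
        pd.testing.assert_frame_equal(corrected, mat)

    def test_true_binders_recovered_from_sticky_background(self):
        rng = np.random.default_rng(47)
        n_true, n_sticky = 50, 150
        idx = [f"p{i}" for i in range(n_true + n_sticky)]
        ctrl_level = rng.normal(10, 0.5, (n_true + n_sticky, 3))
        enr = ctrl_level + rng.normal(0, 0.3, ctrl_level.shape)
        enr[:n_true] += 2.0  # true binders sit 2 log2 units above background
        enriched = pd.DataFrame(enr, index=idx, columns=["r1", "r2", "r3"])
        control = pd.DataFrame(ctrl_level, index=idx, columns=["c1", "c2", "c3"])
        corrected, _ = background_subtract_polya(enriched, control)
        recovered = sum(1 for i in range(n_true) if f"p{i}" in corrected.index)
        assert recovered / n_true > 0.9

    def test_unmatched_rows_flagged(self):
        enriched = pd.DataFrame({"r1": [5.0, 9.0]}, index=["p1", "novel"])
        control = pd.DataFrame({"c1": [1.0]}, index=["p1"])
        corrected, flags = background_subtract_polya(enriched, control)
        assert flags.loc["novel"] == "no_control_match"
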