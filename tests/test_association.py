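"""Marker association models, LD, rank-based tests and thresholds."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from junctionqtl.association import (
    bonferroni_threshold,
    fit_marker_model,
    genotype_class_summary,
    kruskal_wallis,
    ld_r2,
    rank_markers,
    scan,
)
from junctionqtl.io_core import GenotypeMatrix


def _matrix(dosage, positions=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    positions = positions or list(range(100, 100 + m))
    markers = [(f"m{j}", "chr1", positions[j], "A", "G") for j in range(m)]
    return GenotypeMatrix([f"s{i}" for i in range(n)], markers, dosage)


class TestFitMarkerModel:
    def test_noiseless_fit_recovers_slope(self):
        g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 2], dtype=float)
        fit = fit_marker_model(2.0 * g, g)
        assert fit.beta == pytest.approx(2.0, abs=1e-10)
        assert fit.p_value < 1e-12

    def test_monomorphic_marker_skipped(self):
        fit = fit_marker_model(np.arange(6.0), np.ones(6))
        assert fit.missing and fit.reason == "monomorphic"

    def test_beta_se_match_normal_equations_oracle(self, rng):
        n = 8
        g = rng.integers(0, 3, n).astype(float)
        x = rng.normal(size=n)
        y = 1.0 + 0.8 * x + 0.5 * g + rng.normal(size=n)
        fit = fit_marker_model(y, g, X=x)
        # independent solve of the normal equations
        M = np.column_stack([np.ones(n), x, g])
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        resid = y - M @ beta
        sigma2 = resid @ resid / (n - 3)
        se = math.sqrt(sigma2 * np.linalg.inv(M.T @ M)[2, 2])
        assert fit.beta == pytest.approx(beta[2], abs=1e-10)
        assert fit.se == pytest.approx(se, abs=1e-10)

    def test_pairwise_deletion_of_missing(self, rng):
        g = np.array([0, 1, 2, np.nan, 1, 0, 2, 1], dtype=float)
        y = np.array([0.1, 1.2, 2.1, 9.9, 0.9, -0.2, 2.2, 1.1])
        fit = fit_marker_model(y, g)
        keep = ~np.isnan(g)
        ref = fit_marker_model(y[keep], g[keep])
        assert fit.beta == pytest.approx(ref.beta) and fit.n == 7

    def test_collinear_covariates_rejected(self):
        n = 12
        x = np.arange(n, dtype=float)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_marker_model(np.random.default_rng(0).normal(size=n), np.tile([0, 1, 2], 4), X=X)


class TestRandomInterceptREML:
    def test_zero_variance_component_reduces_to_ols(self, rng):
        # groups carry no signal: lambda optimises to the boundary and the
        # GLS fit must coincide with plain least squares
        n = 60
        g = rng.integers(0, 3, n).astype(float)
        y = 0.4 * g + rng.normal(size=n)
        groups = rng.integers(0, 6, n)
        reml = fit_marker_model(y, g, random_group=groups)
        ols = fit_marker_model(y, g)
        if reml.sigma2_group == pytest.approx(0.0, abs=1e-9):
            assert reml.beta == pytest.approx(ols.beta, abs=1e-8)
            assert reml.se == pytest.approx(ols.se, abs=1e-8)
        else:  # lambda stayed positive on this draw: estimates still agree closely
            assert reml.beta == pytest.approx(ols.beta, rel=0.05)

    def test_matches_statsmodels_mixedlm(self, rng):
        statsmodels = pytest.importorskip("statsmodels.api")
        n, k = 120, 8
        groups = np.repeat(np.arange(k), n // k)
        u = rng.normal(0, 1.0, k)[groups]
        g = rng.integers(0, 3, n).astype(float)
        y = 0.5 * g + u + rng.normal(size=n)
        fit = fit_marker_model(y, g, random_group=groups)
        sm_fit = statsmodels.MixedLM(y, np.column_stack([np.ones(n), g]), groups=groups).fit(reml=True)
        assert fit.beta == pytest.approx(sm_fit.params[1], rel=1e-3)
        assert fit.se == pytest.approx(sm_fit.bse[1], rel=1e-2)


class TestScan:
    def _simulate(self, rng, n=200, m=50, effect=1.0):
        G = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        y = effect * G[:, m // 2] + rng.normal(size=n)
        return G, y

    def test_matches_single_marker_fits(self, rng):
        G, y = self._simulate(rng, n=80, m=10)
        gm = _matrix(G)
        X = rng.normal(size=(80, 2))
        res = scan(y, gm, covariates=X)
        for j in [0, 4, 9]:
            fit = fit_marker_model(y, G[:, j], X=X)
            row = res.iloc[j]
            assert row["beta"] == pytest.approx(fit.beta, abs=1e-10)
            assert row["se"] == pytest.approx(fit.se, abs=1e-10)
            assert row["p"] == pytest.approx(fit.p_value, rel=1e-10)
            assert row["var_explained_pct"] == pytest.approx(fit.var_explained_pct, abs=1e-8)

    def test_causal_marker_ranks_first_without_ld(self, rng):
        hits = 0
        for _ in range(40):
            G, y = self._simulate(rng, n=200, m=50)
            res = scan(y, _matrix(G))
            top = res.loc[res["rank"] == 1, "marker"].iloc[0]
            hits += top == f"m{25}"
        assert hits >= 38  # >= 95% of independent-marker draws

    def test_conditioning_absorbs_perfect_ld_proxies(self, rng):
        n = 150
        g = rng.binomial(2, 0.5, n).astype(float)
        G = np.column_stack([g, g.copy(), 2 - g, rng.binomial(2, 0.5, n)])
        y = 3.0 * g + rng.normal(scale=1e-3, size=n)
        gm = _matrix(G)
        res = scan(y, gm, condition_on="m0")
        assert res.loc[0, "reason"] == "conditioned"
        for j in (1, 2):  # duplicate and allele-flipped proxy
            row = res.iloc[j]
            assert row["reason"] == "collinear" or row["p"] > 0.99
        assert res.iloc[3]["p"] > 1e-4  # unlinked marker: no signal left

    def test_conditional_drop_exceeds_five_orders(self, rng):
        n = 300
        g = rng.binomial(2, 0.5, n).astype(float)
        flip = rng.random(n) < 0.05
        proxy = np.where(flip, rng.binomial(2, 0.5, n), g).astype(float)
        G = np.column_stack([g, proxy])
        y = 1.0 * g + rng.normal(size=n)
        gm = _matrix(G)
        plain = scan(y, gm)
        cond = scan(y, gm, condition_on="m0")
        assert cond.loc[1, "p"] > plain.loc[1, "p"] * 1e5

    def test_null_pvalues_uniform(self, rng):
        G = rng.binomial(2, 0.4, size=(150, 400)).astype(float)
        y = rng.normal(size=150)
        res = scan(y, gm := _matrix(G))
        ks = stats.kstest(res["p"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_sample_alignment_by_index(self, rng):
        G, y = self._simulate(rng, n=60, m=5)
        gm = _matrix(G)
        series = pd.Series(y, index=gm.sample_ids)
        shuffled = series.sample(frac=1.0, random_state=0)
        res_a = scan(series, gm)
        res_b = scan(shuffled, gm)
        pd.testing.assert_frame_equal(res_a, res_b)

    def test_disjoint_samples_error(self, rng):
        G, y = self._simulate(rng, n=10, m=3)
        gm = _matrix(G)
        with pytest.raises(ValueError, match="no samples shared"):
            scan(pd.Series(y, index=[f"other{i}" for i in range(10)]), gm)


class TestLdR2:
    def test_identity_and_allele_flip(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_computed_correlation(self):
        g1 = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        g2 = np.array([0, 1, 0, 1, 2, 2], dtype=float)
        r = np.corrcoef(g1, g2)[0, 1]
        assert ld_r2(g1, g2) == pytest.approx(r * r)
        assert ld_r2(g2, g1) == pytest.approx(ld_r2(g1, g2))

    def test_monomorphic_is_missing(self):
        assert math.isnan(ld_r2(np.ones(6), np.array([0, 1, 2, 0, 1, 2])))


def _kw_permutation_p(values, sizes):
    """Exact permutation p-value of the Kruskal-Wallis H over all distinct
    assignments of the observed values to groups of the given sizes."""
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = stats.rankdata(values)
    tie_sizes = np.unique(values, return_counts=True)[1]
    tie_corr = 1.0 - (tie_sizes**3 - tie_sizes).sum() / (n**3 - n)

    def h_of(groups_idx):
        h = 12.0 / (n * (n + 1)) * sum(
            ranks[list(idx)].sum() ** 2 / len(idx) for idx in groups_idx
        ) - 3 * (n + 1)
        return h / tie_corr

    observed = h_of(
        np.split(np.arange(n), np.cumsum(sizes)[:-1])
    )
    count = total = 0
    indices = set(range(n))
    for a in itertools.combinations(range(n), sizes[0]):
        rest = indices - set(a)
        for b in itertools.combinations(sorted(rest), sizes[1]):
            c = tuple(sorted(rest - set(b)))
            total += 1
            if h_of([a, b, c]) >= observed - 1e-12:
                count += 1
    return count / total


class TestKruskalWallis:
    def test_two_group_rank_formula(self):
        H, p = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert H == pytest.approx(27 / 7)

    def test_identical_groups_give_zero_h(self):
        H, _ = kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert H == pytest.approx(0.0)

    def test_all_tied_values(self):
        H, p = kruskal_wallis([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert (H, p) == (0.0, 1.0)

    def test_chi_square_p_close_to_exact_permutation(self):
        # clearly separated groups at n=9: in the significance tail (where
        # the test is used) the chi-square approximation sits within 0.02 of
        # the exact permutation distribution; mid-range p deviates more at
        # this sample size
        values = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0, 7.0, 8.0, 9.0]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        _, p_chi2 = kruskal_wallis(values, groups)
        p_exact = _kw_permutation_p(values, [3, 3, 3])
        assert abs(p_chi2 - p_exact) <= 0.02


class TestGenotypeClassSummary:
    def test_mean_and_se(self):
        out = genotype_class_summary([1.0, 2.0, 3.0], [1, 1, 1])
        row = out.iloc[0]
        assert (row["n"], row["mean"]) == (3, 2.0)
        assert row["se"] == pytest.approx(1 / math.sqrt(3))
        assert row["median"] == 2.0

    def test_empty_classes_omitted(self):
        out = genotype_class_summary([1.0, 2.0], [2, 2])
        assert list(out["dosage"]) == [2]


class TestBonferroni:
    def test_junction_scan_threshold(self):
        assert bonferroni_threshold(0.05, 3128 * 14) == pytest.approx(1.1418e-6, rel=1e-4)

    def test_in_vitro_threshold(self):
        assert bonferroni_threshold(0.05, 12) == pytest.approx(4.1667e-3, rel=1e-4)

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestRankMarkers:
    def test_tie_break_by_position(self):
        df = pd.DataFrame(
            {"marker": ["a", "b", "c"], "pos": [5, 1, 3], "p": [1e-8, 1e-3, 1e-8]}
        )
        out = rank_markers(df)
        assert list(out["rank"]) == [2, 3, 1]

    def test_all_equal_p_follow_position(self):
        df = pd.DataFrame({"marker": list("abc"), "pos": [30, 10, 20], "p": [0.5] * 3})
        assert list(rank_markers(df)["rank"]) == [3, 1, 2]

    def test_random_pvalues_match_sort_oracle(self, rng):
        p = rng.random(100)
        df = pd.DataFrame({"marker": [f"m{i}" for i in range(100)], "pos": range(100), "p": p})
        out = rank_markers(df)
        oracle = np.empty(100, dtype=int)
        oracle[np.argsort(p, kind="stable")] = np.arange(1, 101)
        np.testing.assert_array_equal(out["rank"].to_numpy(dtype=int), oracle)

    def test_missing_p_unranked(self):
        df = pd.DataFrame({"marker": list("ab"), "pos": [1, 2], "p": [0.1, np.nan]})
        out = rank_markers(df)
        assert out.loc[1, "rank"] is pd.NA or pd.isna(out.loc[1, "rank"])
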