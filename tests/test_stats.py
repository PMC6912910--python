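"""Rank tests against enumeration oracles, Spearman, PLS, group summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phylostruct.stats import (
    group_summaries,
    nri_climate_spearman,
    pls_regression,
    significance_stars,
    spearman,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


def signed_rank_exact_p(values) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(values, dtype=float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = d.size
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= abs(w_obs - mean) - 1e-12)
    return float(min(p, 1.0))


def rank_sum_exact_p(a, b) -> float:
    """Two-sided exact p by enumerating all C(n, |a|) group assignments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    na = a.size
    r_obs = ranks[:na].sum()
    stats = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(pooled.size), na)
    ]
    stats = np.asarray(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= abs(r_obs - mean) - 1e-12)
    return float(min(p, 1.0))


class TestSignedRank:
    def test_all_negative_example(self):
        stat, p = wilcoxon_signed_rank([-1.0, -2.0, -3.0])
        assert stat == 0.0
        assert p == pytest.approx(0.25)

    def test_symmetric_values_uninformative(self):
        _, p = wilcoxon_signed_rank([-3, 3, -2, 2, -1, 1])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for n in range(4, 9):
            for _ in range(5):
                x = np.round(rng.standard_normal(n) * 10, 1)
                while (x == 0).any() or np.unique(np.abs(x)).size < n:
                    x = np.round(rng.standard_normal(n) * 10, 1)
                _, p = wilcoxon_signed_rank(x)
                assert p == pytest.approx(signed_rank_exact_p(x), abs=1e-12)

    def test_degenerate_input_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])


class TestRankSum:
    def test_separated_example(self):
        stat, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert stat == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_groups(self):
        # same values => heavy ties => no separation
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for na, nb in [(2, 3), (3, 3), (4, 4), (5, 3)]:
            for _ in range(5):
                x = np.round(rng.standard_normal(na + nb) * 10, 1)
                while np.unique(x).size < x.size:
                    x = np.round(rng.standard_normal(na + nb) * 10, 1)
                _, p = wilcoxon_rank_sum(x[:na], x[na:])
                assert p == pytest.approx(
                    rank_sum_exact_p(x[:na], x[na:]), abs=1e-12
                )


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_ties_equal_pearson_of_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 3.0])
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        want = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(want, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30) + 0.5 * x
        base, _ = spearman(x, y)
        rho_exp, _ = spearman(np.exp(x), y)
        rho_cub, _ = spearman(x, y ** 3)
        assert rho_exp == pytest.approx(base, abs=1e-12)
        assert rho_cub == pytest.approx(base, abs=1e-12)

    def test_zero_rank_variance_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestPLS:
    def test_single_relevant_direction(self):
        # orthogonal noise-free predictors, y exactly linear in one column
        rng = np.random.default_rng(3)
        A = rng.standard_normal((80, 6))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))  # centered + orthogonal
        X = pd.DataFrame(Q, columns=list("abcdef"))
        y = 2.0 * X["c"].to_numpy()
        res = pls_regression(X, y, n_components=3)
        assert res.r2y_cumulative[0] == pytest.approx(1.0, abs=1e-6)

    def test_null_relation_small_r2(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((1000, 10)))
        y = rng.standard_normal(1000)
        res = pls_regression(X, y, n_components=3)
        assert res.r2y_cumulative[-1] < 0.05

    def test_generative_recovery(self):
        """y built from 2 latent X directions with known population
        R^2 = 0.65 is recovered within +/- 0.05 at 3 components."""
        rng = np.random.default_rng(11)
        n = 2000
        X = pd.DataFrame(rng.standard_normal((n, 8)))
        signal = (X[0] + X[3]).to_numpy() / np.sqrt(2)
        r2 = 0.65
        noise = rng.standard_normal(n) * np.sqrt((1 - r2) / r2)
        y = signal + noise
        res = pls_regression(X, y, n_components=3)
        assert res.r2y_cumulative[-1] == pytest.approx(r2, abs=0.05)

    def test_explained_nondecreasing(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.standard_normal((60, 7)))
        y = X.iloc[:, 0] + 0.5 * rng.standard_normal(60)
        res = pls_regression(X, y, n_components=4)
        assert (np.diff(res.r2y_cumulative) >= -1e-9).all()
        assert (np.diff(res.r2x_cumulative) >= -1e-9).all()

    def test_constant_response_errors(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 3)))
        with pytest.raises(ValueError, match="constant"):
            pls_regression(X, np.ones(10), n_components=2)


class TestGroupSummaries:
    def test_location_shift_signs_recovered(self):
        rng = np.random.default_rng(17)
        groups = pd.Series(
            np.repeat(["g1", "g2"], 30),
            index=[f"p{i}" for i in range(60)],
        )
        nri = np.concatenate(
            [rng.normal(1.0, 0.3, 30), rng.normal(-1.0, 0.3, 30)]
        )
        metrics = pd.DataFrame({"nri": nri}, index=groups.index)
        per_group, pairwise = group_summaries(metrics, groups)
        med = per_group.set_index("group")["median_nri"]
        assert med["g1"] > 0 > med["g2"]
        assert (pairwise["p"] < 0.01).all()
        stars = per_group.set_index("group")["nri_vs_zero_stars"]
        assert (stars == "***").all()

    def test_single_group_no_pairwise(self):
        idx = [f"p{i}" for i in range(10)]
        metrics = pd.DataFrame(
            {"nri": np.linspace(-1, 1, 10)}, index=idx
        )
        groups = pd.Series(["only"] * 10, index=idx)
        per_group, pairwise = group_summaries(metrics, groups)
        assert len(per_group) == 1
        assert pairwise.empty

    def test_degenerate_values_flagged(self):
        idx = [f"p{i}" for i in range(6)]
        metrics = pd.DataFrame({"nri": np.zeros(6)}, index=idx)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=idx)
        per_group, _ = group_summaries(metrics, groups)
        assert per_group["tests_skipped"].all()

    def test_stars_tiers(self):
        assert significance_stars(0.005) == "***"
        assert significance_stars(0.03) == "**"
        assert significance_stars(0.07) == "*"
        assert significance_stars(0.5) == ""


class TestAssocTable:
    def test_known_sign_association(self):
        rng = np.random.default_rng(23)
        idx = [f"p{i}" for i in range(80)]
        clim = pd.DataFrame(
            {"bio12": rng.uniform(50, 400, 80),
             "bio1": rng.standard_normal(80)},
            index=idx,
        )
        nri = pd.Series(
            0.01 * clim["bio12"] + 0.2 * rng.standard_normal(80),
            index=idx,
        )
        out = nri_climate_spearman(nri, clim, groups=None)
        row = out[(out["group"] == "all") & (out["factor"] == "bio12")]
        assert row["rho"].iloc[0] > 0.5
        assert row["p"].iloc[0] < 1e-6
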