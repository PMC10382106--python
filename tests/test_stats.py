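"""Exact-test oracles: every exact path is checked against exhaustive
enumeration written independently of the implementation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import perinorm as pn
from perinorm.exceptions import (
    CollinearityError,
    ConfigurationError,
    InsufficientDataError,
)
from perinorm.stats import run_region_family


# -- enumeration oracles ---------------------------------------------------


def signed_rank_exact_oracle(diffs):
    """Two-sided exact signed-rank p by brute force over all sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    signs = np.array(list(itertools.product([0, 1], repeat=n)))
    w_all = signs @ ranks
    lo = np.mean(w_all <= w_obs + 1e-9)
    hi = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def mann_whitney_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p over all label arrangements."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = sum((xi > yj) for xi in x for yj in y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum((xi > yj) for xi in xs for yj in ys))
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


def spearman_perm_oracle(x, y):
    """Exact permutation p for |rho| via scipy on every permutation."""
    rho_obs = abs(sps.spearmanr(x, y).statistic)
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        rho = abs(sps.spearmanr(x, perm).statistic)
        count += rho >= rho_obs - 1e-12
        total += 1
    return count / total


def fisher_rxc_oracle(table):
    """Exact RxC independence p: enumerate all tables with the observed
    margins via brute force over cell values, point-probability rule."""
    arr = np.asarray(table, int)
    rows, cols = arr.sum(1), arr.sum(0)

    def prob(t):
        t = np.asarray(t)
        num = sum(math.lgamma(v + 1) for v in rows) + sum(
            math.lgamma(v + 1) for v in cols
        )
        den = math.lgamma(arr.sum() + 1) + sum(math.lgamma(v + 1) for v in t.flat)
        return math.exp(num - den)

    ranges = [range(min(rows[i], cols[j]) + 1) for i in range(len(rows) - 1)
              for j in range(len(cols) - 1)]
    p_obs = prob(arr)
    total = 0.0
    shape = (len(rows) - 1, len(cols) - 1)
    for cells in itertools.product(*ranges):
        free = np.array(cells).reshape(shape)
        full = np.zeros((len(rows), len(cols)), int)
        full[:-1, :-1] = free
        full[:-1, -1] = rows[:-1] - free.sum(1)
        full[-1, :-1] = cols[:-1] - free.sum(0)
        full[-1, -1] = rows[-1] - full[-1, :-1].sum()
        if (full >= 0).all():
            p = prob(full)
            if p <= p_obs * (1 + 1e-9):
                total += p
    return min(1.0, total)


# -- Wilcoxon --------------------------------------------------------------


class TestWilcoxon:
    def test_three_positive_diffs(self):
        res = pn.wilcoxon_paired([2, 3, 4], [1, 1, 1])
        assert res.statistic == 6.0
        assert res.p_raw == pytest.approx(0.25, abs=1e-12)

    def test_identical_pairs_degenerate(self):
        with pytest.warns(UserWarning):
            res = pn.wilcoxon_paired([1, 2, 3], [1, 2, 3])
        assert res.p_raw == 1.0

    @pytest.mark.parametrize("n,seed", [(8, 0), (12, 1), (20, 2)])
    def test_exact_p_matches_sign_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = pn.wilcoxon_paired(x, y)
        assert res.p_raw == pytest.approx(
            signed_rank_exact_oracle(x - y), abs=1e-12
        )

    def test_exact_p_with_tied_absolute_differences(self):
        x = np.array([3.0, 1.0, 4.0, 2.0, 6.0, 8.0])
        y = np.array([1.0, 3.0, 2.0, 4.0, 1.0, 3.0])  # |d| ties: 2,2,2,2,5,5
        res = pn.wilcoxon_paired(x, y)
        assert res.p_raw == pytest.approx(signed_rank_exact_oracle(x - y), abs=1e-12)

    def test_missing_pairs_dropped(self):
        res = pn.wilcoxon_paired([1, 2, np.nan, 4], [0, 5, 1, np.nan])
        assert res.n_used == 2

    def test_large_n_uses_normal_approximation(self, rng):
        x = rng.normal(0.3, 1, 60)
        y = rng.normal(0.0, 1, 60)
        res = pn.wilcoxon_paired(x, y)
        ref = sps.wilcoxon(x, y, correction=True, method="approx")
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-9)


# -- Kruskal-Wallis --------------------------------------------------------


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = pn.kruskal_wallis([(1, 2), (3, 4), (5, 6)])
        assert res.statistic == pytest.approx(4.571, abs=5e-4)

    def test_all_equal_degenerate(self):
        res = pn.kruskal_wallis([(5, 5), (5, 5, 5)])
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_two_groups_agrees_with_mann_whitney_asymptotically(self, rng):
        x = rng.normal(0, 1, 100)
        y = rng.normal(0.3, 1, 100)
        p_kw = pn.kruskal_wallis([x, y]).p_raw
        p_mw = pn.mann_whitney(x, y).p_raw
        assert abs(p_kw - p_mw) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            pn.kruskal_wallis([(1, 2), ()])


# -- Mann-Whitney ----------------------------------------------------------


class TestMannWhitney:
    def test_separated_pairs(self):
        res = pn.mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples_u_is_half_product(self):
        res = pn.mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_exact_p_matches_arrangement_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = pn.mann_whitney(x, y)
        assert res.p_raw == pytest.approx(mann_whitney_exact_oracle(x, y), abs=1e-12)

    def test_hodges_lehmann_effect(self):
        res = pn.mann_whitney([10, 20], [1, 2])
        assert res.effect == pytest.approx(np.median([9, 8, 19, 18]))


# -- Fisher ----------------------------------------------------------------


class TestFisher:
    def test_two_by_two_balanced_diagonal(self):
        assert pn.fisher_exact([[1, 0], [0, 1]]).p_raw == pytest.approx(1.0)

    def test_two_by_two_perfect_separation(self):
        res = pn.fisher_exact([[5, 0], [0, 5]])
        assert res.p_raw == pytest.approx(2 / math.comb(10, 5), abs=1e-12)

    def test_zero_row_invariance(self):
        full = pn.fisher_exact([[3, 1], [0, 0], [2, 4]]).p_raw
        reduced = pn.fisher_exact([[3, 1], [2, 4]]).p_raw
        assert full == pytest.approx(reduced, abs=1e-12)

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 1, 2], [1, 4, 1]],
            [[2, 2, 2], [2, 0, 4], [1, 3, 1]],
            [[6, 1], [2, 3], [1, 5]],
        ],
    )
    def test_rxc_exact_matches_enumeration_oracle(self, table):
        res = pn.fisher_exact(table)
        assert res.p_raw == pytest.approx(fisher_rxc_oracle(table), abs=1e-12)

    def test_monte_carlo_path_close_to_exact(self):
        table = [[8, 3, 5], [2, 9, 4], [5, 5, 6]]  # N = 47 > 40 -> MC
        res = pn.fisher_exact(table, n_mc=40000, seed=5)
        assert "monte-carlo" in res.note
        exact = pn.fisher_exact(table, monte_carlo_max_n=100).p_raw
        se = np.sqrt(exact * (1 - exact) / 40000)
        assert abs(res.p_raw - exact) < 4 * se + 1e-4

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            pn.fisher_exact([[1, -1], [2, 3]])


# -- Spearman --------------------------------------------------------------


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert pn.spearman(x, [2, 4, 9, 16, 30]).statistic == pytest.approx(1.0)
        assert pn.spearman(x, [-1, -2, -3, -4, -5]).statistic == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_permutation_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        res = pn.spearman(x, y)
        assert res.p_raw == pytest.approx(spearman_perm_oracle(x, y), abs=1e-12)

    def test_t_approximation_for_larger_n(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(0, 2, size=40)
        res = pn.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_degenerate(self):
        with pytest.warns(UserWarning):
            res = pn.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.statistic)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        a = pn.spearman(x, y)
        b = pn.spearman(np.exp(x), 3 * y - 7)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p_raw == pytest.approx(b.p_raw, abs=1e-12)


# -- partial Spearman ------------------------------------------------------


class TestPartialSpearman:
    def test_constant_covariate_reduces_to_plain(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        plain = pn.spearman(x, y)
        partial = pn.partial_spearman(x, y, [np.full(30, 3.0)])
        assert partial.statistic == pytest.approx(plain.statistic, abs=1e-12)
        assert partial.p_raw == pytest.approx(plain.p_raw, abs=1e-12)

    def test_covariate_equal_to_x_rejected(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        with pytest.raises(CollinearityError):
            pn.partial_spearman(x, y, [x.copy()])

    def test_matrix_inversion_oracle(self, rng):
        """Partial rho must equal the normalised off-diagonal of the inverse
        rank-correlation matrix."""
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        y = 0.5 * z + rng.normal(size=50)
        res = pn.partial_spearman(x, y, [z])
        R = np.corrcoef(
            np.vstack([sps.rankdata(x), sps.rankdata(y), sps.rankdata(z)])
        )
        P = np.linalg.inv(R)
        oracle = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert res.statistic == pytest.approx(oracle, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = 0.4 * x - 0.3 * z + rng.normal(size=40)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        res = pn.partial_spearman(x, y, [z])
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p_raw == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_two_covariates_dof(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        covs = [rng.normal(size=25), rng.normal(size=25)]
        res = pn.partial_spearman(x, y, covs)
        # p computed with n-2-k dof
        t = res.statistic * np.sqrt((25 - 4) / (1 - res.statistic**2))
        assert res.p_raw == pytest.approx(2 * sps.t.sf(abs(t), 25 - 4), abs=1e-12)


# -- BH FDR ----------------------------------------------------------------


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert pn.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        adj = pn.bh_fdr([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_missing_values_restored_and_excluded_from_m(self):
        adj = pn.bh_fdr([0.01, np.nan, 0.02, 0.04])
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2, 3]], [0.03, 0.03, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            pn.bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = pn.bh_fdr(ps)
        ps = np.asarray(ps)
        assert np.all(adj >= ps - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


# -- region families -------------------------------------------------------


def _toy_trajectories(rng, n_sub=40, effect_regions=(), beta=0.0, cov=None):
    rows = []
    for i in range(n_sub):
        for region in pn.MODELLED_REGIONS:
            dz = rng.normal()
            if region in effect_regions and cov is not None:
                dz += beta * cov[i]
            rows.append(
                {
                    "subject_id": f"s{i:03d}",
                    "region": region,
                    "z_pre": rng.normal(),
                    "z_post": np.nan,
                    "delta_z": dz,
                }
            )
    df = pd.DataFrame(rows)
    df["z_post"] = df["z_pre"] + df["delta_z"]
    return df


class TestRegionFamily:
    def test_missing_region_reduces_family_size(self, rng):
        traj = _toy_trajectories(rng)
        traj.loc[traj["region"] == "brainstem", "delta_z"] = np.nan
        traj.loc[traj["region"] == "brainstem", "z_pre"] = np.nan
        cov = pd.Series(
            rng.normal(size=40), index=[f"s{i:03d}" for i in range(40)]
        )
        with pytest.warns(UserWarning, match="excluded from FDR"):
            out = run_region_family(traj, "spearman", "f", covariate=cov)
        ok = out.dropna(subset=["p_raw"])
        assert len(ok) == 12
        # BH with m=12 applied by hand
        expect = pn.bh_fdr(ok["p_raw"].to_numpy())
        assert np.allclose(ok["p_fdr"].to_numpy(), expect)

    def test_injected_effect_regions_rank_lowest(self, rng):
        subs = [f"s{i:03d}" for i in range(60)]
        covv = rng.normal(size=60)
        targets = ("brainstem", "cerebellum", "thalamus_r")
        traj = _toy_trajectories(
            rng, n_sub=60, effect_regions=targets, beta=1.5, cov=covv
        )
        cov = pd.Series(covv, index=subs)
        out = run_region_family(traj, "spearman", "f", covariate=cov)
        best3 = set(out.nsmallest(3, "p_raw")["region"])
        assert best3 == set(targets)

    def test_wilcoxon_family_runs_per_region(self, rng):
        traj = _toy_trajectories(rng)
        out = run_region_family(traj, "wilcoxon_pre_post", "f")
        assert len(out) == 13
        assert out["p_raw"].notna().all()
        assert (out["p_fdr"] >= out["p_raw"] - 1e-12).all()
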