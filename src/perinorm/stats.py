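"""Nonparametric association battery with exact small-sample paths.

Implements the tests used for perioperative growth-deviation analysis:
paired Wilcoxon signed-rank (exact for n <= 25 via a distribution recursion
that tolerates mid-ranked ties), Kruskal-Wallis, Mann-Whitney U (exact for
small untied samples), Fisher's exact test (2x2 via the hypergeometric
point-probability rule; RxC by full enumeration when feasible, otherwise a
seeded Monte-Carlo), Spearman and partial Spearman rank correlations
(permutation-exact Spearman p for n <= 9; partial correlations by
rank-transforming then residualising on the covariate ranks), and the
Benjamini-Hochberg step-up FDR adjustment.

All p-values are two-sided; ties are mid-ranked throughout; zero
differences are dropped for the signed-rank test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import CollinearityError, ConfigurationError, InsufficientDataError
from .regions import MODELLED_REGIONS

__all__ = [
    "TestResult",
    "wilcoxon_paired",
    "kruskal_wallis",
    "mann_whitney",
    "fisher_exact",
    "spearman",
    "partial_spearman",
    "bh_fdr",
    "run_region_family",
]


@dataclass
class TestResult:
    """Outcome of one statistical test.

    ``statistic`` is the test's native statistic (W+, H, U, rho...);
    ``effect`` is rho for correlations and a median-difference for group
    comparisons; ``p_fdr`` is filled by family-level adjustment.
    """

    test_name: str
    statistic: float
    effect: float
    p_raw: float
    n_used: int
    family: str | None = None
    p_fdr: float | None = None
    note: str | None = None


def _drop_nan_pairs(*arrays):
    cols = [np.asarray(a, dtype=float) for a in arrays]
    keep = np.all(np.isfinite(np.column_stack(cols)), axis=1)
    return [c[keep] for c in cols]


# -- Wilcoxon signed rank --------------------------------------------------


def _signed_rank_pmf(ranks: np.ndarray):
    """Exact null distribution of W+ for given |difference| ranks.

    Mid-ranks are multiples of 1/2, so doubling keeps sums integral and the
    distribution is built by the standard convolution over sign flips; valid
    with ties because the achievable rank multiset is conditioned on.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    support = np.arange(total + 1) / 2.0
    return support, counts / counts.sum()


def wilcoxon_paired(x, y, exact_max_n: int = 25) -> TestResult:
    """Paired Wilcoxon signed-rank test (two-sided).

    Pairs with a missing value are dropped; zero differences are dropped
    (the classical rule); ties among |differences| are mid-ranked.  The
    exact sign-flip distribution is used for n <= ``exact_max_n`` non-zero
    differences, otherwise a normal approximation with tie correction and
    continuity correction.
    """
    x, y = _drop_nan_pairs(x, y)
    if len(x) != len(y):
        raise ConfigurationError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; degenerate test")
        return TestResult("wilcoxon_paired", 0.0, 0.0, 1.0, 0, note="degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    effect = float(np.median(x - y))
    if n <= exact_max_n:
        support, pmf = _signed_rank_pmf(ranks)
        lo = pmf[support <= w_plus + 1e-9].sum()
        hi = pmf[support >= w_plus - 1e-9].sum()
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        dev = w_plus - mean
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return TestResult("wilcoxon_paired", w_plus, effect, float(p), int(len(x)))


# -- Kruskal-Wallis --------------------------------------------------------


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across two or more groups (tie-corrected).

    The effect size is epsilon-squared, ``(H - k + 1)/(n - k)``, the rank
    analogue of a variance-explained fraction.
    """
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    cleaned = [g[np.isfinite(g)] for g in cleaned]
    if len(cleaned) < 2 or any(len(g) == 0 for g in cleaned):
        raise InsufficientDataError("need >= 2 non-empty groups")
    n = sum(len(g) for g in cleaned)
    k = len(cleaned)
    if all(np.all(g == cleaned[0][0]) for g in cleaned):
        return TestResult("kruskal_wallis", 0.0, 0.0, 1.0, n, note="all equal")
    h, p = sps.kruskal(*cleaned)
    eps2 = (h - k + 1) / (n - k) if n > k else np.nan
    return TestResult("kruskal_wallis", float(h), float(eps2), float(p), n)


# -- Mann-Whitney ----------------------------------------------------------


def mann_whitney(x, y, exact_max_n: int = 8) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact when ``min(n, m) <= exact_max_n`` and there are no ties across the
    pooled sample; otherwise the normal approximation with tie and
    continuity corrections.  The effect is the Hodges-Lehmann shift (median
    of all pairwise differences x - y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= exact_max_n and not has_ties) else (
        "asymptotic"
    )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    hl = float(np.median(np.subtract.outer(x, y)))
    return TestResult(
        "mann_whitney", float(res.statistic), hl, float(res.pvalue), len(x) + len(y)
    )


# -- Fisher exact ----------------------------------------------------------


def _iter_tables(row_sums, col_sums):
    """All non-negative integer tables with the given margins."""

    def rec(rows_left, cols_left):
        if len(rows_left) == 1:
            yield [list(cols_left)]
            return
        r = rows_left[0]

        def cells(remaining, idx, acc):
            if idx == len(cols_left) - 1:
                last = remaining
                if 0 <= last <= cols_left[idx]:
                    yield acc + [last]
                return
            hi = min(remaining, cols_left[idx])
            for v in range(hi + 1):
                yield from cells(remaining - v, idx + 1, acc + [v])

        for first in cells(r, 0, []):
            rest_cols = tuple(c - f for c, f in zip(cols_left, first))
            for tail in rec(rows_left[1:], rest_cols):
                yield [first] + tail

    yield from rec(tuple(row_sums), tuple(col_sums))


def _table_log_prob(table, log_fact):
    arr = np.asarray(table)
    rs, cs = arr.sum(axis=1), arr.sum(axis=0)
    return (
        log_fact[rs].sum()
        + log_fact[cs].sum()
        - log_fact[arr.sum()]
        - log_fact[arr].sum()
    )


def fisher_exact(
    table, monte_carlo_max_n: int = 40, n_mc: int = 20000, seed: int = 0
) -> TestResult:
    """Fisher's exact test of independence for an RxC contingency table.

    2x2 tables use the hypergeometric point-probability rule.  Larger
    tables are tested exactly by enumerating every table with the observed
    margins when the grand total is <= ``monte_carlo_max_n``; otherwise a
    seeded Monte-Carlo permutation of the margins is used and the standard
    error of the estimate is recorded in ``note``.  All-zero rows or
    columns are removed first (they cannot affect the test).
    """
    arr = np.asarray(table, dtype=int)
    if np.any(arr < 0):
        raise ConfigurationError("contingency counts must be non-negative")
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.size == 0 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InsufficientDataError("table degenerate after removing empty margins")
    n_total = int(arr.sum())
    if arr.shape == (2, 2):
        odds, p = sps.fisher_exact(arr, alternative="two-sided")
        return TestResult("fisher_exact", float(odds), float(odds), float(p), n_total)
    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n_total + 1)))])
    obs_lp = _table_log_prob(arr, log_fact)
    row_sums, col_sums = arr.sum(axis=1), arr.sum(axis=0)
    if n_total <= monte_carlo_max_n:
        p = 0.0
        for tab in _iter_tables(row_sums, col_sums):
            lp = _table_log_prob(tab, log_fact)
            if lp <= obs_lp + 1e-9:
                p += np.exp(lp)
        p = min(1.0, p)
        note = "exact enumeration"
    else:
        rng = np.random.default_rng(seed)
        row_labels = np.repeat(np.arange(len(row_sums)), row_sums)
        col_labels = np.repeat(np.arange(len(col_sums)), col_sums)
        hits = 0
        for _ in range(n_mc):
            perm = rng.permutation(col_labels)
            sim = np.zeros_like(arr)
            np.add.at(sim, (row_labels, perm), 1)
            if _table_log_prob(sim, log_fact) <= obs_lp + 1e-9:
                hits += 1
        p = (hits + 1) / (n_mc + 1)
        note = f"monte-carlo ({n_mc} draws), se={np.sqrt(p * (1 - p) / n_mc):.2g}"
    return TestResult("fisher_exact", np.nan, np.nan, float(p), n_total, note=note)


# -- Spearman and partial Spearman ----------------------------------------


def _spearman_rho(xr, yr):
    xr = xr - xr.mean()
    yr = yr - yr.mean()
    denom = np.sqrt((xr**2).sum() * (yr**2).sum())
    if denom == 0:
        return np.nan
    return float((xr * yr).sum() / denom)


def _t_pvalue(rho, df):
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt(df / (1 - rho**2))
    return float(2 * sps.t.sf(abs(t), df))


def spearman(x, y, exact_max_n: int = 9) -> TestResult:
    """Spearman rank correlation with mid-ranked ties (two-sided).

    Exact permutation p for n <= ``exact_max_n``; otherwise the
    t-approximation with n - 2 degrees of freedom.
    """
    x, y = _drop_nan_pairs(x, y)
    n = len(x)
    if n < 4:
        raise InsufficientDataError("need pairwise-complete n >= 4")
    xr, yr = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        warnings.warn("zero rank variance; Spearman rho undefined")
        return TestResult("spearman", np.nan, np.nan, np.nan, n, note="degenerate")
    rho = _spearman_rho(xr, yr)
    if n <= exact_max_n:
        xc = xr - xr.mean()
        yc = yr - yr.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        obs = abs(xc @ yc)
        perms = np.array(list(itertools.permutations(range(n))))
        stats_all = np.abs(yc[perms] @ xc)
        p = float(np.mean(stats_all >= obs - 1e-12 * denom))
    else:
        p = _t_pvalue(rho, n - 2)
    return TestResult("spearman", rho, rho, p, n)


def _residualise_ranks(target, covariate_ranks):
    design = np.column_stack([np.ones(len(target))] + covariate_ranks)
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    return target - design @ beta


def partial_spearman(x, y, covariates) -> TestResult:
    """Partial Spearman correlation of x and y given one or more covariates.

    All variables are mid-ranked, the covariate ranks are projected out of
    both x and y ranks by least squares (with intercept), and the
    correlation of the residuals is tested with n - 2 - k degrees of
    freedom.  Constant covariates are absorbed by the intercept and do not
    count toward k, so with no informative covariates this reduces exactly
    to the plain Spearman correlation.
    """
    covariates = [np.asarray(c, dtype=float) for c in covariates]
    arrays = _drop_nan_pairs(x, y, *covariates)
    x, y, covs = arrays[0], arrays[1], arrays[2:]
    kept = [c for c in covs if np.ptp(c) > 0]
    k = len(kept)
    n = len(x)
    if n < k + 4:
        raise InsufficientDataError(f"need pairwise-complete n >= {k + 4}")
    xr, yr = sps.rankdata(x), sps.rankdata(y)
    cr = [sps.rankdata(c) for c in kept]
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        warnings.warn("zero rank variance; partial Spearman undefined")
        return TestResult(
            "partial_spearman", np.nan, np.nan, np.nan, n, note="degenerate"
        )
    if k:
        design = np.column_stack([np.ones(n)] + cr)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise CollinearityError(
                "rank-transformed covariates are collinear with each other "
                "or constant-degenerate"
            )
    rx = _residualise_ranks(xr, cr)
    ry = _residualise_ranks(yr, cr)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise CollinearityError(
            "a covariate's ranks coincide with the variable of interest"
        )
    rho = _spearman_rho(rx, ry)
    p = _t_pvalue(rho, n - 2 - k)
    return TestResult("partial_spearman", rho, rho, p, n)


# -- FDR -------------------------------------------------------------------


def bh_fdr(p_values, family: str | None = None):
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries are excluded from the family size m and restored as
    missing in their original positions.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    adj = np.full_like(p, np.nan)
    if finite.sum():
        adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return adj


# -- region-family driver --------------------------------------------------

_SCALAR_TESTS = {
    "spearman": lambda v, cov, extra: spearman(cov, v),
    "partial_spearman": lambda v, cov, extra: partial_spearman(cov, v, extra),
    "mann_whitney": lambda v, cov, extra: mann_whitney(
        v[np.asarray(cov) == 0], v[np.asarray(cov) == 1]
    ),
}


def run_region_family(
    trajectories: pd.DataFrame,
    test: str,
    family: str,
    covariate=None,
    adjust_for=None,
    groups=None,
    value: str = "delta_z",
    regions=None,
    min_n: int = 4,
) -> pd.DataFrame:
    """Apply one test per region and BH-adjust across the family.

    ``trajectories`` is the long subject x region table.  ``covariate`` /
    ``adjust_for`` / ``groups`` are per-subject Series aligned by
    ``subject_id``.  Regions with fewer than ``min_n`` usable subjects are
    reported with missing p-values and excluded from the family size m.
    """
    regions = list(MODELLED_REGIONS if regions is None else regions)
    rows = []
    for region in regions:
        sub = trajectories[trajectories["region"] == region]
        res = None
        try:
            if test == "wilcoxon_pre_post":
                pair = sub.dropna(subset=["z_pre", "z_post"])
                if len(pair) < min_n:
                    raise InsufficientDataError(f"{region}: n={len(pair)}")
                res = wilcoxon_paired(pair["z_post"], pair["z_pre"])
            elif test == "kruskal":
                merged = sub.dropna(subset=[value]).copy()
                merged["g"] = merged["subject_id"].map(groups)
                merged = merged.dropna(subset=["g"])
                if len(merged) < min_n:
                    raise InsufficientDataError(f"{region}: n={len(merged)}")
                res = kruskal_wallis(
                    [g[value].to_numpy() for _, g in merged.groupby("g")]
                )
            elif test in _SCALAR_TESTS:
                merged = sub.dropna(subset=[value]).copy()
                merged["cov"] = merged["subject_id"].map(covariate)
                extras = []
                if adjust_for is not None:
                    adjust_list = (
                        adjust_for if isinstance(adjust_for, (list, tuple)) else [adjust_for]
                    )
                    for j, a in enumerate(adjust_list):
                        merged[f"adj{j}"] = merged["subject_id"].map(a)
                        extras.append(f"adj{j}")
                merged = merged.dropna(subset=["cov"] + extras)
                if len(merged) < min_n:
                    raise InsufficientDataError(f"{region}: n={len(merged)}")
                res = _SCALAR_TESTS[test](
                    merged[value].to_numpy(),
                    merged["cov"].to_numpy(dtype=float),
                    [merged[e].to_numpy(dtype=float) for e in extras],
                )
            else:
                raise ConfigurationError(f"unknown family test: {test}")
        except InsufficientDataError as exc:
            warnings.warn(f"family {family!r}: {exc}; region excluded from FDR")
            rows.append(
                {
                    "region": region,
                    "test_name": test,
                    "family": family,
                    "statistic": np.nan,
                    "effect": np.nan,
                    "p_raw": np.nan,
                    "n_used": 0,
                    "note": str(exc),
                }
            )
            continue
        rows.append(
            {
                "region": region,
                "test_name": res.test_name,
                "family": family,
                "statistic": res.statistic,
                "effect": res.effect,
                "p_raw": res.p_raw,
                "n_used": res.n_used,
                "note": res.note,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy(), family=family)
    return out
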