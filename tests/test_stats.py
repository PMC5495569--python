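"""Statistics battery: hand-computed fixtures, enumeration oracles, calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fearext import stats

# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def brute_force_mw_p(x, y):
    """Exhaustive two-sided exact p over all rank assignments (oracle)."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = min(ranks[:n1].sum() - n1 * (n1 + 1) / 2, ranks[n1:].sum() - n2 * (n2 + 1) / 2)
    n = n1 + n2
    ux_all = np.array([sum(c) - n1 * (n1 + 1) / 2
                       for c in itertools.combinations(range(1, n + 1), n1)])
    return min(1.0, 2.0 * np.mean(ux_all <= u_obs))


def test_mw_separated_samples_exact():
    res = stats.mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.100, abs=1e-12)
    assert res.extra["method"] == "exact"


def test_mw_identical_multisets_p_near_one():
    res = stats.mann_whitney_u([1, 2, 3, 3], [1, 2, 3, 3])
    assert res.p_value >= 0.99


def test_mw_empty_sample_rejected():
    with pytest.raises(ValueError):
        stats.mann_whitney_u([], [1.0])


def test_mw_exact_matches_brute_force_small_samples(rng):
    for n1, n2 in [(2, 3), (3, 3), (4, 5), (5, 5)]:
        for _ in range(5):
            x = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
            y = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), x)
            res = stats.mann_whitney_u(x, y)
            assert res.p_value == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)


def test_mw_exact_agrees_with_scipy_exact(rng):
    for _ in range(10):
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        mine = stats.mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_mw_exact_and_asymptotic_agree(rng):
    """Normal approximation within 0.02 of enumeration at n = 8, 8."""
    for _ in range(50):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        exact = stats.mann_whitney_u(x, y, mode="exact")
        approx = stats.mann_whitney_u(x, y, mode="asymptotic")
        assert abs(exact.p_value - approx.p_value) <= 0.02


# ---------------------------------------------------------------------------
# Kruskal-Wallis / Friedman
# ---------------------------------------------------------------------------

def test_kw_hand_fixture():
    res = stats.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert res.statistic == pytest.approx(4.571, abs=5e-4)
    assert res.df == 2


def test_kw_all_identical_h_zero():
    assert stats.kruskal_wallis([[5, 5], [5, 5], [5, 5]]).statistic == 0.0


def test_kw_rank_invariance_under_monotone_transform(rng):
    groups = [rng.normal(size=5) for _ in range(3)]
    a = stats.kruskal_wallis(groups)
    b = stats.kruskal_wallis([np.exp(g) for g in groups])
    assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


def test_kw_two_groups_rejected():
    with pytest.raises(ValueError):
        stats.kruskal_wallis([[1, 2], [3, 4]])


def test_friedman_ordered_blocks():
    res = stats.friedman([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert res.statistic == pytest.approx(6.0, abs=1e-12)
    assert res.df == 2


def test_friedman_all_tied_within_blocks():
    assert stats.friedman([[2, 2, 2], [7, 7, 7]]).statistic == 0.0


def test_friedman_block_permutation_invariance(rng):
    m = rng.normal(size=(6, 4))
    a = stats.friedman(m)
    b = stats.friedman(m[rng.permutation(6)])
    assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


def test_friedman_matches_scipy_on_tie_free_data(rng):
    m = rng.normal(size=(8, 4))
    mine = stats.friedman(m)
    ref = sps.friedmanchisquare(*m.T)
    assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)


# ---------------------------------------------------------------------------
# Dunn + BKY
# ---------------------------------------------------------------------------

def bky_two_stage_oracle(pvals, q):
    """Literal two-stage linear step-up: first pass at q/(1+q), re-estimate m0,
    second pass at q * m / m0."""
    p = np.asarray(pvals, dtype=float)
    m = p.size

    def step_up(p, alpha):
        order = np.argsort(p)
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = np.flatnonzero(p[order] <= thresh)
        k = passed.max() + 1 if passed.size else 0
        rej = np.zeros(m, bool)
        rej[order[:k]] = True
        return rej

    q1 = q / (1.0 + q)
    r1 = step_up(p, q1).sum()
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    m0 = m - r1
    return step_up(p, q1 * m / m0)


def test_dunn_bky_extreme_pvectors():
    sep = [list(np.arange(8) / 10 + off) for off in (0.0, 10.0, 20.0)]
    strong = stats.dunn_bky(sep)
    assert len(strong.significant_pairs()) == 3
    null = stats.dunn_bky([[1, 5, 9], [2, 4, 8], [1.5, 4.5, 8.5]])
    assert len(null.significant_pairs()) == 0


def test_bky_decisions_match_literal_two_stage(rng):
    from statsmodels.stats.multitest import multipletests
    for _ in range(200):
        m = rng.integers(3, 12)
        p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
        ours = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
        assert (ours == bky_two_stage_oracle(p, 0.05)).all()


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(1e-6, 1.0), min_size=3, max_size=10))
def test_bky_between_bonferroni_and_unadjusted(pvals):
    from statsmodels.stats.multitest import multipletests
    p = np.array(pvals)
    bky = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
    bonf = p <= 0.05 / p.size
    raw = p <= 0.05
    assert (bky >= bonf).all() and (bky <= raw).all()


def test_dunn_repeated_design_matches_rank_formula():
    m = np.array([[1.0, 2.0, 3.0]] * 6)
    table = stats.dunn_bky(m, design="repeated", labels=["a", "b", "c"])
    # perfectly ordered blocks: mean-rank difference 2 between extremes
    extreme = [c for c in table.comparisons if c.pair == ("a", "c")][0]
    assert extreme.statistic == pytest.approx(
        -2.0 / np.sqrt(3 * 4 / (6.0 * 6)), rel=1e-12)


# ---------------------------------------------------------------------------
# RM-ANOVA + Newman-Keuls
# ---------------------------------------------------------------------------

def test_rm_anova_hand_fixture():
    res = stats.rm_anova1([[1, 2], [3, 3]])
    assert res.statistic == pytest.approx(1.0, abs=1e-12)
    assert res.df == (1, 1)


@pytest.mark.parametrize("n,k,df", [(56, 5, (4, 220)), (16, 5, (4, 60))])
def test_rm_anova_design_degrees_of_freedom(n, k, df, rng):
    res = stats.rm_anova1(rng.normal(size=(n, k)))
    assert res.df == df


def test_rm_anova_subject_effect_removed(rng):
    m = rng.normal(size=(10, 4))
    shifted = m + rng.normal(size=(10, 1)) * 100.0
    assert stats.rm_anova1(m).statistic == pytest.approx(
        stats.rm_anova1(shifted).statistic, rel=1e-8)


def test_rm_anova_zero_error_variance_rejected():
    with pytest.raises(ValueError):
        stats.rm_anova1([[1, 2], [2, 3]])   # error SS exactly zero


def test_newman_keuls_equal_means_nothing_significant():
    table = stats.newman_keuls([5.0, 5.0, 5.0], ms_error=1.0, df_error=20, n=8)
    assert table.significant_pairs() == []


def test_newman_keuls_extreme_mean_all_pairs_significant():
    table = stats.newman_keuls([0.0, 0.1, 100.0], ms_error=1.0, df_error=20, n=8,
                               labels=["a", "b", "c"])
    sig = table.significant_pairs()
    assert ("a", "c") in sig and ("b", "c") in sig


def test_newman_keuls_matches_direct_q_lookup():
    """Three-group decisions agree with direct studentized-range lookups."""
    means = [0.0, 0.8, 2.0]
    ms_error, df_error, n = 1.0, 27, 10
    table = stats.newman_keuls(means, ms_error, df_error, n, labels=["a", "b", "c"])
    se = np.sqrt(ms_error / n)
    q3 = sps.studentized_range.ppf(0.95, 3, df_error)
    q2 = sps.studentized_range.ppf(0.95, 2, df_error)
    expect_ac = (means[2] - means[0]) / se > q3
    decisions = {c.pair: c.significant for c in table.comparisons}
    assert decisions[("a", "c")] == expect_ac
    if expect_ac:
        assert decisions[("a", "b")] == ((means[1] - means[0]) / se > q2)
        assert decisions[("b", "c")] == ((means[2] - means[1]) / se > q2)


# ---------------------------------------------------------------------------
# KS and the confidence bound
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,y,d", [
    ([1, 2, 3], [1, 2, 3], 0.0),
    ([1, 2, 3], [4, 5, 6], 1.0),
    ([1, 3], [2, 4], 0.5),
])
def test_ks_statistic(x, y, d):
    assert stats.ks_two_sample(x, y).statistic == pytest.approx(d, abs=1e-12)


def test_upper_conf_bound_fixture_and_monotonicity():
    assert stats.upper_conf_bound([0, 0, 100]) == pytest.approx(364.2, abs=0.05)
    assert stats.upper_conf_bound([7.0, 7.0, 7.0]) == pytest.approx(7.0)
    v = [3.0, 9.0, 1.0, 7.0]
    assert (stats.upper_conf_bound(v, 0.99) > stats.upper_conf_bound(v, 0.95)
            > stats.upper_conf_bound(v, 0.90))


# ---------------------------------------------------------------------------
# Type-I calibration under the null
# ---------------------------------------------------------------------------

def test_type_one_error_calibration():
    """Empirical size of each test at alpha = 0.05 stays in [0.03, 0.07]."""
    rng = np.random.default_rng(7)
    n_rep = 10_000

    rej = 0
    for _ in range(n_rep):
        if stats.mann_whitney_u(rng.normal(size=8), rng.normal(size=8)).p_value < 0.05:
            rej += 1
    assert 0.03 <= rej / n_rep <= 0.07

    rej = 0
    for _ in range(n_rep):
        groups = rng.normal(size=(3, 10))
        if stats.kruskal_wallis(list(groups)).p_value < 0.05:
            rej += 1
    assert 0.03 <= rej / n_rep <= 0.07

    rej = 0
    for _ in range(n_rep):
        if stats.friedman(rng.normal(size=(12, 4))).p_value < 0.05:
            rej += 1
    assert 0.03 <= rej / n_rep <= 0.07
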