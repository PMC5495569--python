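"""Nonparametric statistics battery with exact small-sample behaviour.

The tests collected here are the ones a behavioural-electrophysiology study
typically leans on: Mann-Whitney U for two groups, Kruskal-Wallis H for three
or more independent groups, Friedman's chi-square for repeated measures,
Dunn's pairwise post-hoc comparisons gated by the Benjamini-Krieger-Yekutieli
(BKY) two-stage FDR procedure, classical repeated-measures one-way ANOVA with
Newman-Keuls post-tests, the two-sample Kolmogorov-Smirnov test for cumulative
distributions, and the upper bound of a t confidence interval (used to split
rats into successful / poor extinction-recall groups).

Conventions: all p-values are two-sided.  The Mann-Whitney statistic is
``U = min(U_x, U_y)`` with midranks for ties; the p-value is computed by exact
enumeration of the null U distribution whenever both samples are small
(``max(n) <= 10``) and tie-free, otherwise by a normal approximation with tie
and continuity corrections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "PosthocTable",
    "mann_whitney_u",
    "kruskal_wallis",
    "friedman",
    "dunn_bky",
    "rm_anova1",
    "newman_keuls",
    "ks_two_sample",
    "upper_conf_bound",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    name: str
    statistic: float
    df: tuple | int | None
    p_value: float
    n: tuple
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class PosthocComparison:
    pair: tuple
    statistic: float
    p_raw: float
    significant: bool


@dataclass(frozen=True)
class PosthocTable:
    """Pairwise post-hoc decisions; ``significant`` flags are FDR/stepwise adjusted."""

    method: str
    level: float
    comparisons: tuple

    def significant_pairs(self) -> list:
        return [c.pair for c in self.comparisons if c.significant]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple:
    """Null distribution of U_x: counts[u] = #rank assignments with U_x = u.

    Classic recursion N(n1, n2, u) = N(n1-1, n2, u-n2) + N(n1, n2-1, u);
    the counts are the coefficients of the Gaussian binomial [n1+n2, n1]_q.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_counts(n1 - 1, n2)
    b = _u_counts(n1, n2 - 1)
    out = []
    for u in range(n1 * n2 + 1):
        s = 0
        if 0 <= u - n2 < len(a):
            s += a[u - n2]
        if u < len(b):
            s += b[u]
        out.append(s)
    return tuple(out)


def _exact_p_two_sided(u: float, n1: int, n2: int) -> float:
    counts = _u_counts(n1, n2)
    total = sum(counts)
    u_floor = int(np.floor(u + 1e-12))
    lower = sum(counts[: u_floor + 1])
    return float(min(1.0, 2.0 * lower / total))


def mann_whitney_u(x: Sequence[float], y: Sequence[float], mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode`` is one of ``auto`` (exact when both n <= 10 and tie-free),
    ``exact`` or ``asymptotic``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u_x = r1 - n1 * (n1 + 1) / 2.0
    u_y = n1 * n2 - u_x
    u = min(u_x, u_y)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and max(n1, n2) <= 10 and not has_ties)
    if use_exact and has_ties:
        raise ValueError("exact enumeration requires tie-free samples")

    if use_exact:
        p = _exact_p_two_sided(u, n1, n2)
        method = "exact"
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:  # all observations identical
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / np.sqrt(var)
            z = max(z, 0.0)
            p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        method = "asymptotic"
    return TestResult("mann_whitney_u", float(u), None, p, (n1, n2),
                      {"U_x": float(u_x), "U_y": float(u_y), "method": method,
                       "ties": has_ties})


# ---------------------------------------------------------------------------
# Kruskal-Wallis / Friedman
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected), p from chi-square with k-1 df."""
    if len(groups) < 3:
        raise ValueError("kruskal_wallis requires >= 3 groups; use mann_whitney_u for 2")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be non-empty")
    k = len(arrs)
    if np.unique(np.concatenate(arrs)).size == 1:
        # all observations tied: no rank variation, H = 0 by convention
        return TestResult("kruskal_wallis", 0.0, k - 1, 1.0,
                          tuple(a.size for a in arrs))
    h, p = sps.kruskal(*arrs)
    return TestResult("kruskal_wallis", float(h), k - 1, float(p),
                      tuple(a.size for a in arrs))


def friedman(matrix: np.ndarray) -> TestResult:
    """Friedman test on a blocks x treatments matrix (no missing cells).

    chi^2_F = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1), with midranks within
    each block; p from the chi-square distribution with k-1 df.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D blocks x treatments matrix")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    if n < 2 or k < 3:
        raise ValueError("need >= 2 blocks and >= 3 treatments")
    ranks = sps.rankdata(m, axis=1)
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, k - 1))
    return TestResult("friedman", float(chi2), k - 1, p, (n, k),
                      {"rank_sums": rj.tolist()})


# ---------------------------------------------------------------------------
# Dunn's post-hoc with BKY two-stage FDR
# ---------------------------------------------------------------------------

def _dunn_independent(groups) -> tuple[list, list, list, tuple]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    sizes = [a.size for a in arrs]
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, start = [], 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    pairs, zs, ps = [], [], []
    for i, j in itertools.combinations(range(len(arrs)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        pairs.append((i, j))
        zs.append(float(z))
        ps.append(float(min(1.0, 2.0 * sps.norm.sf(abs(z)))))
    return pairs, zs, ps, tuple(sizes)


def _dunn_repeated(matrix) -> tuple[list, list, list, tuple]:
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    ranks = sps.rankdata(m, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs, zs, ps = [], [], []
    for i, j in itertools.combinations(range(k), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / se
        pairs.append((i, j))
        zs.append(float(z))
        ps.append(float(min(1.0, 2.0 * sps.norm.sf(abs(z)))))
    return pairs, zs, ps, (n, k)


def dunn_bky(data, design: str = "independent", q: float = 0.05,
             labels: Sequence[str] | None = None) -> PosthocTable:
    """Dunn's pairwise rank comparisons with BKY two-stage FDR decisions.

    ``data`` is a list of groups when ``design='independent'`` (Kruskal-Wallis
    follow-up) or a blocks x treatments matrix when ``design='repeated'``
    (Friedman follow-up).  Decisions use the Benjamini-Krieger-Yekutieli
    two-stage linear step-up procedure at level ``q``.
    """
    if design == "independent":
        if len(data) < 2:
            raise ValueError("need at least 2 groups")
        pairs, zs, ps, _ = _dunn_independent(data)
    elif design == "repeated":
        m = np.asarray(data, dtype=float)
        if m.ndim != 2 or m.shape[1] < 2:
            raise ValueError("need a blocks x treatments matrix with >= 2 treatments")
        pairs, zs, ps, _ = _dunn_repeated(m)
    else:
        raise ValueError(f"unknown design {design!r}")
    reject = multipletests(ps, alpha=q, method="fdr_tsbky")[0]
    if labels is not None:
        pairs = [(labels[i], labels[j]) for i, j in pairs]
    comps = tuple(PosthocComparison(p_, z_, praw_, bool(r_))
                  for p_, z_, praw_, r_ in zip(pairs, zs, ps, reject))
    return PosthocTable("dunn_bky_" + design, q, comps)


# ---------------------------------------------------------------------------
# Repeated-measures one-way ANOVA + Newman-Keuls
# ---------------------------------------------------------------------------

def rm_anova1(matrix: np.ndarray) -> TestResult:
    """Repeated-measures one-way ANOVA on a subjects x conditions matrix.

    F = MS_conditions / MS_error with df = (k-1, (k-1)(n-1)); the subject
    effect is removed from the error term.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D subjects x conditions matrix")
    if np.isnan(m).any():
        raise ValueError("matrix must be complete")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = m.mean()
    ss_cond = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((m - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        raise ValueError("zero within-subject error variance; F undefined")
    f = (ss_cond / df1) / ms_err
    p = float(sps.f.sf(f, df1, df2))
    return TestResult("rm_anova1", float(f), (df1, df2), p, (n, k),
                      {"ms_error": float(ms_err), "ss_conditions": float(ss_cond)})


def newman_keuls(means: Sequence[float], ms_error: float, df_error: int,
                 n: int, alpha: float = 0.05,
                 labels: Sequence[str] | None = None) -> PosthocTable:
    """Stepwise Newman-Keuls comparisons of condition means.

    Means are ordered; each pair is tested with the studentized range at a
    critical value depending on the stretch (number of means spanned), and a
    pair nested inside a non-significant stretch inherits non-significance.
    """
    means = np.asarray(means, dtype=float)
    k = means.size
    if n < 2:
        raise ValueError("need n >= 2 observations per mean")
    if k < 2:
        raise ValueError("need >= 2 means")
    order = np.argsort(means)
    se = np.sqrt(ms_error / n)
    sig = {}

    def test_range(lo: int, hi: int):
        # lo/hi index into the sorted order
        if (lo, hi) in sig:
            return
        stretch = hi - lo + 1
        if se == 0:
            significant = means[order[hi]] != means[order[lo]]
            qstat = np.inf if significant else 0.0
        else:
            qstat = (means[order[hi]] - means[order[lo]]) / se
            qcrit = sps.studentized_range.ppf(1 - alpha, stretch, df_error)
            significant = bool(qstat > qcrit)
        sig[(lo, hi)] = (float(qstat), significant)
        if significant:
            if hi - lo >= 1:
                if hi - 1 > lo:
                    test_range(lo, hi - 1)
                if hi > lo + 1:
                    test_range(lo + 1, hi)
        else:
            for a in range(lo, hi + 1):
                for b in range(a + 1, hi + 1):
                    sig.setdefault((a, b), (float((means[order[b]] - means[order[a]]) / se) if se > 0 else 0.0,
                                            False))

    test_range(0, k - 1)
    # ensure all adjacent-and-wider pairs are present (test any untouched)
    for lo in range(k):
        for hi in range(lo + 1, k):
            if (lo, hi) not in sig:
                test_range(lo, hi)
    comps = []
    for (lo, hi), (qstat, significant) in sorted(sig.items()):
        i, j = int(order[lo]), int(order[hi])
        pair = (labels[i], labels[j]) if labels is not None else (i, j)
        # raw p for the observed q at its stretch (reported, decisions are stepwise)
        stretch = hi - lo + 1
        p_raw = float(sps.studentized_range.sf(qstat, stretch, df_error)) if np.isfinite(qstat) else 0.0
        comps.append(PosthocComparison(pair, qstat, p_raw, significant))
    return PosthocTable("newman_keuls", alpha, tuple(comps))


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov and the CI bound
# ---------------------------------------------------------------------------

def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample KS test: D = sup |F_x - F_y|, asymptotic two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult("ks_two_sample", float(res.statistic), None,
                      float(res.pvalue), (x.size, y.size))


def upper_conf_bound(values: Sequence[float], level: float = 0.99) -> float:
    """Upper bound of the two-sided t confidence interval for the mean."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need n >= 2 values for a confidence bound")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    t = sps.t.ppf((1 + level) / 2.0, n - 1)
    return float(v.mean() + t * v.std(ddof=1) / np.sqrt(n))
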