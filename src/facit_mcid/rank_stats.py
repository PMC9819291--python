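"""Nonparametric tests and correlations used throughout the fatigue analyses.

Thin, explicitly-configured wrappers around :mod:`scipy.stats`:

* :func:`spearman_rho` -- Spearman rank correlation (mid-ranks for ties),
  t-approximation p-value by default, exact permutation p for n <= 8;
* :func:`mann_whitney_u` -- two-sample rank-sum test, tie-corrected normal
  approximation without continuity correction, exact null distribution for
  small samples without ties;
* :func:`wilcoxon_signed_rank` -- paired signed-rank test, zero differences
  dropped by default (Wilcoxon's rule) or kept (Pratt);
* :func:`chi_square` -- Pearson chi-square on an r x k count table;
* :func:`compare_groups` -- a Table-3-shaped batch of two-group comparisons.

All results come back as a :class:`TestResult` carrying the statistic, the
two-sided p-value, the sample sizes and a method tag naming the p-value
route actually taken.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "DegenerateDataError",
    "spearman_rho",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "chi_square",
    "compare_groups",
]


class DegenerateDataError(ValueError):
    """The requested statistic is undefined on this input (e.g. a constant
    vector for a rank correlation, or all-zero paired differences)."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


_EXACT_SPEARMAN_N = 8
_EXACT_RANKSUM_N = 12
_EXACT_SIGNRANK_N = 12


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p by full enumeration of rank permutations."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]                       # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum(axis=1))
    rho_all = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rho_all) >= abs(rho_obs) - 1e-12))


def spearman_rho(x, y, p_mode: str = "auto") -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    ``p_mode`` is ``"auto"`` (exact permutation for n <= 8, t-approximation
    otherwise), ``"exact"`` or ``"approx"``.

    Raises :class:`DegenerateDataError` when either vector is constant
    (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("rank correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    exact = p_mode == "exact" or (p_mode == "auto" and n <= _EXACT_SPEARMAN_N)
    if exact:
        if n > 10:
            raise ValueError("exact Spearman p only feasible for n <= 10")
        p = _spearman_exact_p(rx, ry, rho)
        method = "spearman-exact"
    else:
        # t approximation on n-2 df; rho = +/-1 gives p -> 0
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        method = "spearman-t"
    return TestResult(rho, min(p, 1.0), (n,), method)


def mann_whitney_u(a, b, method: str = "auto") -> TestResult:
    """Two-sample Mann-Whitney U test (two-sided).

    The statistic is U for the first sample: the number of (a, b) pairs with
    a > b, ties counted half.  ``method`` is ``"auto"`` (exact null
    distribution when ``n_a + n_b <= 12`` and there are no ties, otherwise
    tie-corrected normal approximation without continuity correction),
    ``"exact"`` or ``"asymptotic"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = method == "exact" or (
        method == "auto" and a.size + b.size <= _EXACT_RANKSUM_N and not has_ties
    )
    if use_exact and has_ties:
        use_exact = False  # exact null distribution assumes no ties
    if np.ptp(pooled) == 0:
        # identical constant samples: U at its null mean, no evidence
        return TestResult(a.size * b.size / 2.0, 1.0, (a.size, b.size),
                          "mwu-degenerate")
    if use_exact:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        tag = "mwu-exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        tag = "mwu-normal"
    return TestResult(float(res.statistic), float(res.pvalue),
                      (a.size, b.size), tag)


def wilcoxon_signed_rank(before, after, zero_method: str = "wilcox",
                         method: str = "auto") -> TestResult:
    """Paired Wilcoxon signed-rank test (two-sided) on ``after - before``.

    The statistic is W+, the sum of ranks of the positive differences
    (ranks taken over |differences|).  ``zero_method`` is ``"wilcox"``
    (drop zero differences, the default) or ``"pratt"``.  The exact null
    distribution is used for <= 12 nonzero untied pairs, otherwise the
    tie-corrected normal approximation without continuity correction.

    Raises :class:`DegenerateDataError` when every difference is zero.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must be paired vectors of equal length")
    d = after - before
    nz = d[d != 0]
    if nz.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    # W+ with the chosen zero handling
    if zero_method == "wilcox":
        ranks = stats.rankdata(np.abs(nz))
        w_plus = float(ranks[nz > 0].sum())
    else:
        ranks = stats.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
    no_ties = len(np.unique(np.abs(nz))) == nz.size
    use_exact = method == "exact" or (
        method == "auto" and nz.size <= _EXACT_SIGNRANK_N and no_ties
        and zero_method == "wilcox"
    )
    if use_exact and not no_ties:
        use_exact = False
    scipy_method = "exact" if use_exact else "approx"
    res = stats.wilcoxon(d, zero_method=zero_method, correction=False,
                         alternative="two-sided", method=scipy_method)
    tag = "signrank-exact" if use_exact else "signrank-normal"
    return TestResult(w_plus, float(res.pvalue), (d.size,), tag)


def chi_square(table) -> TestResult:
    """Pearson chi-square test of independence on an r x k count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(table < 0) or np.any(table != np.floor(table)):
        raise ValueError("table must contain nonnegative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero row/column margin")
    res = stats.chi2_contingency(table, correction=False)
    n = int(table.sum())
    return TestResult(float(res.statistic), float(res.pvalue), (n,),
                      f"chi2-df{int(res.dof)}")


def compare_groups(frame: pd.DataFrame, group: str,
                   variables: list[str]) -> pd.DataFrame:
    """Two-group comparison table (one row per variable).

    Continuous variables are compared with the Mann-Whitney U test and
    summarized as median (Q1; Q3) per group; binary/categorical variables
    (<= 2 distinct non-missing values) with the chi-square test and
    summarized as counts.  The ``group`` column must have exactly two
    levels.
    """
    levels = sorted(frame[group].dropna().unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"grouping column {group!r} must have exactly 2 levels")
    g0 = frame[frame[group] == levels[0]]
    g1 = frame[frame[group] == levels[1]]
    rows = []
    for var in variables:
        x0 = g0[var].dropna().to_numpy()
        x1 = g1[var].dropna().to_numpy()
        distinct = frame[var].dropna().nunique()
        if distinct <= 2:
            counts = np.array([
                [(x0 == v).sum() for v in sorted(frame[var].dropna().unique())],
                [(x1 == v).sum() for v in sorted(frame[var].dropna().unique())],
            ])
            res = chi_square(counts)
            summ0 = f"{int((x0 == counts.shape[1] - 1).sum())}/{len(x0)}"
            summ1 = f"{int((x1 == counts.shape[1] - 1).sum())}/{len(x1)}"
        else:
            res = mann_whitney_u(x0, x1)
            q0 = np.percentile(x0, [50, 25, 75])
            q1 = np.percentile(x1, [50, 25, 75])
            summ0 = f"{q0[0]:.2f} ({q0[1]:.2f}; {q0[2]:.2f})"
            summ1 = f"{q1[0]:.2f} ({q1[1]:.2f}; {q1[2]:.2f})"
        rows.append({
            "variable": var,
            f"{group}={levels[0]}": summ0,
            f"{group}={levels[1]}": summ1,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "method": res.method,
        })
    return pd.DataFrame(rows)
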