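"""Self-contained statistical kernel used by every other module.

Implements the four primitives the connectivity pipeline is built on:
the Fisher r-to-z transform, one- and two-sample Student t-tests
(pooled variance, exact t reference distribution), Benjamini-Hochberg
step-up FDR, and Pearson correlation with its t-based significance
test.  Everything here is a pure function of its arguments.

Only the Student-t cumulative distribution is delegated to
``scipy.special``; the statistics themselves are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "TestResult",
    "FdrDecision",
    "R_CLIP",
    "fisher_z",
    "inverse_fisher_z",
    "one_sample_t",
    "two_sample_t",
    "one_sample_t_array",
    "two_sample_t_array",
    "bh_fdr",
    "pearson_corr",
]

#: Correlations of exactly +/-1 (possible on short synthetic series) are
#: clipped to +/-(1 - R_CLIP_EPS) before arctanh so z stays finite.
R_CLIP_EPS = 1e-7
R_CLIP = 1.0 - R_CLIP_EPS


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single significance test.

    ``statistic`` holds t for the t-tests and r for the correlation test;
    ``p_two_tailed`` is always a two-tailed p in [0, 1].
    """

    statistic: float
    df: int
    p_two_tailed: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class FdrDecision:
    """Benjamini-Hochberg step-up decision over a family of p-values."""

    p_values: np.ndarray
    q_level: float
    rejected: np.ndarray
    adjusted_p: np.ndarray

    @property
    def n_rejected(self) -> int:
        return int(np.count_nonzero(self.rejected))


def _as_finite_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def fisher_z(r, clip: bool = True):
    """Fisher r-to-z transform, arctanh(r).

    Variance-stabilizes correlation coefficients so they can be compared
    with Gaussian-theory t-tests.  Scalar in, scalar out; arrays pass
    through elementwise.  Values at or beyond +/-1 are clipped to
    +/-(1 - 1e-7) when ``clip`` is true, otherwise rejected.
    """
    arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("correlation input must be finite")
    if clip:
        arr = np.clip(arr, -R_CLIP, R_CLIP)
    elif np.any(np.abs(arr) >= 1.0):
        raise ValueError("|r| >= 1 with clipping disabled")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def inverse_fisher_z(z):
    """tanh(z), the inverse of :func:`fisher_z`."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


def _t_p_two_tailed(t, df):
    """Two-tailed p from the exact Student-t CDF."""
    t = np.asarray(t, dtype=float)
    return 2.0 * special.stdtr(df, -np.abs(t))


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """One-sample two-tailed Student t-test of mean(values) against mu0."""
    v = _as_finite_1d(values, "values")
    n = v.size
    if n < 2:
        raise ValueError("one_sample_t requires n >= 2")
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate sample: zero variance")
    t = (v.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    return TestResult(float(t), df, float(_t_p_two_tailed(t, df)))


def two_sample_t(a, b) -> TestResult:
    """Pooled-variance two-sample two-tailed Student t-test.

    Positive t means mean(a) > mean(b); df = n_a + n_b - 2.  Pooled
    (equal-variance) Student form, the classical choice whose df matches
    group-comparison reports with n1 + n2 - 2 degrees of freedom.
    """
    a = _as_finite_1d(a, "a")
    b = _as_finite_1d(b, "b")
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("two_sample_t requires n >= 2 per group")
    df = na + nb - 2
    ss = (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    sp2 = ss / df
    if sp2 == 0.0:
        raise ValueError("degenerate samples: zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return TestResult(float(t), df, float(_t_p_two_tailed(t, df)))


def one_sample_t_array(values: np.ndarray, mu0: float = 0.0):
    """Vectorized one-sample t over the columns of an (n, m) array.

    Returns ``(t, df, p)`` with t and p of length m.  Columns with zero
    variance yield t = nan, p = nan (callers decide how to treat them).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("expected (n >= 2, m) array")
    n = v.shape[0]
    sd = v.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (v.mean(axis=0) - mu0) / (sd / np.sqrt(n))
    p = np.where(np.isfinite(t), _t_p_two_tailed(np.nan_to_num(t), df), np.nan)
    t = np.where(sd > 0, t, np.nan)
    p = np.where(sd > 0, p, np.nan)
    return t, df, p


def two_sample_t_array(a: np.ndarray, b: np.ndarray):
    """Vectorized pooled two-sample t over columns of (n_a, m) vs (n_b, m)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("expected (n_a, m) and (n_b, m) arrays")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("two_sample_t requires n >= 2 per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    ok = sp2 > 0
    p = np.where(ok, _t_p_two_tailed(np.where(ok, t, 0.0), df), np.nan)
    t = np.where(ok, t, np.nan)
    return t, df, p


def bh_fdr(p_values, q_level: float = 0.05) -> FdrDecision:
    """Benjamini-Hochberg step-up FDR control at level ``q_level``.

    Rejects the k smallest p-values where k is the largest index with
    p_(k) <= k * q / m; the comparison is made on that step-up form
    directly (the equivalent ``adjusted_p <= q`` test can flip at the
    last floating-point ulp).  Adjusted p-values use the standard
    monotone (reverse cumulative minimum) construction.

    An empty family returns an empty decision, not an error.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if not (0.0 < q_level < 1.0):
        raise ValueError("q_level must lie in (0, 1)")
    if p.size and (np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        empty = np.empty(0)
        return FdrDecision(p, q_level, np.empty(0, dtype=bool), empty)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    adj_sorted = p[order] * m / ranks
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    below = p[order] <= ranks * q_level / m
    k_star = int(np.flatnonzero(below)[-1]) + 1 if below.any() else 0
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return FdrDecision(p.copy(), q_level, rejected, adjusted)


def pearson_corr(x, y) -> TestResult:
    """Pearson correlation with its two-tailed t-based significance test.

    p comes from t = r * sqrt(n - 2) / sqrt(1 - r^2) with df = n - 2.
    The returned ``statistic`` is r.  Collinear data (|r| = 1) report
    p = 0 exactly.
    """
    x = _as_finite_1d(x, "x")
    y = _as_finite_1d(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("pearson_corr requires n >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(xd @ xd)
    sy = np.sqrt(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance input")
    r = float(np.clip((xd @ yd) / (sx * sy), -1.0, 1.0))
    df = n - 2
    if 1.0 - r * r <= 0.0:
        return TestResult(r, df, 0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return TestResult(r, df, float(_t_p_two_tailed(t, df)))
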