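"""Statistical kernels shared by all pipeline stages.

Exposes the hypergeometric log-mass, Fisher's exact test on a 2x2 table,
Benjamini–Hochberg step-up adjustment, a Z-test against an empirical null,
and a one-sample t-test.  The exact test sums the conditional hypergeometric
mass over the support of the table's ``a`` cell; the two-sided p-value is the
total mass of all margin-fixed tables whose point probability does not exceed
the observed one (relative tie tolerance 1e-7, since floating-point equality
of masses is ill-defined).  Extreme t tail probabilities are evaluated in log
space so that statistics of magnitude several hundred report finite
log-probabilities instead of underflowing to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: Relative tolerance for point-mass ties in the two-sided exact test.
TIE_RTOL = 1e-7


class StatsDomainError(ValueError):
    """Raised when kernel inputs are outside their domain."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a/b = foreground with/without, c/d = background with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise StatsDomainError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise StatsDomainError("both rows of the contingency table must be non-empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """Exchange foreground and background rows."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class TestResult:
    """Test outcome: statistic, p-value, sidedness, optional df and log10 p.

    ``log10_p`` is carried alongside ``p_value`` because empirical-null
    comparisons can produce tail probabilities far below float underflow.
    """

    statistic: float
    p_value: float
    sidedness: str
    df: float | None = None
    log10_p: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sidedness not in ("two_sided", "greater", "less"):
            raise StatsDomainError(f"unknown sidedness {self.sidedness!r}")


def log_hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """Log of P(X = k) for X ~ Hypergeom(N, K, n).

    ``N`` population size, ``K`` marked members, ``n`` draws, ``k`` marked
    draws; the mass is C(K,k) C(N-K,n-k) / C(N,n).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise StatsDomainError(f"require 0 <= K,n <= N; got K={K}, n={n}, N={N}")
    if not (max(0, n - (N - K)) <= k <= min(K, n)):
        raise StatsDomainError(f"k={k} outside the support for K={K}, n={n}, N={N}")
    return float(sps.hypergeom.logpmf(k, N, K, n))


def _support_pmf(table: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Support values of cell ``a`` and their conditional masses, margins fixed."""
    r1 = table.a + table.b
    c1 = table.a + table.c
    N = table.n
    lo = max(0, c1 - (N - r1))
    hi = min(r1, c1)
    avals = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(avals, N, c1, r1)
    return avals, pmf


def fisher_exact(table: ContingencyTable, sidedness: str = "two_sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    ``greater`` is the upper tail on cell ``a`` (foreground enrichment);
    ``two_sided`` sums all margin-fixed tables with point mass <= observed
    (relative tie tolerance :data:`TIE_RTOL`).  A degenerate column margin
    (no subject, or every subject, carries the feature) yields p = 1 with the
    ``degenerate`` flag set.
    """
    if sidedness not in ("two_sided", "greater", "less"):
        raise StatsDomainError(f"unknown sidedness {sidedness!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    odds = math.inf if b * c == 0 and a * d > 0 else (
        (a * d) / (b * c) if b * c > 0 else math.nan
    )
    if a + c == 0 or b + d == 0:
        return TestResult(statistic=odds, p_value=1.0, sidedness=sidedness, degenerate=True)

    avals, pmf = _support_pmf(table)
    p_obs = pmf[int(a - avals[0])]
    if sidedness == "greater":
        p = float(pmf[avals >= a].sum())
    elif sidedness == "less":
        p = float(pmf[avals <= a].sum())
    else:
        p = float(pmf[pmf <= p_obs * (1.0 + TIE_RTOL)].sum())
    if p > 1.0 - 1e-9:  # whole-support sums land at 1 - O(eps); snap
        p = 1.0
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    return TestResult(statistic=odds, p_value=p, sidedness=sidedness,
                      log10_p=math.log10(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise StatsDomainError("bh_adjust requires a non-empty 1-d array")
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise StatsDomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def z_test(observed: float, null_mean: float, null_sd: float) -> TestResult:
    """Z-score of an observed value against an empirical null mean/sd.

    The p-value is the upper tail of the standard normal at |z| (how extreme
    the observation is relative to the null spread, direction ignored).
    """
    if not null_sd > 0:
        raise StatsDomainError("null_sd must be positive")
    z = (observed - null_mean) / null_sd
    logp = float(sps.norm.logsf(abs(z)))
    p = min(max(math.exp(logp), float(np.finfo(float).tiny)), 1.0)
    return TestResult(statistic=z, p_value=p, sidedness="greater",
                      log10_p=logp / math.log(10))


def one_sample_t(sample_mean: float, sample_sd: float, n: int, mu0: float) -> TestResult:
    """One-sample t-test of a sample mean against a reference value mu0.

    t = (mean - mu0) / (sd / sqrt(n)), df = n - 1, two-sided p from the t
    distribution; the tail is evaluated through the log survival function so
    extreme statistics keep a finite log10 p.
    """
    if n < 2:
        raise StatsDomainError("one_sample_t requires n >= 2")
    if not sample_sd > 0:
        raise StatsDomainError("sample_sd must be positive")
    df = n - 1
    t = (sample_mean - mu0) / (sample_sd / math.sqrt(n))
    log_tail = float(sps.t.logsf(abs(t), df))
    logp = log_tail + math.log(2.0)
    p = min(max(math.exp(logp), float(np.finfo(float).tiny)), 1.0)
    return TestResult(statistic=t, p_value=p, sidedness="two_sided", df=float(df),
                      log10_p=logp / math.log(10))
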