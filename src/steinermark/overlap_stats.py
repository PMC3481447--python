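"""Overlap statistics for two gene sets against a network background.

Percent overlap is the Jaccard index scaled to 100: 100*o/(m+n-o) for set
sizes m, n and intersection o. Significance is the one-sided upper tail of
the hypergeometric distribution (Fisher's exact test),

    p = P(X >= o),  X ~ Hypergeometric(N, m, n),

with N the number of genes in the network's largest connected component. The
tail is evaluated in log space (log-gamma binomial coefficients, log-sum-exp)
because observed overlaps can be as extreme as 1e-159 — far below what a
direct survival-function evaluation can represent. ``log10_p`` is the
authoritative quantity for such values; ``p_value`` is its (possibly clamped)
linear counterpart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

_TINIEST = 5e-324  # smallest positive subnormal double, used only as a clamp


@dataclass(frozen=True)
class OverlapResult:
    N: int
    m: int
    n: int
    o: int
    percent: float
    p_value: float
    log10_p: float


def _check_counts(N: int, m: int, n: int, o: int) -> None:
    if N < 1:
        raise ValueError("background size N must be >= 1")
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError("set sizes must satisfy 0 <= m, n <= N")
    if not 0 <= o <= min(m, n):
        raise ValueError("overlap must satisfy 0 <= o <= min(m, n)")


def percent_overlap(m: int, n: int, o: int) -> float:
    """100 * o / (m + n - o); requires 0 <= o <= min(m, n) and a non-empty union."""
    if not 0 <= o <= min(m, n):
        raise ValueError("overlap must satisfy 0 <= o <= min(m, n)")
    union = m + n - o
    if union < 1:
        raise ValueError("union of the two sets must be non-empty")
    return 100.0 * o / union


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def overlap_pvalue(N: int, m: int, n: int, o: int) -> tuple:
    """Upper-tail hypergeometric probability P(X >= o).

    Returns ``(p_value, log10_p)``. Counts below the distribution's support
    minimum (o <= max(0, m+n-N)) give exactly 1. Impossible terms contribute
    zero probability rather than raising.
    """
    _check_counts(N, m, n, o)
    support_lo = max(0, m + n - N)
    if o <= support_lo:
        return 1.0, 0.0
    i = np.arange(o, min(m, n) + 1)
    log_terms = _log_binom(m, i) + _log_binom(N - m, n - i) - _log_binom(N, n)
    log_p = float(logsumexp(log_terms)) if len(i) else -np.inf
    log_p = min(log_p, 0.0)
    p = math.exp(log_p)
    if p == 0.0:
        p = _TINIEST
    return p, log_p / math.log(10.0)


def overlap_result(N: int, m: int, n: int, o: int) -> OverlapResult:
    """Bundle percent overlap and the Fisher's-exact tail for one comparison."""
    p, log10p = overlap_pvalue(N, m, n, o)
    return OverlapResult(N=N, m=m, n=n, o=o, percent=percent_overlap(m, n, o), p_value=p, log10_p=log10p)
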