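"""Ewens sampling formula machinery for Fu's F_S.

Under the neutral infinite-alleles model with scaled mutation rate theta,
the number of distinct alleles K in a sample of n has

    P(K = k) = |s(n, k)| * theta^k / (theta)_n,

where |s(n, k)| are unsigned Stirling numbers of the first kind and
(theta)_n is the rising factorial.  Everything here is computed in log
space so that samples up to at least n = 100 never overflow.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

__all__ = ["log_stirling_first_row", "log_haplotype_number_pmf", "prob_k_or_more"]


@lru_cache(maxsize=None)
def log_stirling_first_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (log 0 = -inf).

    Built with the recurrence |s(n, k)| = |s(n-1, k-1)| + (n-1) |s(n-1, k)|
    carried out in log space.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    row = np.full(n + 1, -np.inf)
    row[1] = 0.0  # |s(1,1)| = 1
    if n == 1:
        return row
    prev = log_stirling_first_row(n - 1)
    row[1 : n + 1] = np.logaddexp(
        np.concatenate(([-np.inf], prev[1:n])),  # |s(n-1, k-1)|
        np.log(n - 1) + np.concatenate((prev[1:n], [-np.inf])),  # (n-1)|s(n-1, k)|
    )
    row[n] = 0.0  # exact: |s(n, n)| = 1
    return row


def log_haplotype_number_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 1..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = log_stirling_first_row(n)[1:]
    k = np.arange(1, n + 1)
    logterms = ls + k * np.log(theta)
    return logterms - logsumexp(logterms)  # normaliser equals log (theta)_n


def prob_k_or_more(n: int, k_obs: int, theta: float) -> float:
    """S' = P(K >= k_obs) under Ewens; the tail probability inside F_S."""
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must lie in 1..n")
    logp = log_haplotype_number_pmf(n, theta)
    return float(np.exp(logsumexp(logp[k_obs - 1 :])))


def log_odds_k_or_more(n: int, k_obs: int, theta: float) -> float:
    """ln(S' / (1 - S')) computed fully in log space.

    Returns +inf when k_obs = 1 (the tail is the whole distribution).
    Normalisation cancels in the odds, so only the relative term weights
    matter; the shared maximum is subtracted before exponentiating.
    """
    if k_obs <= 1:
        return np.inf
    terms = log_stirling_first_row(n)[1:] + np.arange(1, n + 1) * np.log(theta)
    terms = terms - terms.max()
    w = np.exp(terms)
    lo = w[: k_obs - 1].sum()
    hi = w[k_obs - 1 :].sum()
    if lo == 0.0:
        return np.inf
    if hi == 0.0:
        return -np.inf
    return float(np.log(hi) - np.log(lo))
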