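"""Neutrality-test summary statistics for multi-locus haplotype data.

Implements, per locus and averaged across loci:

* Tajima's D — contrast of mean pairwise differences K against S/a_n.
* Fu & Li's F* — contrast of K against singleton segregating sites,
  without an outgroup, with the corrected variance constants.
* Fu's F_S — log-odds of observing at least the sampled number of distinct
  haplotypes under the Ewens sampling formula at theta = theta_pi.
* Ramos-Onsins & Rozas's R2 — spread of per-sequence singleton counts
  around K/2, divided by S.
* Achaz's Y* — the K-versus-Watterson contrast computed after discarding
  singletons, normalised through the frequency-spectrum covariance matrix
  of Fu (1995).
* Kelly's Z_nS — mean r^2 over all pairs of biallelic segregating sites.

plus Nei's haplotype diversity Hd and Watterson's theta.  A statistic that
is undefined for a locus (S = 0, or fewer than two biallelic sites for
Z_nS, or no non-singleton sites for Y*) is returned as None and excluded
from across-locus means, with the count of contributing loci reported.

Singletons are folded: a site counts as a singleton when exactly one
sampled sequence carries a state seen only once at that site (no ancestral
state is assumed).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import ewens
from .coalsim import HaplotypeDataset, SegPatterns
from .hky import BASES

__all__ = [
    "STATISTICS",
    "SiteFrequencySummary",
    "SummaryStatisticProfile",
    "site_summary",
    "summary_from_patterns",
    "tajima_D",
    "fu_li_F_star",
    "fu_FS",
    "ramos_onsins_R2",
    "achaz_Y_star",
    "kelly_ZnS",
    "nei_Hd",
    "locus_statistics",
    "profile",
    "mean_over_defined",
]

#: Canonical statistic order used in every table.
STATISTICS = ("D", "F_star", "F_S", "R2", "Y_star", "ZnS")

_BASE_CODE = {c: i for i, c in enumerate(BASES)}


def as_matrix(alignment) -> np.ndarray:
    """Coerce an alignment (list of equal-length strings, or a small-int
    matrix) to an (n, L) uint8 matrix."""
    if isinstance(alignment, np.ndarray):
        if alignment.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        return alignment.astype(np.uint8, copy=False)
    seqs = list(alignment)
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("ragged alignment: sequences differ in length")
    try:
        rows = [[_BASE_CODE[c] for c in s.upper()] for s in seqs]
    except KeyError as exc:  # pragma: no cover - input validation
        raise ValueError(f"unknown base {exc.args[0]!r}") from exc
    return np.asarray(rows, dtype=np.uint8)


# ---------------------------------------------------------------------------
# per-sample-size constants

@lru_cache(maxsize=None)
def harmonic_sums(n: int) -> tuple[float, float]:
    """(a_n, b_n) = (sum_{i<n} 1/i, sum_{i<n} 1/i^2)."""
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima (1989)."""
    a1, a2 = harmonic_sums(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2)


@lru_cache(maxsize=None)
def fu_li_fstar_constants(n: int) -> tuple[float, float]:
    """(u*, v*) for Fu & Li's F*, derived exactly.

    The F* numerator is K - ((n-1)/n) eta_S, a linear contrast of the site
    frequency spectrum, so its variance alpha theta + beta theta^2 follows
    exactly from the Fu (1995) covariance matrix.  The printed constants in
    the original papers are approximations that differ among sources; here
    (u*, v*) are chosen so that u* S + v* S^2 is an unbiased estimator of
    that exact variance (E[S] = a_n theta, E[S^2] = a_n theta +
    (a_n^2 + b_n) theta^2).
    """
    a, b = harmonic_sums(n)
    i = np.arange(1, n)
    npairs = n * (n - 1) / 2.0
    c = i * (n - i) / npairs
    c = c.astype(float)
    c[0] -= (n - 1) / n
    c[n - 2] -= (n - 1) / n
    alpha, beta = spectrum_test_variance(n, tuple(c))
    v = beta / (a**2 + b)
    u = alpha / a - v
    return u, v


@lru_cache(maxsize=None)
def fu1995_sigma(n: int) -> np.ndarray:
    """Covariance coefficients sigma_ij of the site frequency spectrum.

    Cov(xi_i, xi_j) = delta_ij theta / i + sigma_ij theta^2 for the
    neutral constant-size coalescent (Fu 1995); entry [i-1, j-1] holds
    sigma_ij, i, j = 1..n-1.
    """
    a = np.zeros(n + 2)
    for k in range(1, n + 2):
        a[k] = a[k - 1] + 1.0 / k  # a[k] = sum_{i<=k} 1/i; a_n = a[n-1]
    an = a[n - 1]
    an1 = a[n]

    def beta(i: int) -> float:
        return 2.0 * n * (an1 - a[i - 1]) / ((n - i + 1) * (n - i)) - 2.0 / (n - i)

    sig = np.zeros((n - 1, n - 1))
    for i in range(1, n):
        if 2 * i < n:
            sig[i - 1, i - 1] = beta(i + 1)
        elif 2 * i == n:
            sig[i - 1, i - 1] = 2.0 * (an - a[i - 1]) / (n - i) - 1.0 / i**2
        else:
            sig[i - 1, i - 1] = beta(i) - 1.0 / i**2
    for hi in range(2, n):
        for lo in range(1, hi):
            # stated for the larger index hi and smaller index lo
            if hi + lo < n:
                val = (beta(hi + 1) - beta(hi)) / 2.0
            elif hi + lo == n:
                val = (
                    (an - a[hi - 1]) / (n - hi)
                    + (an - a[lo - 1]) / (n - lo)
                    - (beta(hi) + beta(lo + 1)) / 2.0
                    - 1.0 / (hi * lo)
                )
            else:
                val = (beta(lo) - beta(lo + 1)) / 2.0 - 1.0 / (hi * lo)
            sig[hi - 1, lo - 1] = sig[lo - 1, hi - 1] = val
    return sig


@lru_cache(maxsize=None)
def spectrum_test_variance(n: int, coeffs: tuple[float, ...]) -> tuple[float, float]:
    """(alpha, beta) with Var(sum_i coeffs_i xi_i) = alpha theta + beta theta^2."""
    c = np.asarray(coeffs)
    i = np.arange(1, n)
    alpha = float(np.sum(c**2 / i))
    beta = float(c @ fu1995_sigma(n) @ c)
    return alpha, beta


@lru_cache(maxsize=None)
def achaz_ystar_constants(n: int) -> dict:
    """Normalisation pieces for Achaz's Y* (singletons discarded, folded)."""
    if n < 5:
        raise ValueError("Y* needs n >= 5")
    a, b = harmonic_sums(n)
    a_star = a - 1.0 - 1.0 / (n - 1)
    b_star = b - 1.0 - 1.0 / (n - 1) ** 2
    m_pair = n * (n - 1) / 2.0 - n  # sum_{i=2}^{n-2} (n - i)
    coeffs = np.zeros(n - 1)
    for i in range(2, n - 1):
        coeffs[i - 1] = i * (n - i) / m_pair - 1.0 / a_star
    if np.abs(coeffs).max() < 1e-12:
        # n = 5: both usable frequency classes get identical weight in
        # pi* and Watterson*, so the contrast is identically zero
        return {"degenerate": True}
    alpha, beta = spectrum_test_variance(n, tuple(coeffs))
    return {
        "degenerate": False,
        "a_star": a_star,
        "b_star": b_star,
        "m_pair": m_pair,
        "alpha": alpha,
        "beta": beta,
    }


# ---------------------------------------------------------------------------
# per-locus site summaries

@dataclass
class SiteFrequencySummary:
    """Site counts for one locus, sufficient for all six statistics."""

    n: int  # sampled alleles
    S: int  # segregating sites (each polymorphic column counts once)
    K: float  # mean pairwise differences over all C(n, 2) pairs
    eta_S: int  # folded singleton sites
    H_N: int  # distinct haplotypes
    U: np.ndarray  # per-sequence singleton counts, length n
    bi: np.ndarray  # (n, S_bi) 0/1 indicators of biallelic sites

    @property
    def theta_pi(self) -> float:
        return self.K

    @property
    def a_n(self) -> float:
        return harmonic_sums(self.n)[0]

    @property
    def b_n(self) -> float:
        return harmonic_sums(self.n)[1]

    @property
    def theta_W(self) -> float:
        return self.S / self.a_n

    def __post_init__(self) -> None:
        if not (0 <= self.eta_S <= self.S):
            raise ValueError("eta_S must lie in [0, S]")
        if not (1 <= self.H_N <= self.n):
            raise ValueError("H_N must lie in [1, n]")


def site_summary(alignment) -> SiteFrequencySummary:
    """Summarise a nucleotide alignment (>= 2 equal-length sequences)."""
    mat = as_matrix(alignment)
    n, L = mat.shape
    if n < 2:
        raise ValueError("need at least two sequences")
    counts = np.stack([(mat == s).sum(axis=0) for s in range(4)])  # (4, L)
    present = counts > 0
    poly = present.sum(axis=0) >= 2
    S = int(poly.sum())
    npairs = n * (n - 1) / 2.0
    same = (counts * (counts - 1) // 2).sum(axis=0)
    K = float((npairs - same[poly]).sum() / npairs) if S else 0.0

    ones = counts == 1
    singleton_col = poly & (ones.sum(axis=0) == 1)
    U = np.zeros(n, dtype=np.int64)
    eta = 0
    for col in np.nonzero(singleton_col)[0]:
        state = int(np.argmax(ones[:, col]))
        carrier = int(np.argmax(mat[:, col] == state))
        U[carrier] += 1
        eta += 1

    # distinct haplotypes over full sequences
    H_N = np.unique(mat, axis=0).shape[0] if L else 1

    bi_cols = np.nonzero(poly & (present.sum(axis=0) == 2))[0]
    if bi_cols.size:
        sub = mat[:, bi_cols]
        bi = (sub != sub[0]).astype(np.uint8)  # indicator of "not first row's state"
    else:
        bi = np.zeros((n, 0), dtype=np.uint8)
    return SiteFrequencySummary(n=n, S=S, K=K, eta_S=eta, H_N=H_N, U=U, bi=bi)


def summary_from_patterns(pat: SegPatterns) -> SiteFrequencySummary:
    """Summarise an infinite-sites 0/1 pattern set (fast popcount path)."""
    n = pat.n
    masks = pat.masks
    S = masks.size
    if S == 0:
        return SiteFrequencySummary(
            n=n, S=0, K=0.0, eta_S=0, H_N=1, U=np.zeros(n, dtype=np.int64),
            bi=np.zeros((n, 0), dtype=np.uint8),
        )
    c = np.bitwise_count(masks).astype(np.int64)
    npairs = n * (n - 1) / 2.0
    K = float((c * (n - c)).sum() / npairs)
    U = np.zeros(n, dtype=np.int64)
    full = np.uint64((1 << n) - 1)
    lo = masks[c == 1]
    hi = masks[c == n - 1]
    eta = int(lo.size + hi.size) if n > 2 else 0
    if n > 2:
        for m in lo:
            U[int(m).bit_length() - 1] += 1
        for m in hi:
            U[int(np.uint64(full ^ m)).bit_length() - 1] += 1
    bi = pat.to_matrix()
    bi_c = np.ascontiguousarray(bi)
    H_N = len({bi_c[i].tobytes() for i in range(n)})
    return SiteFrequencySummary(n=n, S=int(S), K=K, eta_S=eta, H_N=H_N, U=U, bi=bi)


def _coerce_summary(x) -> SiteFrequencySummary:
    if isinstance(x, SiteFrequencySummary):
        return x
    if isinstance(x, SegPatterns):
        return summary_from_patterns(x)
    return site_summary(x)


# ---------------------------------------------------------------------------
# the six statistics

def tajima_D(summary) -> float | None:
    """Tajima (1989) D; None when no site segregates."""
    s = _coerce_summary(summary)
    if s.S == 0 or s.n < 3:
        return None
    e1, e2 = tajima_constants(s.n)
    var = e1 * s.S + e2 * s.S * (s.S - 1)
    if var <= 0:
        return None
    return (s.K - s.S / s.a_n) / np.sqrt(var)


def fu_li_F_star(summary) -> float | None:
    """Fu & Li (1993) F* (no outgroup); None when no site segregates."""
    s = _coerce_summary(summary)
    if s.S == 0 or s.n < 3:
        return None
    u, v = fu_li_fstar_constants(s.n)
    var = u * s.S + v * s.S**2
    if var <= 0:
        return None
    return (s.K - (s.n - 1) / s.n * s.eta_S) / np.sqrt(var)


def fu_FS(summary) -> float | None:
    """Fu (1997) F_S from the Ewens sampling formula at theta = theta_pi."""
    s = _coerce_summary(summary)
    if s.S == 0 or s.theta_pi <= 0:
        return None
    val = ewens.log_odds_k_or_more(s.n, s.H_N, s.theta_pi)
    if not np.isfinite(val):
        return None
    return float(val)


def ramos_onsins_R2(summary, alignment=None) -> float | None:
    """Ramos-Onsins & Rozas (2002) R2; None when no site segregates."""
    s = _coerce_summary(summary if alignment is None else alignment)
    if s.S == 0:
        return None
    dev = s.U - s.K / 2.0
    return float(np.sqrt(np.mean(dev**2)) / s.S)


def achaz_Y_star(summary) -> float | None:
    """Achaz (2008) Y*: the pi-vs-Watterson contrast ignoring singletons.

    None when every segregating site is a singleton (S - eta_S <= 0) or
    the sample is too small for the truncated spectrum (n < 5).
    """
    s = _coerce_summary(summary)
    if s.n < 5:
        return None
    s_star = s.S - s.eta_S
    if s_star <= 0:
        return None
    c = achaz_ystar_constants(s.n)
    if c["degenerate"]:
        return None
    npairs = s.n * (s.n - 1) / 2.0
    pi_star = (s.K - 2.0 * s.eta_S / s.n) * npairs / c["m_pair"]
    theta_w_star = s_star / c["a_star"]
    theta_hat = s_star / c["a_star"]
    theta2_hat = s_star * (s_star - 1) / (c["a_star"] ** 2 + c["b_star"])
    var = c["alpha"] * theta_hat + c["beta"] * theta2_hat
    if var <= 0:
        return None
    return float((pi_star - theta_w_star) / np.sqrt(var))


def kelly_ZnS(alignment) -> float | None:
    """Kelly (1997) Z_nS: mean r^2 over pairs of biallelic segregating sites.

    None with fewer than two biallelic segregating sites; sites with more
    than two states are excluded from pairs.
    """
    s = _coerce_summary(alignment)
    m = s.bi.astype(np.float64)
    S = m.shape[1]
    if S < 2:
        return None
    p = m.mean(axis=0)
    cov = m.T @ m / s.n - np.outer(p, p)
    pq = p * (1 - p)  # strictly positive: sites are segregating and biallelic
    r2 = cov**2 / np.outer(pq, pq)
    # mean over distinct pairs; diagonal entries are exactly 1
    return float((r2.sum() - S) / (S * (S - 1)))


def nei_Hd(alignment) -> float:
    """Nei's haplotype diversity with the n/(n-1) small-sample correction."""
    if isinstance(alignment, SiteFrequencySummary) or isinstance(alignment, SegPatterns):
        s = _coerce_summary(alignment)
        mat = s.bi
        n = s.n
    else:
        mat = as_matrix(alignment)
        n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    if mat.shape[1] == 0:
        return 0.0
    _, counts = np.unique(mat, axis=0, return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


# ---------------------------------------------------------------------------
# multi-locus profiles

_STAT_FUNCS = {
    "D": tajima_D,
    "F_star": fu_li_F_star,
    "F_S": fu_FS,
    "R2": ramos_onsins_R2,
    "Y_star": achaz_Y_star,
    "ZnS": kelly_ZnS,
}


def locus_statistics(
    summary: SiteFrequencySummary, statistics: Sequence[str] = STATISTICS
) -> dict[str, float | None]:
    """All requested statistics for one locus summary."""
    return {name: _STAT_FUNCS[name](summary) for name in statistics}


def mean_over_defined(values: Iterable[float | None]) -> tuple[float | None, int]:
    """Arithmetic mean of the defined entries and their count.

    Undefined loci may arrive as None or as NaN (pandas stores None that
    way in float columns); both are excluded.
    """
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return None, 0
    return float(np.mean(vals)), len(vals)


@dataclass
class SummaryStatisticProfile:
    """Per-locus statistic table plus across-locus means."""

    per_locus: pd.DataFrame  # one row per locus; columns = STATISTICS + Hd
    across_loci: dict[str, float | None]
    n_defined: dict[str, int]
    Hd_var: float | None  # sampling variance of Hd across loci


def profile(
    dataset: HaplotypeDataset, statistics: Sequence[str] = STATISTICS
) -> SummaryStatisticProfile:
    """Compute the full statistic profile of a multi-locus dataset."""
    if dataset.n_loci < 1:
        raise ValueError("dataset has no loci")
    rows = []
    for aln in dataset.loci:
        s = site_summary(aln)
        row = locus_statistics(s, statistics)
        row["Hd"] = nei_Hd(aln)
        row["S"] = s.S
        row["theta_W"] = s.theta_W
        rows.append(row)
    per_locus = pd.DataFrame(rows)
    across, ndef = {}, {}
    for name in list(statistics) + ["Hd"]:
        across[name], ndef[name] = mean_over_defined(per_locus[name])
    hd = per_locus["Hd"].to_numpy(dtype=float)
    hd_var = float(np.var(hd, ddof=1)) if len(hd) > 1 else None
    return SummaryStatisticProfile(
        per_locus=per_locus, across_loci=across, n_defined=ndef, Hd_var=hd_var
    )
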