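"""Independent, deliberately naive reference implementations of the
neutrality statistics, used only as test oracles.

Everything here works directly on lists of sequence strings with explicit
loops, exact ``fractions.Fraction`` arithmetic where practical, and sympy's
Stirling numbers, sharing no code with the package's vectorised
implementations.
"""

from fractions import Fraction
from itertools import combinations
from math import factorial, log, sqrt

import sympy


def pairwise_k(seqs):
    """Mean pairwise differences over all C(n,2) pairs (exact fraction)."""
    n = len(seqs)
    total = 0
    for a, b in combinations(seqs, 2):
        total += sum(1 for x, y in zip(a, b) if x != y)
    return Fraction(total, n * (n - 1) // 2)


def segregating_sites(seqs):
    return sum(1 for col in zip(*seqs) if len(set(col)) > 1)


def singleton_columns(seqs):
    """Columns where exactly one sequence carries a state seen once."""
    cols = []
    for j, col in enumerate(zip(*seqs)):
        once = [s for s in set(col) if col.count(s) == 1]
        if len(set(col)) > 1 and len(once) == 1:
            cols.append((j, col.index(once[0])))
    return cols


def haplotype_counts(seqs):
    counts = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    return sorted(counts.values(), reverse=True)


def ref_hd(seqs):
    n = len(seqs)
    sq = sum(Fraction(c, n) ** 2 for c in haplotype_counts(seqs))
    return float(Fraction(n, n - 1) * (1 - sq))


def _an(n):
    return sum(Fraction(1, i) for i in range(1, n))


def _bn(n):
    return sum(Fraction(1, i * i) for i in range(1, n))


def ref_tajima_d(seqs):
    n = len(seqs)
    S = segregating_sites(seqs)
    if S == 0 or n < 3:
        return None
    a1, a2 = _an(n), _bn(n)
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return float((pairwise_k(seqs) - Fraction(S) / a1) / Fraction(sqrt(float(var))))


def fu1995_sigma_exact(n):
    """Fu (1995) spectrum covariance coefficients, in exact rationals."""
    a = {k: sum(Fraction(1, i) for i in range(1, k + 1)) for k in range(0, n + 1)}
    an, an1 = a[n - 1], a[n]

    def beta(i):
        return Fraction(2 * n, 1) * (an1 - a[i - 1]) / ((n - i + 1) * (n - i)) - Fraction(2, n - i)

    sig = {}
    for i in range(1, n):
        if 2 * i < n:
            sig[(i, i)] = beta(i + 1)
        elif 2 * i == n:
            sig[(i, i)] = 2 * (an - a[i - 1]) / (n - i) - Fraction(1, i * i)
        else:
            sig[(i, i)] = beta(i) - Fraction(1, i * i)
    for hi in range(2, n):
        for lo in range(1, hi):
            if hi + lo < n:
                v = (beta(hi + 1) - beta(hi)) / 2
            elif hi + lo == n:
                v = (
                    (an - a[hi - 1]) / (n - hi)
                    + (an - a[lo - 1]) / (n - lo)
                    - (beta(hi) + beta(lo + 1)) / 2
                    - Fraction(1, hi * lo)
                )
            else:
                v = (beta(lo) - beta(lo + 1)) / 2 - Fraction(1, hi * lo)
            sig[(hi, lo)] = sig[(lo, hi)] = v
    return sig


def _contrast_variance(n, coeffs):
    """(alpha, beta): Var = alpha*theta + beta*theta^2 for sum c_i xi_i."""
    sig = fu1995_sigma_exact(n)
    alpha = sum(coeffs[i] ** 2 / i for i in range(1, n) if coeffs[i])
    beta = sum(
        coeffs[i] * coeffs[j] * sig[(i, j)]
        for i in range(1, n)
        for j in range(1, n)
        if coeffs[i] and coeffs[j]
    )
    return alpha, beta


def ref_fu_li_f_star(seqs):
    n = len(seqs)
    S = segregating_sites(seqs)
    if S == 0 or n < 3:
        return None
    a1, a2 = _an(n), _bn(n)
    npairs = Fraction(n * (n - 1), 2)
    coeffs = {i: Fraction(i * (n - i), 1) / npairs for i in range(1, n)}
    coeffs[1] -= Fraction(n - 1, n)
    coeffs[n - 1] -= Fraction(n - 1, n)
    alpha, beta = _contrast_variance(n, coeffs)
    v = beta / (a1**2 + a2)
    u = alpha / a1 - v
    var = u * S + v * S * S
    if var <= 0:
        return None
    eta = len(singleton_columns(seqs))
    num = pairwise_k(seqs) - Fraction(n - 1, n) * eta
    return float(num) / sqrt(float(var))


def ref_achaz_y_star(seqs):
    n = len(seqs)
    if n < 5:
        return None
    S = segregating_sites(seqs)
    eta = len(singleton_columns(seqs))
    s_star = S - eta
    if s_star <= 0:
        return None
    a_star = _an(n) - 1 - Fraction(1, n - 1)
    b_star = _bn(n) - 1 - Fraction(1, (n - 1) ** 2)
    npairs = Fraction(n * (n - 1), 2)
    m_pair = npairs - n
    coeffs = {i: Fraction(i * (n - i), 1) / m_pair - 1 / a_star for i in range(2, n - 1)}
    coeffs[1] = coeffs[n - 1] = Fraction(0)
    alpha, beta = _contrast_variance(n, coeffs)
    pi_star = (pairwise_k(seqs) - Fraction(2 * eta, n)) * npairs / m_pair
    num = pi_star - Fraction(s_star) / a_star
    th = Fraction(s_star) / a_star
    th2 = Fraction(s_star * (s_star - 1)) / (a_star**2 + b_star)
    var = alpha * th + beta * th2
    if var <= 0:
        return None
    return float(num) / sqrt(float(var))


def ref_fu_fs(seqs):
    n = len(seqs)
    S = segregating_sites(seqs)
    if S == 0:
        return None
    k_obs = len(haplotype_counts(seqs))
    theta = float(pairwise_k(seqs))
    if theta <= 0 or k_obs <= 1:
        return None
    weights = [
        int(sympy.functions.combinatorial.numbers.stirling(n, k, kind=1))
        * theta**k
        for k in range(1, n + 1)
    ]
    hi = sum(weights[k_obs - 1 :])
    lo = sum(weights[: k_obs - 1])
    if lo == 0 or hi == 0:
        return None
    return log(hi) - log(lo)


def ref_r2(seqs):
    n = len(seqs)
    S = segregating_sites(seqs)
    if S == 0:
        return None
    u = [0] * n
    for _, carrier in singleton_columns(seqs):
        u[carrier] += 1
    k = float(pairwise_k(seqs))
    return sqrt(sum((ui - k / 2) ** 2 for ui in u) / n) / S


def ref_zns(seqs):
    n = len(seqs)
    bi = []
    for col in zip(*seqs):
        states = sorted(set(col))
        if len(states) == 2:
            bi.append([1 if c == states[1] else 0 for c in col])
    if len(bi) < 2:
        return None
    vals = []
    for x, y in combinations(bi, 2):
        pa = sum(x) / n
        pb = sum(y) / n
        pab = sum(1 for i in range(n) if x[i] and y[i]) / n
        d = pab - pa * pb
        vals.append(d * d / (pa * (1 - pa) * pb * (1 - pb)))
    return sum(vals) / len(vals)


def ref_unique_proportion(fl, fu, nl, nu):
    """Measure of [fl,fu] \\ [nl,nu] over the width of [fl,fu]."""
    inter = max(0.0, min(fu, nu) - max(fl, nl))
    return ((fu - fl) - inter) / (fu - fl)
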