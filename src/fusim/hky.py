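"""Finite-site nucleotide mutation under HKY with rate heterogeneity.

The study's mutation model is HKY with equal base frequencies, a
transition/transversion ratio of 2, 10% invariant sites, and two-category
discrete-gamma rate variation at mu = 1e-7 substitutions/site/generation.
With equal base frequencies HKY reduces to Kimura's two-parameter model, so
branch transition probabilities have a closed form and sequences can be
evolved site-by-site without simulating individual substitution events.

Rate-class conventions: an invariant site has rate 0; variable sites draw
one of the discrete-gamma category rates (equal-probability categories,
category rate = the mean of the gamma density within its quantile band,
Yang 1994), normalised so the mean rate over *variable* sites is 1.

Parameterisation note: the transition/transversion *ratio* R (total
transition rate over total transversion rate) relates to the HKY rate-bias
kappa as R = kappa / 2 under equal base frequencies, so R = 2 means
kappa = 4.  Only R enters the closed-form probabilities used here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .coalsim import Genealogy

__all__ = ["MutationModel", "discrete_gamma_rates", "evolve_sequences", "BASES"]

#: Base coding used throughout: index in this string is the uint8 code.
BASES = "ACGT"


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean-1 category rates of the equal-probability discrete gamma.

    Category i covers the gamma quantile band [i/k, (i+1)/k); its rate is
    the conditional mean of a mean-1 gamma(shape) variate in that band.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    g = stats.gamma(a=shape, scale=1.0 / shape)  # mean 1
    edges = g.ppf(np.linspace(0.0, 1.0, n_categories + 1))
    # E[X; X in band] via the gamma(a+1) cdf identity: E[X 1{X<x}] = P(G_{a+1} < x)
    g1 = stats.gamma(a=shape + 1.0, scale=1.0 / shape)
    partial = g1.cdf(edges)
    rates = (partial[1:] - partial[:-1]) * n_categories
    return rates / rates.mean() * 1.0  # exact mean 1 despite ppf round-off


@dataclass(frozen=True)
class MutationModel:
    """HKY mutation model with invariant sites and discrete-gamma rates."""

    mu: float = 1e-7
    tstv_ratio: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    prop_invariant: float = 0.10
    gamma_categories: int = 2
    gamma_shape: float = 1.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if self.tstv_ratio <= 0:
            raise ValueError("ts/tv ratio must be positive")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9 or min(self.base_freqs) < 0:
            raise ValueError("base_freqs must be nonnegative and sum to 1")
        if not (0.0 <= self.prop_invariant < 1.0):
            raise ValueError("prop_invariant must lie in [0, 1)")
        if self.gamma_categories < 1:
            raise ValueError("gamma_categories must be >= 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if tuple(self.base_freqs) != (0.25, 0.25, 0.25, 0.25):
            raise ValueError(
                "only equal base frequencies are supported (K80 closed form)"
            )

    @property
    def kappa(self) -> float:
        """HKY rate-bias parameter; equals 2 * ts/tv ratio at equal frequencies."""
        return 2.0 * self.tstv_ratio

    def site_rates(self, locus_length: int, rng: np.random.Generator) -> np.ndarray:
        """Draw a relative rate for every site (0 for invariant sites)."""
        cat_rates = discrete_gamma_rates(self.gamma_shape, self.gamma_categories)
        rates = cat_rates[rng.integers(self.gamma_categories, size=locus_length)]
        invariant = rng.random(locus_length) < self.prop_invariant
        rates[invariant] = 0.0
        return rates


def _k80_probs(rate_times: np.ndarray, tstv: float) -> tuple[np.ndarray, np.ndarray]:
    """K80 closed-form substitution probabilities after ``rate_times``.

    ``rate_times`` is mu * relative_rate * branch_length per site, i.e. the
    expected number of substitutions.  Total rate alpha + 2 beta = 1 with
    alpha / (2 beta) = tstv.  Returns (P_transition, P_each_transversion).
    """
    beta = 1.0 / (2.0 * tstv + 2.0)
    alpha = 2.0 * tstv * beta
    e4 = np.exp(-4.0 * beta * rate_times)
    e2 = np.exp(-2.0 * (alpha + beta) * rate_times)
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4
    return p_ts, p_tv


def evolve_sequences(
    genealogy: "Genealogy",
    mm: MutationModel,
    locus_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve one locus along a genealogy; returns (n_leaves, L) uint8 codes.

    Base coding is A=0, C=1, G=2, T=3; with this coding the transition
    partner of base b is ``b ^ 2`` and the transversion partners are
    ``b ^ 1`` and ``b ^ 3``.
    """
    n = genealogy.n_leaves
    n_nodes = genealogy.n_nodes
    rates = mm.site_rates(locus_length, rng)
    seqs = np.empty((n_nodes, locus_length), dtype=np.uint8)
    seqs[genealogy.root] = rng.integers(4, size=locus_length, dtype=np.uint8)
    variable = rates > 0
    var_idx = np.nonzero(variable)[0]
    var_rates = rates[var_idx]
    # parents always have higher indices: walk root -> leaves
    for node in range(n_nodes - 2, -1, -1):
        par = genealogy.parent[node]
        t = genealogy.time[par] - genealogy.time[node]
        child = seqs[par].copy()
        if t > 0 and var_idx.size:
            p_ts, p_tv = _k80_probs(mm.mu * var_rates * t, mm.tstv_ratio)
            u = rng.random(var_idx.size)
            ts = u < p_ts
            tv1 = (~ts) & (u < p_ts + p_tv)
            tv2 = (~ts) & (~tv1) & (u < p_ts + 2.0 * p_tv)
            sub = var_idx[ts]
            child[sub] ^= 2
            sub = var_idx[tv1]
            child[sub] ^= 1
            sub = var_idx[tv2]
            child[sub] ^= 3
        seqs[node] = child
    return seqs[:n]
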