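"""Simulated distributions of multi-locus mean statistics under a model.

For one observed dataset and one candidate demographic model, the
distribution of each statistic's across-locus mean is estimated by
repeatedly re-simulating the whole multi-locus dataset under the model,
seeding each locus with the observed per-locus Watterson theta (the
"coalescent simulations given theta" convention).  Each distribution is
summarised by its central 90% confidence interval (5th and 95th empirical
percentiles, linear interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coalsim import HaplotypeDataset, simulate_null_replicate
from .demography import DemographicModel
from .sumstats import (
    STATISTICS,
    locus_statistics,
    mean_over_defined,
    site_summary,
    summary_from_patterns,
)

__all__ = [
    "StatisticDistribution",
    "ConfidenceInterval",
    "estimate_distributions",
    "estimate_distributions_from_theta",
    "central_90_CI",
    "pod_theta_per_locus",
]


@dataclass
class StatisticDistribution:
    """Replicate values of one statistic's across-locus mean under one model."""

    statistic: str
    model: DemographicModel
    values: np.ndarray  # defined replicate means only
    n_reps: int  # replicates requested

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("distribution values must be finite")
        if self.values.size > self.n_reps:
            raise ValueError("more values than requested replicates")


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def pod_theta_per_locus(pod: HaplotypeDataset) -> np.ndarray:
    """Observed Watterson theta per locus (per gene, not per site)."""
    return np.array([site_summary(aln).theta_W for aln in pod.loci])


def estimate_distributions_from_theta(
    model: DemographicModel,
    n_alleles: int,
    theta_per_locus: Sequence[float],
    n_reps: int,
    rng: np.random.Generator,
    statistics: Sequence[str] = STATISTICS,
) -> dict[str, StatisticDistribution]:
    """Estimate the across-locus-mean distributions by simulation.

    Each replicate simulates every locus under ``model`` (theta-seeded,
    infinite sites), computes each statistic per locus, and averages the
    defined loci; replicates where a statistic is defined at no locus are
    dropped from that statistic's distribution.
    """
    theta = np.asarray(theta_per_locus, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be nonnegative")
    if np.all(theta == 0):
        raise ValueError("degenerate POD: theta is zero at every locus")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    collected: dict[str, list[float]] = {s: [] for s in statistics}
    for _ in range(n_reps):
        per_locus: dict[str, list[float | None]] = {s: [] for s in statistics}
        for th in theta:
            pat = simulate_null_replicate(model, n_alleles, float(th), rng)
            vals = locus_statistics(summary_from_patterns(pat), statistics)
            for s in statistics:
                per_locus[s].append(vals[s])
        for s in statistics:
            m, _ = mean_over_defined(per_locus[s])
            if m is not None:
                collected[s].append(m)
    return {
        s: StatisticDistribution(
            statistic=s, model=model, values=np.array(collected[s]), n_reps=n_reps
        )
        for s in statistics
    }


def estimate_distributions(
    pod: HaplotypeDataset,
    model: DemographicModel,
    n_reps: int,
    rng: np.random.Generator,
    statistics: Sequence[str] = STATISTICS,
) -> dict[str, StatisticDistribution]:
    """As :func:`estimate_distributions_from_theta`, seeded from a POD."""
    if pod.n_loci < 1:
        raise ValueError("POD has no loci")
    theta = pod_theta_per_locus(pod)
    return estimate_distributions_from_theta(
        model, pod.n_alleles, theta, n_reps, rng, statistics
    )


def central_90_CI(dist: StatisticDistribution | np.ndarray) -> ConfidenceInterval:
    """Central 90% CI: (5th, 95th) percentiles, linear interpolation."""
    values = dist.values if isinstance(dist, StatisticDistribution) else np.asarray(dist)
    if values.size < 20:
        raise ValueError("need at least 20 values for a stable 90% CI")
    lo, hi = np.percentile(values, [5.0, 95.0], method="linear")
    return ConfidenceInterval(lower=float(lo), upper=float(hi))
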