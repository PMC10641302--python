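"""Traditional hypothesis testing of size constancy on simulated datasets.

Each multi-locus dataset is tested against a constant-size neutral null:
the observed across-locus mean of every statistic is compared with its
empirical distribution over theta-seeded coalescent replicates.  A
significantly positive D, F*, F_S or Y* (or significantly large R2/Z_nS)
is read as population decline, the mirror-image tail as growth, and
anything else as constancy — the misreading a practitioner would make when
lineage fusion is not in the candidate set.

Two-sided testing at level alpha puts alpha/2 in each tail (alpha = 0.05;
0.02 for F_S).  Empirical p-values use the (r + 1) / (N + 1) estimator.
A one-tailed-at-alpha convention is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coalsim import HaplotypeDataset
from .demography import DatasetComposition, FusionScenario, SingleDemeModel
from .hky import MutationModel
from .nulldist import estimate_distributions
from .sumstats import STATISTICS, mean_over_defined, profile

__all__ = ["TestResult", "DEFAULT_ALPHA", "test_pod", "decline_count"]

#: Significance levels; F_S uses the stricter conventional level.
DEFAULT_ALPHA = {s: 0.05 for s in STATISTICS}
DEFAULT_ALPHA["F_S"] = 0.02

INFERENCES = ("constancy", "growth", "decline")


@dataclass(frozen=True)
class TestResult:
    statistic: str
    observed: float
    p_lower: float  # P(null <= observed), with the +1 correction
    p_upper: float  # P(null >= observed)
    alpha: float
    inference: str

    def __post_init__(self) -> None:
        if self.inference not in INFERENCES:
            raise ValueError(f"unknown inference {self.inference!r}")


def _classify(p_lower: float, p_upper: float, alpha: float, two_sided: bool) -> str:
    thr = alpha / 2.0 if two_sided else alpha
    # larger values of every statistic point toward decline (slower
    # coalescence deep in the tree); smaller values toward growth
    if p_upper <= thr:
        return "decline"
    if p_lower <= thr:
        return "growth"
    return "constancy"


def test_pod(
    pod: HaplotypeDataset,
    n_reps: int,
    rng: np.random.Generator,
    statistics: Sequence[str] = STATISTICS,
    alpha: dict[str, float] | None = None,
    two_sided: bool = True,
) -> dict[str, TestResult]:
    """Test a dataset against the constant-size neutral null."""
    alpha = dict(DEFAULT_ALPHA if alpha is None else alpha)
    null_model = SingleDemeModel(kind="constant", base_Ne=pod.model.base_Ne
                                 if pod.model is not None else 10_000.0)
    obs_profile = profile(pod, statistics)
    dists = estimate_distributions(pod, null_model, n_reps, rng, statistics)
    out: dict[str, TestResult] = {}
    for s in statistics:
        obs = obs_profile.across_loci[s]
        if obs is None or not np.isfinite(obs):
            continue
        null = dists[s].values
        N = null.size
        if N == 0:
            continue
        p_up = (np.count_nonzero(null >= obs) + 1) / (N + 1)
        p_lo = (np.count_nonzero(null <= obs) + 1) / (N + 1)
        out[s] = TestResult(
            statistic=s,
            observed=obs,
            p_lower=p_lo,
            p_upper=p_up,
            alpha=alpha[s],
            inference=_classify(p_lo, p_up, alpha[s], two_sided),
        )
    return out


def decline_count(
    scenario: FusionScenario,
    comp: DatasetComposition,
    n_replicate_pods: int,
    rng: np.random.Generator | np.random.SeedSequence | int,
    mm: MutationModel | None = None,
    n_reps: int = 1000,
    statistics: Sequence[str] = STATISTICS,
    two_sided: bool = True,
) -> dict[str, int]:
    """How many of ``n_replicate_pods`` datasets falsely infer decline.

    Simulates independent datasets under the fusion scenario, tests each
    against size constancy, and counts decline inferences per statistic.
    """
    from .coalsim import simulate_pod  # local import to avoid cycle noise

    mm = mm or MutationModel()
    if isinstance(rng, np.random.Generator):
        seed_seq = rng.bit_generator.seed_seq.spawn(1)[0]
    elif isinstance(rng, np.random.SeedSequence):
        seed_seq = rng
    else:
        seed_seq = np.random.SeedSequence(rng)
    counts = {s: 0 for s in statistics}
    for child in seed_seq.spawn(n_replicate_pods):
        pod_seq, null_seq = child.spawn(2)
        pod = simulate_pod(scenario, comp, mm, pod_seq)
        results = test_pod(
            pod, n_reps, np.random.default_rng(null_seq), statistics,
            two_sided=two_sided,
        )
        for s, res in results.items():
            if res.inference == "decline":
                counts[s] += 1
    return counts
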