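"""Distinguishability of lineage fusion as CI non-overlap.

Distinguishability is scored as the proportion of the fusion scenario's
central 90% CI that is *not* covered by a competing non-fusion scenario's
90% CI — equivalently the Lebesgue measure of the fusion interval minus its
intersection with the competitor, over the fusion interval's width:

* disjoint intervals (either direction)           -> 1
* competitor overhangs only the lower end         -> (FU - NU) / (FU - FL)
* competitor overhangs only the upper end         -> (NL - FL) / (FU - FL)
* competitor nested inside the fusion CI          -> sum of both components
* fusion CI nested inside the competitor          -> 0

where (FL, FU) and (NL, NU) are the fusion and non-fusion bounds.
Intervals that merely touch at an endpoint count as disjoint (a
measure-zero tie).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .nulldist import ConfidenceInterval

__all__ = ["DistinguishabilityResult", "unique_proportion", "distinguishability_grid"]

OVERLAP_CASES = (
    "disjoint",
    "partial_upper",
    "partial_lower",
    "nested_nonfuse_inside",
    "fuse_inside_nonfuse",
    "identical",
)


@dataclass(frozen=True)
class DistinguishabilityResult:
    statistic: str
    nonfusion_model: str
    unique_proportion: float
    overlap_case: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.unique_proportion <= 1.0):
            raise ValueError("unique_proportion must lie in [0, 1]")
        if self.overlap_case not in OVERLAP_CASES:
            raise ValueError(f"unknown overlap case {self.overlap_case!r}")


def unique_proportion(
    fuse: ConfidenceInterval,
    nonfuse: ConfidenceInterval,
    statistic: str = "",
    nonfusion_model: str = "",
) -> DistinguishabilityResult:
    """Proportion of the fusion CI not overlapped by the non-fusion CI."""
    fl, fu = fuse.lower, fuse.upper
    nl, nu = nonfuse.lower, nonfuse.upper
    width = fu - fl
    if width <= 0:
        raise ValueError("fusion CI has zero width; unique proportion undefined")

    if fl == nl and fu == nu:
        case, value = "identical", 0.0
    elif nl >= fu or nu <= fl:
        case, value = "disjoint", 1.0
    else:
        upper_part = max(0.0, fu - nu) / width
        lower_part = max(0.0, nl - fl) / width
        value = min(1.0, upper_part + lower_part)
        if upper_part > 0 and lower_part > 0:
            case = "nested_nonfuse_inside"
        elif upper_part > 0:
            case = "partial_upper"
        elif lower_part > 0:
            case = "partial_lower"
        else:
            case = "fuse_inside_nonfuse"
    return DistinguishabilityResult(
        statistic=statistic,
        nonfusion_model=nonfusion_model,
        unique_proportion=value,
        overlap_case=case,
    )


def distinguishability_grid(
    fusion_CIs: Mapping[str, ConfidenceInterval],
    nonfusion_CIs: Mapping[tuple[str, str], ConfidenceInterval],
    statistics: list[str] | None = None,
    models: list[str] | None = None,
) -> pd.DataFrame:
    """Unique-proportion table: one row per statistic, one column per model.

    ``nonfusion_CIs`` is keyed by ``(model_name, statistic)``.  Cells whose
    CI is missing on either side are NaN (flagged, never silently dropped).
    """
    if statistics is None:
        statistics = list(fusion_CIs)
    if models is None:
        models = sorted({m for (m, _) in nonfusion_CIs})
    grid = pd.DataFrame(index=statistics, columns=models, dtype=float)
    for stat in statistics:
        fci = fusion_CIs.get(stat)
        for model in models:
            nci = nonfusion_CIs.get((model, stat))
            if fci is None or nci is None:
                continue
            grid.loc[stat, model] = unique_proportion(
                fci, nci, statistic=stat, nonfusion_model=model
            ).unique_proportion
    grid.index.name = "statistic"
    return grid
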