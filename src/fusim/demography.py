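"""Demographic models for the lineage-fusion simulation study.

Two kinds of history are considered, both with piecewise-constant diploid
effective sizes and instantaneous events, in continuous time measured in
generations before present (present = 0):

* :class:`FusionScenario` — two sister populations of size ``base_Ne``
  diverge at ``t_div``, evolve in isolation, then merge instantaneously at
  ``t_fuse`` into a single panmictic deme (again of size ``base_Ne``) from
  which all sampling takes place at the present.  The ratio
  ``(t_div - t_fuse) / t_fuse`` — divergence duration over post-fusion lag —
  is the scenario's D:L ratio and controls how detectable fusion is.

* :class:`SingleDemeModel` — a single panmictic deme whose size changes by a
  step ``factor`` at one event time (growth/decline) or over a bounded
  interval (bottleneck), or never changes (constant).

The canonical study grid consists of four fusion scenarios (D:L in
{1, 3, 5, 9}), ten non-fusion comparison models (constant; growth x2/x3/x4;
bottleneck and decline to 1/2, 1/3, 1/4 of base size), and nine dataset
compositions that partition a fixed 800,000 bp of sequencing effort among
sampled alleles, locus length, and locus count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Union

__all__ = [
    "FusionScenario",
    "SingleDemeModel",
    "DatasetComposition",
    "DemographicModel",
    "canonical_fusion_scenarios",
    "canonical_nonfusion_models",
    "canonical_compositions",
    "model_from_dict",
    "save_models_yaml",
    "load_models_yaml",
]

#: Total sequencing effort per pseudo-observed dataset, in base pairs.
POD_TOTAL_BP = 800_000


class ModelValidationError(ValueError):
    """Raised when a demographic model violates its structural invariants."""


@dataclass(frozen=True)
class FusionScenario:
    """Complete merging of two long-diverged sister populations.

    Parameters
    ----------
    base_Ne
        Diploid effective size of every deme (ancestral, both sisters, and
        the merged pool), in individuals.
    t_div
        Time of the initial divergence, generations before present.
    t_fuse
        Time of the instantaneous merge, generations before present.
    mix
        Fraction of the merged gene pool contributed by sister population A.
        Backward in time, each sampled lineage that is still uncoalesced at
        ``t_fuse`` is assigned to A with this probability.
    sample_time
        When the gene pool is sampled (always the present here).
    """

    base_Ne: float = 10_000.0
    t_div: float = 20_000.0
    t_fuse: float = 10_000.0
    mix: float = 0.5
    sample_time: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.base_Ne >= 2:
            raise ModelValidationError(f"base_Ne must be >= 2, got {self.base_Ne}")
        if not (self.t_div > self.t_fuse > 0):
            raise ModelValidationError(
                f"need t_div > t_fuse > 0, got t_div={self.t_div}, t_fuse={self.t_fuse}"
            )
        if not (0.0 <= self.mix <= 1.0):
            raise ModelValidationError(f"mix must lie in [0, 1], got {self.mix}")
        if self.sample_time != 0.0:
            raise ModelValidationError("sampling is only supported at the present")

    @property
    def dl_ratio(self) -> float:
        """Divergence duration over post-fusion lag, (t_div - t_fuse) / t_fuse."""
        return (self.t_div - self.t_fuse) / self.t_fuse

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kind"] = "fusion"
        return d


_SINGLE_DEME_KINDS = ("constant", "growth", "decline", "bottleneck")


@dataclass(frozen=True)
class SingleDemeModel:
    """One panmictic deme with at most one step change in size.

    ``factor`` multiplies ``base_Ne`` during/after the event looking forward
    in time: a growth model has size ``factor * base_Ne`` from ``t_event`` to
    the present and ``base_Ne`` before; a bottleneck has the reduced size on
    ``(t_end, t_start)`` only.
    """

    kind: str = "constant"
    base_Ne: float = 10_000.0
    factor: float = 1.0
    t_event: float | None = None
    t_start: float | None = None
    t_end: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _SINGLE_DEME_KINDS:
            raise ModelValidationError(f"unknown model kind {self.kind!r}")
        if not self.base_Ne >= 2:
            raise ModelValidationError(f"base_Ne must be >= 2, got {self.base_Ne}")
        if self.kind == "constant":
            if self.factor != 1.0:
                raise ModelValidationError("constant model requires factor = 1")
        elif self.kind == "growth":
            if not self.factor > 1.0:
                raise ModelValidationError("growth requires factor > 1")
            if self.t_event is None or self.t_event <= 0:
                raise ModelValidationError("growth requires t_event > 0")
        elif self.kind == "decline":
            if not 0.0 < self.factor < 1.0:
                raise ModelValidationError("decline requires 0 < factor < 1")
            if self.t_event is None or self.t_event <= 0:
                raise ModelValidationError("decline requires t_event > 0")
        elif self.kind == "bottleneck":
            if not 0.0 < self.factor < 1.0:
                raise ModelValidationError("bottleneck requires 0 < factor < 1")
            if (
                self.t_start is None
                or self.t_end is None
                or not (self.t_start > self.t_end > 0)
            ):
                raise ModelValidationError("bottleneck requires t_start > t_end > 0")

    def size_at(self, t: float) -> float:
        """Diploid size at time ``t`` generations before present."""
        if self.kind == "constant":
            return self.base_Ne
        if self.kind in ("growth", "decline"):
            return self.factor * self.base_Ne if t < self.t_event else self.base_Ne
        # bottleneck
        if self.t_end <= t < self.t_start:
            return self.factor * self.base_Ne
        return self.base_Ne

    def epochs(self) -> list[tuple[float, float, float]]:
        """Size history as ``(start, end, N)`` intervals, backward in time.

        ``end`` of the last epoch is ``inf``.
        """
        N = self.base_Ne
        if self.kind == "constant":
            return [(0.0, float("inf"), N)]
        if self.kind in ("growth", "decline"):
            return [(0.0, self.t_event, self.factor * N), (self.t_event, float("inf"), N)]
        return [
            (0.0, self.t_end, N),
            (self.t_end, self.t_start, self.factor * N),
            (self.t_start, float("inf"), N),
        ]

    def to_dict(self) -> dict:
        return asdict(self)


DemographicModel = Union[FusionScenario, SingleDemeModel]


@dataclass(frozen=True)
class DatasetComposition:
    """How a fixed sequencing budget is split among alleles, length, loci."""

    n_alleles: int
    locus_length: int
    n_loci: int
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("n_alleles", "locus_length", "n_loci"):
            v = getattr(self, attr)
            if not (isinstance(v, int) and v > 0):
                raise ModelValidationError(f"{attr} must be a positive integer, got {v!r}")
        if self.n_alleles % 2 != 0:
            raise ModelValidationError("n_alleles must be even (diploid samples)")

    @property
    def total_bp(self) -> int:
        return self.n_alleles * self.locus_length * self.n_loci

    def to_dict(self) -> dict:
        return asdict(self)


def canonical_fusion_scenarios() -> list[FusionScenario]:
    """The four study fusion scenarios, in increasing D:L order (1, 3, 5, 9)."""
    return [
        FusionScenario(
            base_Ne=10_000.0,
            t_div=t_div,
            t_fuse=10_000.0,
            mix=0.5,
            name=f"DL{int((t_div - 10_000) // 10_000)}",
        )
        for t_div in (20_000.0, 40_000.0, 60_000.0, 100_000.0)
    ]


def canonical_nonfusion_models(base_Ne: float = 10_000.0) -> list[SingleDemeModel]:
    """The ten comparison models, in the study's plotting order.

    Constant size; growth to 2x, 3x, 4x; bottleneck to 1/2, 1/3, 1/4;
    decline to 1/2, 1/3, 1/4.  Growth/decline step at ``1 * base_Ne``
    generations before present; bottlenecks span ``(1 * base_Ne,
    2 * base_Ne)``.  The printed "0.33x"/"0.25x" severities are stored as
    exact thirds and quarters.
    """
    t1 = 1.0 * base_Ne
    t2 = 2.0 * base_Ne
    models = [SingleDemeModel(kind="constant", base_Ne=base_Ne, name="constant")]
    for f in (2.0, 3.0, 4.0):
        models.append(
            SingleDemeModel(
                kind="growth", base_Ne=base_Ne, factor=f, t_event=t1, name=f"growth_{f:g}x"
            )
        )
    for f, label in ((0.5, "0.5"), (1.0 / 3.0, "0.33"), (0.25, "0.25")):
        models.append(
            SingleDemeModel(
                kind="bottleneck",
                base_Ne=base_Ne,
                factor=f,
                t_start=t2,
                t_end=t1,
                name=f"bottleneck_{label}x",
            )
        )
    for f, label in ((0.5, "0.5"), (1.0 / 3.0, "0.33"), (0.25, "0.25")):
        models.append(
            SingleDemeModel(
                kind="decline", base_Ne=base_Ne, factor=f, t_event=t1, name=f"decline_{label}x"
            )
        )
    return models


#: (alleles, locus length bp, number of loci) for POD-1 .. POD-9.
_CANONICAL_COMPOSITIONS = [
    (10, 800, 100),
    (10, 1600, 50),
    (10, 8000, 10),
    (20, 400, 100),
    (20, 800, 50),
    (20, 4000, 10),
    (40, 200, 100),
    (40, 400, 50),
    (40, 2000, 10),
]


def canonical_compositions() -> list[DatasetComposition]:
    """The nine dataset compositions, each totalling 800,000 bp."""
    out = []
    for i, (n, L, k) in enumerate(_CANONICAL_COMPOSITIONS, start=1):
        comp = DatasetComposition(n_alleles=n, locus_length=L, n_loci=k, name=f"POD-{i}")
        assert comp.total_bp == POD_TOTAL_BP
        out.append(comp)
    return out


def model_from_dict(d: dict) -> DemographicModel:
    """Rebuild a model from its ``to_dict`` form (plain YAML/JSON payload)."""
    d = dict(d)
    kind = d.pop("kind", None)
    if kind == "fusion":
        return FusionScenario(**d)
    if kind in _SINGLE_DEME_KINDS:
        return SingleDemeModel(kind=kind, **{k: v for k, v in d.items()})
    raise ModelValidationError(f"cannot rebuild model of kind {kind!r}")


def save_models_yaml(models: list[DemographicModel], path) -> None:
    """Write models to a plain-text YAML config (keys mirror field names)."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump([m.to_dict() for m in models], fh, sort_keys=False)


def load_models_yaml(path) -> list[DemographicModel]:
    """Read a YAML config written by :func:`save_models_yaml`."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [model_from_dict(d) for d in payload]
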