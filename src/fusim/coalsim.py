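"""Coalescent simulation of genealogies and haplotype data.

This module is the data generator for the whole study.  It serves two
distinct simulation paths, mirroring how multi-locus haplotype studies are
actually run:

* **Pseudo-observed datasets (PODs)** — finite-site nucleotide alignments.
  A genealogy is simulated in generation time under a demographic model,
  and sequences evolve along it under HKY with a proportion of invariant
  sites and discrete-gamma rate heterogeneity (:func:`apply_mutations`).

* **Theta-seeded null replicates** — infinite-sites 0/1 haplotype patterns
  used to build null distributions of the neutrality statistics.  Here the
  genealogy is the same, but mutations are placed as a Poisson process with
  per-locus Watterson theta supplied externally, the convention of
  single-population coalescent machinery in DnaSP/MLCOALSIM
  (:func:`simulate_null_replicate`).

Both paths share :func:`simulate_genealogy`, a structured coalescent with
piecewise-constant deme sizes.  Backward in time under a fusion scenario,
the sample starts in one panmictic deme; at ``t_fuse`` every surviving
lineage is independently assigned to sister population A (probability
``mix``) or B, between ``t_fuse`` and ``t_div`` coalescence happens only
within a sister population, and at ``t_div`` the sisters merge into the
single ancestral deme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .demography import (
    DatasetComposition,
    DemographicModel,
    FusionScenario,
    SingleDemeModel,
)
from .hky import MutationModel, evolve_sequences

__all__ = [
    "Genealogy",
    "HaplotypeDataset",
    "SegPatterns",
    "MutationModel",
    "simulate_genealogy",
    "apply_mutations",
    "simulate_pod",
    "simulate_null_replicate",
    "locus_rngs",
]


@dataclass
class Genealogy:
    """A rooted binary coalescent tree over ``n_leaves`` contemporaneous samples.

    Nodes ``0 .. n_leaves-1`` are the sampled alleles (time 0); internal
    nodes ``n_leaves .. 2*n_leaves-2`` are created in coalescence order, so
    every parent index exceeds its children's and the last node is the root.
    Times are generations before present.
    """

    parent: np.ndarray  # int, length 2n-1, parent[root] == -1
    time: np.ndarray  # float, length 2n-1
    n_leaves: int

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (generations)."""
        idx = np.arange(self.n_nodes - 1)
        return self.time[self.parent[idx]] - self.time[idx]

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_masks(self) -> np.ndarray:
        """Bitmask of descendant leaves below each node (uint64, n <= 64)."""
        if self.n_leaves > 64:
            raise ValueError("leaf bitmasks support at most 64 samples")
        masks = np.zeros(self.n_nodes, dtype=np.uint64)
        masks[: self.n_leaves] = np.uint64(1) << np.arange(self.n_leaves, dtype=np.uint64)
        for v in range(self.n_nodes - 1):
            masks[self.parent[v]] |= masks[v]
        return masks

    def validate(self) -> None:
        n = self.n_leaves
        if self.parent.shape != (2 * n - 1,) or self.time.shape != (2 * n - 1,):
            raise ValueError("inconsistent array shapes")
        if np.any(self.time[:n] != 0.0):
            raise ValueError("leaves must sit at the present")
        if np.any(np.diff(self.time[n:]) < 0):
            raise ValueError("internal node times must be nondecreasing toward the root")
        if self.parent[self.root] != -1:
            raise ValueError("root must have parent -1")
        lengths = self.branch_lengths()
        if np.any(lengths < 0):
            raise ValueError("negative branch length")


class _DrawBuffer:
    """Buffered mean-1 exponential and uniform draws (cuts RNG call overhead)."""

    __slots__ = ("rng", "exp", "uni", "ei", "ui")

    def __init__(self, rng: np.random.Generator, n_hint: int):
        self.rng = rng
        m = max(2 * n_hint + 16, 32)
        self.exp = rng.exponential(size=m)
        self.uni = rng.random(size=m)
        self.ei = 0
        self.ui = 0

    def next_exp(self) -> float:
        if self.ei >= self.exp.size:
            self.exp = self.rng.exponential(size=self.exp.size)
            self.ei = 0
        v = self.exp[self.ei]
        self.ei += 1
        return v

    def next_uni(self) -> float:
        if self.ui >= self.uni.size:
            self.uni = self.rng.random(size=self.uni.size)
            self.ui = 0
        v = self.uni[self.ui]
        self.ui += 1
        return v


def _coalesce_step(active: list[int], buf: _DrawBuffer) -> tuple[int, int]:
    """Remove a uniformly random pair from ``active``; return it."""
    k = len(active)
    i = int(buf.next_uni() * k)
    j = int(buf.next_uni() * (k - 1))
    if j >= i:
        j += 1
    if i > j:
        i, j = j, i
    b = active.pop(j)
    a = active.pop(i)
    return a, b


def _sim_single_deme(
    epochs: list[tuple[float, float, float]], n_alleles: int, rng: np.random.Generator
) -> Genealogy:
    """Kingman coalescent with piecewise-constant diploid size."""
    n = n_alleles
    buf = _DrawBuffer(rng, n)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    nxt = n
    t = 0.0
    ei = 0
    while len(active) > 1:
        start, end, N = epochs[ei]
        k = len(active)
        rate = k * (k - 1) / 2.0 / (2.0 * N)
        wait = buf.next_exp() / rate
        if t + wait < end:
            t += wait
            a, b = _coalesce_step(active, buf)
            parent[a] = nxt
            parent[b] = nxt
            time[nxt] = t
            active.append(nxt)
            nxt += 1
        else:
            t = end
            ei += 1
    return Genealogy(parent=parent, time=time, n_leaves=n)


def _sim_fusion(
    scen: FusionScenario, n_alleles: int, rng: np.random.Generator
) -> Genealogy:
    n = n_alleles
    N = scen.base_Ne
    buf = _DrawBuffer(rng, n)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    nxt = n

    def run_phase(
        demes: list[list[int]], t: float, t_end: float, nxt: int
    ) -> tuple[float, int]:
        while sum(len(d) > 1 for d in demes) > 0:
            rates = [len(d) * (len(d) - 1) / 2.0 / (2.0 * N) for d in demes]
            total = sum(rates)
            wait = buf.next_exp() / total
            if t + wait >= t_end:
                return t_end, nxt
            t += wait
            # choose deme proportionally to its coalescence rate
            u = buf.next_uni() * total
            di = 0
            acc = rates[0]
            while u > acc:
                di += 1
                acc += rates[di]
            a, b = _coalesce_step(demes[di], buf)
            parent[a] = nxt
            parent[b] = nxt
            time[nxt] = t
            demes[di].append(nxt)
            nxt += 1
        return t_end, nxt

    # merged panmictic phase: present back to t_fuse
    demes = [list(range(n))]
    t, nxt = run_phase(demes, 0.0, scen.t_fuse, nxt)
    lineages = demes[0]
    if len(lineages) > 1:
        # split surviving lineages between the two sister populations
        assign = rng.random(len(lineages)) < scen.mix
        deme_a = [x for x, in_a in zip(lineages, assign) if in_a]
        deme_b = [x for x, in_a in zip(lineages, assign) if not in_a]
        t, nxt = run_phase([deme_a, deme_b], scen.t_fuse, scen.t_div, nxt)
        lineages = deme_a + deme_b
    if len(lineages) > 1:
        # ancestral panmictic deme
        demes = [lineages]
        t, nxt = run_phase(demes, scen.t_div, math.inf, nxt)
    return Genealogy(parent=parent, time=time, n_leaves=n)


def simulate_genealogy(
    model: DemographicModel, n_alleles: int, rng: np.random.Generator
) -> Genealogy:
    """Simulate one coalescent genealogy under ``model``.

    Time is in generations; the pairwise coalescence rate within a deme of
    diploid size ``N`` is ``1 / (2N)`` per generation.
    """
    if n_alleles < 2:
        raise ValueError("need at least 2 sampled alleles")
    if isinstance(model, FusionScenario):
        return _sim_fusion(model, n_alleles, rng)
    if isinstance(model, SingleDemeModel):
        return _sim_single_deme(model.epochs(), n_alleles, rng)
    raise TypeError(f"unsupported model type {type(model)!r}")


def apply_mutations(
    genealogy: Genealogy,
    mm: MutationModel,
    locus_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve sequences along ``genealogy`` under the finite-site HKY model.

    Returns an ``(n_alleles, locus_length)`` uint8 matrix with bases coded
    A=0, C=1, G=2, T=3.
    """
    if locus_length < 1:
        raise ValueError("locus_length must be >= 1")
    genealogy.validate()
    return evolve_sequences(genealogy, mm, locus_length, rng)


@dataclass
class HaplotypeDataset:
    """A multi-locus phase-known haplotype dataset (a POD).

    ``loci`` holds one ``(n_alleles, locus_length)`` uint8 base-code matrix
    per independent, non-recombining locus.
    """

    loci: list[np.ndarray]
    model: DemographicModel | None = None
    composition: DatasetComposition | None = None
    seed: int | None = None

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_alleles(self) -> int:
        return int(self.loci[0].shape[0])


def locus_rngs(seed_seq: np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    """Deterministic independent child streams, one per locus."""
    return [np.random.default_rng(s) for s in seed_seq.spawn(n)]


def simulate_pod(
    scenario: DemographicModel,
    comp: DatasetComposition,
    mm: MutationModel,
    rng: np.random.Generator | np.random.SeedSequence | int,
) -> HaplotypeDataset:
    """Simulate a full POD: one independent genealogy + alignment per locus."""
    if isinstance(rng, np.random.Generator):
        seed_seq = rng.bit_generator.seed_seq.spawn(1)[0]
    elif isinstance(rng, np.random.SeedSequence):
        seed_seq = rng
    else:
        seed_seq = np.random.SeedSequence(rng)
    loci = []
    for locus_rng in locus_rngs(seed_seq, comp.n_loci):
        gen = simulate_genealogy(scenario, comp.n_alleles, locus_rng)
        loci.append(apply_mutations(gen, mm, comp.locus_length, locus_rng))
    return HaplotypeDataset(loci=loci, model=scenario, composition=comp)


@dataclass
class SegPatterns:
    """Infinite-sites segregating patterns for one locus.

    Each site is the set of sampled alleles carrying the derived mutation,
    stored as a uint64 bitmask over ``n`` leaves.  This is the minimal
    representation from which all six neutrality statistics can be computed.
    """

    n: int
    masks: np.ndarray  # uint64, one per segregating site

    @property
    def S(self) -> int:
        return int(self.masks.size)

    def to_matrix(self) -> np.ndarray:
        """(n, S) uint8 0/1 haplotype matrix."""
        if self.S == 0:
            return np.zeros((self.n, 0), dtype=np.uint8)
        bits = (
            self.masks[None, :] >> np.arange(self.n, dtype=np.uint64)[:, None]
        ) & np.uint64(1)
        return bits.astype(np.uint8)


def simulate_null_replicate(
    model: DemographicModel,
    n_alleles: int,
    theta: float,
    rng: np.random.Generator,
) -> SegPatterns:
    """One theta-seeded infinite-sites locus under ``model``.

    ``theta`` is Watterson's theta per locus (4*Ne*mu*L), so mutations fall
    on the genealogy at rate ``theta / 2`` per lineage per ``2 * base_Ne``
    generations; under constant size this makes the expected pairwise
    difference equal ``theta``.  Event times inside ``model`` are converted
    to coalescent units through the model's own ``base_Ne``; ``theta`` only
    scales the mutation process.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    gen = simulate_genealogy(model, n_alleles, rng)
    if theta == 0:
        return SegPatterns(n=n_alleles, masks=np.zeros(0, dtype=np.uint64))
    lengths = gen.branch_lengths()  # generations
    two_n = 2.0 * model.base_Ne
    total = lengths.sum() / two_n  # coalescent units
    n_mut = rng.poisson(theta / 2.0 * total)
    if n_mut == 0:
        return SegPatterns(n=n_alleles, masks=np.zeros(0, dtype=np.uint64))
    cum = np.cumsum(lengths)
    branch = np.searchsorted(cum, rng.random(n_mut) * cum[-1], side="right")
    masks = gen.leaf_masks()[branch]
    # a mutation on the branch above the root's child subtending all leaves
    # would be fixed, but such branches do not exist (root excluded above).
    full = np.uint64((1 << n_alleles) - 1)
    keep = (masks != 0) & (masks != full)
    return SegPatterns(n=n_alleles, masks=masks[keep])
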