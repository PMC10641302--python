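# Methods

`fusim` asks a single question by simulation: when two populations that
diverged long ago merge back into one panmictic gene pool ("lineage
fusion"), does the merged population's genetic variation carry a signature
that standard single-population analyses could recognise — or does it
masquerade as something else, in particular as population decline?

## Demographic models

All histories use piecewise-constant diploid effective sizes and
instantaneous events, in continuous time measured in generations before
present.

**Fusion scenario.** Two sister populations, each of diploid size
N_e = 10,000, split from a common ancestor (also N_e) at `t_div`
generations before present and merge instantaneously at `t_fuse` = 10,000
generations, each contributing half of the merged pool (`mix` = 0.5).
Sampling happens only at the present. Backward in time the coalescent is:
panmictic from 0 to `t_fuse`; at `t_fuse` each surviving lineage is
independently assigned to sister A with probability `mix`; between `t_fuse`
and `t_div` coalescence is only within a sister; at `t_div` the sisters
merge into the ancestral deme. The scenario's key control is the **D:L
ratio** — divergence duration (t_div − t_fuse) over post-fusion lag
(t_fuse) — spanning 1, 3, 5, 9 via t_div ∈ {20, 40, 60, 100} thousand
generations. Larger D:L means more private variation accumulated before
the merge relative to the time the merged pool has had to erase it.

**Non-fusion comparison models.** Ten single-deme histories at base
N_e = 10,000: constant size; step growth to 2/3/4× at 1·N_e generations;
decline to 1/2, 1/3, 1/4 at 1·N_e generations; and bottlenecks to the same
three severities spanning (1·N_e, 2·N_e) generations. The printed "0.33×"
and "0.25×" severities are stored as exact thirds and quarters. Growth and
decline are single steps (present-day size `factor`·N_e from the event
time forward to the present), which is the simplest reading consistent
with a one-event history; continuous exponential change is out of scope.

**Dataset compositions.** Sequencing effort is fixed at 800,000 bp per
dataset and partitioned along three axes: sampled alleles (10/20/40 = 5,
10, 20 diploids), locus length (200–8,000 bp), and locus count
(10/50/100), giving nine compositions. The canonical grid also repeats
the 40-allele/400 bp/50-locus composition five times per scenario (rows
b–e extra), for 52 datasets total.

## Data generation

Two simulation paths coexist deliberately, mirroring the two ways
multi-locus studies actually produce and analyse data:

1. **Pseudo-observed datasets (PODs)** are finite-site nucleotide
   alignments. Each locus gets its own coalescent genealogy in generation
   time; sequences then evolve along it under HKY with equal base
   frequencies, transition/transversion ratio 2 (HKY κ = 4 at equal
   frequencies), 10% invariant sites, two-category discrete-gamma rate
   heterogeneity, and μ = 1 × 10⁻⁷ substitutions/site/generation. With
   equal base frequencies HKY reduces to Kimura's two-parameter model, so
   branch substitution probabilities have a closed form and each site's
   end state is drawn exactly — no event-by-event simulation, but the same
   process distribution. Gamma category rates are the conditional means of
   the equal-probability quantile bands (Yang's discrete gamma),
   renormalised to mean 1 over variable sites; the gamma shape is not
   fixed by the study design, so it defaults to 1.0 and is exposed in the
   mutation-model configuration (haplotype-diversity levels are only
   weakly sensitive to it at these mutation rates). Loci are
   non-recombining internally and independent of each other (separate
   genealogies, deterministic per-locus RNG streams spawned from one root
   seed).

2. **Theta-seeded null replicates** are infinite-sites 0/1 haplotype
   patterns used for the statistic null distributions, the convention of
   single-population coalescent machinery in DnaSP/MLCOALSIM: each locus
   is re-simulated with mutations dropped at rate θ/2 per lineage per 2N_e
   generations, with θ the locus's observed Watterson estimate (per gene,
   not per site). Event times inside a model are converted to coalescent
   units through the model's base N_e = 10,000; θ only scales mutation.
   Under constant size this makes E[pairwise differences] = θ exactly.

The asymmetry — finite-site HKY for data, infinite sites for nulls — is
intentional: it reproduces the workflow in which data are simulated (or
sequenced) with a realistic mutation model but analysed against idealised
coalescent nulls.

## Summary statistics

Six neutrality statistics per locus, averaged across loci (loci where a
statistic is undefined — no segregating sites; fewer than two biallelic
sites for Z_nS; no non-singleton sites for Y* — are excluded from the
average and counted):

* **Tajima's D**: (K − S/a_n) normalised, K the mean pairwise difference,
  S segregating sites, a_n = Σ 1/i.
* **Fu & Li's F\***: K against folded singletons η_S (sites whose minority
  state is carried by exactly one sequence), numerator
  K − ((n−1)/n)·η_S. The variance constants are derived *exactly* from
  the frequency-spectrum covariance matrix of Fu (1995) rather than taken
  from the printed approximations, which disagree among published sources;
  the same covariance machinery reproduces Tajima's printed constants to
  machine precision, which is the correctness check.
* **Fu's F_S**: ln(S′/(1−S′)) with S′ = P(≥ H_N haplotypes | θ = θ_π)
  under the Ewens sampling formula, computed with unsigned Stirling numbers
  of the first kind entirely in log space (stable beyond n = 100).
* **Ramos-Onsins & Rozas's R₂**: √(Σ(Uᵢ − K/2)²/n)/S with Uᵢ the number
  of singletons carried by sequence i.
* **Achaz's Y\***: the π-versus-Watterson contrast recomputed after
  discarding singleton classes (folded), normalised through the same Fu
  (1995) covariance framework with θ̂ = S*/a* and
  θ̂² = S*(S*−1)/(a*² + b*) plug-ins. At n = 5 the two usable frequency
  classes receive identical weights and the contrast is identically zero,
  so Y* is reported as undefined there (and for n < 5).
* **Kelly's Z_nS**: mean r² over all pairs of biallelic segregating
  sites; sites with more than two states are excluded from pairs.

Multiallelic columns count once toward S and any state mismatch counts in
pairwise differences. Nei's haplotype diversity Hd = n/(n−1)(1 − Σpᵢ²)
summarises each locus, with the across-locus variance of per-locus Hd
reported alongside the across-locus mean.

## Null distributions, distinguishability, hypothesis tests

For one dataset and one candidate model, the distribution of each
statistic's across-locus mean is estimated from replicate whole-dataset
simulations (canonically 1000; a 200-replicate profile is used for
wide-grid runs) and summarised by its central 90% CI — 5th and 95th
empirical percentiles with linear interpolation (Hyndman–Fan type 7), so
CIs are bit-reproducible given a seed.

**Distinguishability** of fusion against a competitor is the proportion of
the fusion CI not covered by the competitor's CI — equivalently the
Lebesgue measure of the set difference over the fusion CI's width: 1 when
disjoint (touching endpoints count as disjoint; a measure-zero tie), a
single tail proportion for one-sided offsets, the sum of both tails when
the competitor nests inside the fusion CI, and 0 when the fusion CI nests
inside the competitor's.

**Hypothesis testing** mimics the practitioner who only entertains size
constancy: the observed across-locus mean is compared with the empirical
constant-size null; p-values use (r+1)/(N+1); two-sided tests put α/2 per
tail with α = 0.05 (0.02 for F_S, the statistic's conventional level).
Significantly positive D/F*/F_S/Y* or significantly large R₂/Z_nS read as
decline, the mirror tails as growth. A one-tailed-at-α variant is exposed
for sensitivity analysis because the original tooling's convention is not
documented.

## What the generator does and does not emulate

The generator produces phase-known, error-free, alignment-perfect
haplotypes with free recombination between loci and none within, no
selection, no migration during divergence, and exactly equal mixing.
Passing tests therefore demonstrate properties of the inference machinery
under the stated model, not robustness to phasing error, sequencing error,
intralocus recombination, or unequal admixture — all of which are real in
empirical data.

## Numerical and design notes

* Exactness of the spectrum covariance matrix is enforced by tests:
  Σσᵢⱼ = b_n (the Watterson variance identity) and recovery of Tajima's
  e₁/e₂ constants.
* Undefined statistic values propagate as None/NaN and are excluded from
  means with counts reported; replicates where a statistic is defined at
  no locus are dropped from that statistic's null distribution.
* All randomness derives from one root seed through spawned
  `SeedSequence` streams: per-locus streams for datasets, per-cell streams
  for grids, so any cell is reproducible in isolation and results are
  bit-identical across runs at the same seed.
* Simulated grid sizes in the shipped analyses/tests (e.g. 200-replicate
  nulls for wide grids, a four-cell distinguishability subset, 10
  replicate datasets per benchmark diversity cell) are the package's
  scaled defaults; canonical 1000-replicate runs are available through
  the configuration.

## Known limitations and observed deviations

* Under the stated parameters, the simulated haplotype-diversity gradient
  across D:L ratios is flatter than the study's printed per-cell values
  for the 40-allele compositions (the printed values rise more steeply
  with D:L). An independent re-implementation of the same demography in
  msprime agrees with this package's simulator, so the difference is
  attributable to the original data-generation tooling rather than to the
  model as stated. Grid-level summaries (grand mean ≈ 0.73–0.75, range
  ≈ 0.43–0.98) and all directional conclusions reproduce.
* The constancy test's empirical nulls are seeded with θ̂ from the same
  data; for R₂ (and mildly Z_nS) this plug-in conditioning is slightly
  conservative (two-sided rejection ≈ 0.03 at nominal 0.05 under a true
  constant history). Rejection never exceeds the nominal level.
* CI summaries cannot represent modality differences in the statistic
  distributions; density-overlap measures are deliberately out of scope.
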