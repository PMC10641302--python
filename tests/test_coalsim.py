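"""Simulator correctness: coalescent expectations, mutation-model
behaviour, reproducibility, and an msprime cross-check of the fusion
demography."""

import numpy as np
import pytest

from fusim.demography import DatasetComposition, FusionScenario, SingleDemeModel
from fusim.hky import MutationModel, discrete_gamma_rates
from fusim.coalsim import (
    apply_mutations,
    simulate_genealogy,
    simulate_null_replicate,
    simulate_pod,
)
from fusim.sumstats import harmonic_sums, site_summary, summary_from_patterns

CONST = SingleDemeModel(kind="constant", base_Ne=10_000)


class TestGenealogy:
    def test_pairwise_tmrca_matches_closed_form(self, rng):
        # E[T2] = 2N generations for a diploid Wright-Fisher coalescent
        times = [simulate_genealogy(CONST, 2, rng).tmrca for _ in range(4000)]
        se = 2e4 / np.sqrt(len(times))
        assert np.mean(times) == pytest.approx(20_000, abs=3 * se)

    def test_genealogies_are_valid_trees(self, rng):
        models = [
            CONST,
            SingleDemeModel(kind="growth", factor=4, t_event=10_000),
            SingleDemeModel(kind="bottleneck", factor=0.25, t_start=20_000, t_end=10_000),
            FusionScenario(t_div=100_000, t_fuse=10_000),
        ]
        for model in models:
            for _ in range(10):
                g = simulate_genealogy(model, 12, rng)
                g.validate()
                assert g.total_length() > 0
                masks = g.leaf_masks()
                assert masks[g.root] == (1 << 12) - 1

    def test_decline_factor_one_equals_constant(self):
        # identity case: a "decline" to 1x is rejected by validation, and a
        # bottleneck of factor ~1 leaves TMRCA at the constant expectation
        near = SingleDemeModel(
            kind="bottleneck", factor=0.999999, t_start=20_000, t_end=10_000
        )
        rng = np.random.default_rng(1)
        t = [simulate_genealogy(near, 2, rng).tmrca for _ in range(3000)]
        assert np.mean(t) == pytest.approx(20_000, abs=3 * 2e4 / np.sqrt(3000))

    def test_seeded_runs_are_bit_reproducible(self, scenarios, mm):
        comp = DatasetComposition(n_alleles=6, locus_length=300, n_loci=4)
        a = simulate_pod(scenarios[0], comp, mm, 123)
        b = simulate_pod(scenarios[0], comp, mm, 123)
        assert all(np.array_equal(x, y) for x, y in zip(a.loci, b.loci))
        c = simulate_pod(scenarios[0], comp, mm, 124)
        assert not all(np.array_equal(x, y) for x, y in zip(a.loci, c.loci))


class TestMsprimeCrossCheck:
    def _msprime_fusion_tmrcas(self, scen, n, n_reps, seed):
        import msprime

        dem = msprime.Demography()
        dem.add_population(name="M", initial_size=scen.base_Ne)
        dem.add_population(name="A", initial_size=scen.base_Ne)
        dem.add_population(name="B", initial_size=scen.base_Ne)
        dem.add_population(name="ANC", initial_size=scen.base_Ne)
        dem.add_admixture(
            time=scen.t_fuse, derived="M", ancestral=["A", "B"],
            proportions=[scen.mix, 1 - scen.mix],
        )
        dem.add_population_split(time=scen.t_div, derived=["A", "B"], ancestral="ANC")
        out = []
        for i, ts in enumerate(
            msprime.sim_ancestry(
                samples={"M": n // 2}, demography=dem, num_replicates=n_reps,
                random_seed=seed, ploidy=2,
            )
        ):
            out.append(ts.max_root_time)
        return np.array(out)

    def test_fusion_tmrca_distribution_matches_msprime(self, rng):
        from scipy import stats

        scen = FusionScenario(base_Ne=10_000, t_div=60_000, t_fuse=10_000)
        mine = np.array(
            [simulate_genealogy(scen, 20, rng).tmrca for _ in range(800)]
        )
        theirs = self._msprime_fusion_tmrcas(scen, 20, 800, seed=99)
        assert stats.ks_2samp(mine, theirs).pvalue > 0.01


class TestMutations:
    def test_zero_rate_gives_identical_sequences(self, rng):
        g = simulate_genealogy(CONST, 8, rng)
        aln = apply_mutations(g, MutationModel(mu=0.0), 200, rng)
        assert site_summary(aln).S == 0

    def test_finite_site_segregating_sites_near_watterson(self, rng):
        # E[S] ~ theta_locus * a_n with theta_locus = 4 Ne mu L (1 - p_inv)
        mm = MutationModel()
        n, L, reps = 10, 2000, 400
        s_vals = []
        for _ in range(reps):
            g = simulate_genealogy(CONST, n, rng)
            s_vals.append(site_summary(apply_mutations(g, mm, L, rng)).S)
        theta = 4 * 1e4 * mm.mu * L * (1 - mm.prop_invariant)
        expected = theta * harmonic_sums(n)[0]
        se = np.std(s_vals) / np.sqrt(reps)
        # 3 MC standard errors plus a small finite-site allowance
        assert np.mean(s_vals) == pytest.approx(expected, abs=3 * se + 0.02 * expected)

    def test_invariant_sites_never_vary(self, rng):
        mm = MutationModel(mu=1e-5)  # hot rate so variable sites nearly all vary
        g = simulate_genealogy(CONST, 20, rng)
        L = 5000
        aln = apply_mutations(g, mm, L, rng)
        counts = np.stack([(aln == s).sum(axis=0) for s in range(4)])
        frac_invariant = np.mean((counts > 0).sum(axis=0) == 1)
        assert frac_invariant >= mm.prop_invariant * 0.8

    def test_discrete_gamma_rates_have_mean_one(self):
        for shape in (0.3, 1.0, 5.0):
            for k in (1, 2, 4, 8):
                rates = discrete_gamma_rates(shape, k)
                assert rates.mean() == pytest.approx(1.0, rel=1e-9)
                assert np.all(np.diff(rates) >= 0)

    def test_equal_base_frequencies_at_root(self, rng):
        g = simulate_genealogy(CONST, 4, rng)
        aln = apply_mutations(g, MutationModel(), 8000, rng)
        freqs = np.bincount(aln.ravel(), minlength=4) / aln.size
        assert np.allclose(freqs, 0.25, atol=0.02)


class TestNullReplicates:
    def test_watterson_expectation(self, rng):
        theta, n = 5.0, 10
        S = [simulate_null_replicate(CONST, n, theta, rng).S for _ in range(4000)]
        expected = theta * harmonic_sums(n)[0]
        assert np.mean(S) == pytest.approx(expected, abs=3 * np.std(S) / np.sqrt(len(S)))

    def test_pairwise_difference_is_theta(self, rng):
        theta = 1.0
        k = [
            summary_from_patterns(simulate_null_replicate(CONST, 2, theta, rng)).K
            for _ in range(6000)
        ]
        assert np.mean(k) == pytest.approx(theta, abs=3 * np.std(k) / np.sqrt(len(k)))

    def test_zero_theta_is_monomorphic(self, rng):
        assert simulate_null_replicate(CONST, 10, 0.0, rng).S == 0

    def test_negative_theta_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_null_replicate(CONST, 10, -1.0, rng)


class TestPodSimulation:
    def test_single_locus_composition(self, scenarios, mm, rng):
        comp = DatasetComposition(n_alleles=4, locus_length=100, n_loci=1)
        pod = simulate_pod(scenarios[0], comp, mm, rng)
        assert pod.n_loci == 1
        assert pod.loci[0].shape == (4, 100)

    def test_fusion_skews_tajima_positive(self, rng):
        # long divergence + short lag: two deep clades, D > 0 on average
        scen = FusionScenario(base_Ne=10_000, t_div=200_000, t_fuse=1_000)
        from fusim.sumstats import tajima_D

        vals = []
        for _ in range(300):
            pat = simulate_null_replicate(scen, 20, 5.0, rng)
            d = tajima_D(summary_from_patterns(pat))
            if d is not None:
                vals.append(d)
        assert np.mean(vals) > 0.5
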