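"""Per-locus statistics: frozen toy values, reference cross-checks,
invariances, and the undefined-value conventions."""

import numpy as np
import pytest

import reference_stats as ref
from conftest import random_toy_alignment
from fusim import sumstats as ss
from fusim.coalsim import SegPatterns

TOY_TWO_CLADES = ["AAAA", "AAAA", "TTTA", "TTTA"]


class TestSiteSummary:
    def test_monomorphic(self):
        s = ss.site_summary(["AAAA"] * 4)
        assert (s.S, s.K, s.H_N, s.eta_S) == (0, 0.0, 1, 0)

    def test_two_clade_toy_by_pair_enumeration(self):
        s = ss.site_summary(TOY_TWO_CLADES)
        assert s.S == 3
        assert s.K == 2.0  # 4 of 6 pairs differ at 3 sites: 12/6
        assert s.H_N == 2
        assert s.eta_S == 0
        assert s.theta_W == pytest.approx(3 / (1 + 1 / 2 + 1 / 3))

    def test_single_singleton(self):
        s = ss.site_summary(["AAAA", "AAAA", "AAAA", "AAAT"])
        assert (s.S, s.eta_S, s.H_N) == (1, 1, 2)
        assert s.K == 0.5
        assert list(s.U) == [0, 0, 0, 1]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            ss.site_summary(["AAA", "AAAA"])

    def test_multiallelic_column_counts_once(self):
        s = ss.site_summary(["A", "C", "G", "G"])
        assert s.S == 1
        # two states occur once each: not a singleton column by convention
        assert s.eta_S == 0


class TestStatisticValues:
    def test_tajima_positive_for_balanced_clades(self):
        s = ss.site_summary(TOY_TWO_CLADES)
        assert ss.tajima_D(s) > 0
        assert ss.tajima_D(s) == pytest.approx(ref.ref_tajima_d(TOY_TWO_CLADES), abs=1e-9)

    def test_fu_li_signs(self):
        assert ss.fu_li_F_star(ss.site_summary(TOY_TWO_CLADES)) > 0
        all_singletons = ["TAAAA", "ATAAA", "AATAA", "AAATA", "AAAAT"]
        assert ss.fu_li_F_star(ss.site_summary(all_singletons)) < 0

    def test_fu_fs_toy_against_ewens_brute_force(self):
        # n=4, all haplotypes distinct, theta_pi = 2.0
        aln = ["AATT", "ATAT", "TAAT", "TTTT"]
        s = ss.site_summary(aln)
        assert s.H_N == 4
        expected = ref.ref_fu_fs(aln)
        assert ss.fu_FS(s) == pytest.approx(expected, rel=1e-9)

    def test_r2_zero_when_each_sequence_has_one_private_singleton(self):
        aln = ["TAAA", "ATAA", "AATA", "AAAT"]
        assert ss.ramos_onsins_R2(ss.site_summary(aln)) == 0.0

    def test_zns_complete_ld_is_one(self):
        assert ss.kelly_ZnS(TOY_TWO_CLADES) == pytest.approx(1.0)

    def test_zns_independent_sites_is_zero(self):
        assert ss.kelly_ZnS(["TT", "TA", "AT", "AA"]) == pytest.approx(0.0)

    def test_hd_values(self):
        assert ss.nei_Hd(["AAAA"] * 4) == 0.0
        assert ss.nei_Hd(["AATT", "ATAT", "TAAT", "TTTT"]) == pytest.approx(1.0)
        assert ss.nei_Hd(TOY_TWO_CLADES) == pytest.approx(2 / 3)


class TestUndefinedConventions:
    def test_all_undefined_when_monomorphic(self):
        s = ss.site_summary(["ACGT"] * 6)
        assert ss.tajima_D(s) is None
        assert ss.fu_li_F_star(s) is None
        assert ss.fu_FS(s) is None
        assert ss.ramos_onsins_R2(s) is None
        assert ss.achaz_Y_star(s) is None
        assert ss.kelly_ZnS(s) is None

    def test_y_star_undefined_when_only_singletons(self):
        aln = ["TAAAAA", "ATAAAA", "AATAAA", "AAATAA", "AAAATA", "AAAAAT"]
        s = ss.site_summary(aln)
        assert s.S == s.eta_S == 6
        assert ss.achaz_Y_star(s) is None

    def test_zns_needs_two_biallelic_sites(self):
        assert ss.kelly_ZnS(["AAAT", "AAAA", "AAAA", "AAAA"]) is None


class TestReferenceCrossCheck:
    def test_hundred_random_toys_match_reference(self):
        rng = np.random.default_rng(424242)
        pairs = {
            "D": (ss.tajima_D, ref.ref_tajima_d),
            "F_star": (ss.fu_li_F_star, ref.ref_fu_li_f_star),
            "F_S": (ss.fu_FS, ref.ref_fu_fs),
            "R2": (ss.ramos_onsins_R2, ref.ref_r2),
            "Y_star": (ss.achaz_Y_star, ref.ref_achaz_y_star),
            "ZnS": (ss.kelly_ZnS, ref.ref_zns),
            "Hd": (ss.nei_Hd, ref.ref_hd),
        }
        for _ in range(100):
            aln = random_toy_alignment(rng)
            s = ss.site_summary(aln)
            for name, (mine_fn, ref_fn) in pairs.items():
                mine = mine_fn(s) if name != "Hd" else mine_fn(aln)
                expected = ref_fn(aln)
                assert (mine is None) == (expected is None), (name, aln)
                if mine is not None:
                    assert mine == pytest.approx(expected, abs=1e-6), (name, aln)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            aln = random_toy_alignment(rng)
            perm = list(rng.permutation(len(aln)))
            shuffled = [aln[i] for i in perm]
            s1, s2 = ss.site_summary(aln), ss.site_summary(shuffled)
            for fn in (ss.tajima_D, ss.fu_li_F_star, ss.fu_FS,
                       ss.ramos_onsins_R2, ss.achaz_Y_star, ss.kelly_ZnS):
                v1, v2 = fn(s1), fn(s2)
                assert (v1 is None) == (v2 is None)
                if v1 is not None:
                    assert v1 == pytest.approx(v2, abs=1e-12)
            assert ss.nei_Hd(aln) == pytest.approx(ss.nei_Hd(shuffled))


class TestConstantsMachinery:
    def test_tajima_constants_recovered_from_covariance_framework(self):
        # the same spectrum covariance matrix that normalises Y* must
        # reproduce Tajima's printed variance constants exactly
        for n in (5, 10, 23, 40):
            a1, a2 = ss.harmonic_sums(n)
            i = np.arange(1, n)
            npairs = n * (n - 1) / 2
            c = i * (n - i) / npairs - 1 / a1
            alpha, beta = ss.spectrum_test_variance(n, tuple(c))
            e1, e2 = ss.tajima_constants(n)
            assert alpha == pytest.approx(e1 * a1, rel=1e-12)
            assert beta == pytest.approx(e2 * (a1**2 + a2), rel=1e-12)

    def test_sigma_row_sums_give_watterson_variance(self):
        # Var(S) = a_n theta + b_n theta^2 pins the full matrix sum
        for n in (6, 15, 40):
            a1, a2 = ss.harmonic_sums(n)
            assert ss.fu1995_sigma(n).sum() == pytest.approx(a2, rel=1e-12)


class TestPatternsPath:
    def test_patterns_and_alignment_paths_agree(self):
        # encode binary patterns as A/T alignments and compare all statistics
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(5, 12))
            S = int(rng.integers(2, 10))
            masks = []
            for _ in range(S):
                c = int(rng.integers(1, n))
                bits = rng.permutation(n)[:c]
                masks.append(sum(1 << int(b) for b in bits))
            pat = SegPatterns(n=n, masks=np.array(masks, dtype=np.uint64))
            aln = ["".join("AT"[b] for b in row) for row in pat.to_matrix()]
            sp = ss.summary_from_patterns(pat)
            sa = ss.site_summary(aln)
            assert (sp.S, sp.eta_S, sp.H_N) == (sa.S, sa.eta_S, sa.H_N)
            assert sp.K == pytest.approx(sa.K)
            assert list(sp.U) == list(sa.U)
            for fn in (ss.tajima_D, ss.fu_li_F_star, ss.fu_FS,
                       ss.ramos_onsins_R2, ss.achaz_Y_star, ss.kelly_ZnS):
                v1, v2 = fn(sp), fn(sa)
                assert (v1 is None) == (v2 is None)
                if v1 is not None:
                    assert v1 == pytest.approx(v2, abs=1e-9)


class TestProfile:
    def test_mean_excludes_undefined_loci(self):
        from fusim.coalsim import HaplotypeDataset
        from fusim.sumstats import as_matrix

        poly = as_matrix(TOY_TWO_CLADES)
        mono = as_matrix(["AAAA"] * 4)
        ds = HaplotypeDataset(loci=[poly, mono])
        prof = ss.profile(ds)
        assert prof.n_defined["D"] == 1
        assert prof.across_loci["D"] == pytest.approx(ss.tajima_D(ss.site_summary(TOY_TWO_CLADES)))
        assert prof.across_loci["Hd"] == pytest.approx((2 / 3 + 0.0) / 2)
        assert prof.Hd_var == pytest.approx(np.var([2 / 3, 0.0], ddof=1))

    def test_all_monomorphic_dataset(self):
        from fusim.coalsim import HaplotypeDataset
        from fusim.sumstats import as_matrix

        ds = HaplotypeDataset(loci=[as_matrix(["AAAA"] * 4)] * 3)
        prof = ss.profile(ds)
        assert prof.across_loci["Hd"] == 0.0
        for s in ss.STATISTICS:
            assert prof.across_loci[s] is None
            assert prof.n_defined[s] == 0
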