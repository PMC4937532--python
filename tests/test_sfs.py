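import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from sweepscan.io import AncestralAlleles
from sweepscan.sfs import (
    SFS,
    build_sfs,
    fay_wu_h_normalized,
    fold_sfs,
    genome_fst,
    haplotype_spectrum,
    pi_per_site,
    project_count,
    site_fst_wc,
    site_pi,
    tajimas_d,
    watterson_theta,
)


class TestSitePi:
    def test_three_one_split(self):
        assert site_pi([0, 0, 0, 1]) == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        assert site_pi([1, 1, 1, 1]) == 0.0

    def test_two_two_split_matches_pair_enumeration(self):
        assert site_pi([0, 0, 1, 1]) == pytest.approx(2 / 3)
        assert site_pi([0, 0, 1, 1]) == pytest.approx(oracles.pi_pairwise([0, 0, 1, 1]))

    def test_fewer_than_two_calls_undefined(self):
        assert np.isnan(site_pi([1, -1, -1]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from([0, 1, -1]), min_size=2, max_size=15))
    def test_equals_pairwise_enumeration(self, calls):
        mine = site_pi(calls)
        ref = oracles.pi_pairwise(calls)
        if np.isnan(ref):
            assert np.isnan(mine)
        else:
            assert mine == pytest.approx(ref, abs=1e-12)


class TestWatterson:
    @pytest.mark.parametrize("S,n,expect", [(6, 4, 36 / 11), (0, 9, 0.0), (5, 2, 5.0)])
    def test_closed_form(self, S, n, expect):
        assert watterson_theta(S, n) == pytest.approx(expect)

    def test_n_below_two_raises(self):
        with pytest.raises(ValueError):
            watterson_theta(3, 1)


class TestTajimasD:
    def test_n2_identity_zero(self):
        calls = np.array([[0, 1], [1, 0], [0, 1]], dtype=np.int8)
        assert tajimas_d(calls) == 0.0

    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajimas_d(np.zeros((5, 6), dtype=np.int8)))

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        calls = (rng.random((40, 10)) < rng.beta(0.8, 0.8, (40, 1))).astype(np.int8)
        d = tajimas_d(calls)
        k = calls.sum(axis=1)
        seg = (k > 0) & (k < 10)
        pi_sum = sum(oracles.pi_pairwise(row) for row in calls[seg])
        expect = oracles.tajimas_d(pi_sum, int(seg.sum()), 10)
        assert d == pytest.approx(expect, abs=1e-9)


class TestWeirCockerhamFst:
    def test_fixed_difference_is_one(self):
        calls = np.array([1] * 20 + [0] * 20, dtype=np.int8)
        panel = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        assert site_fst_wc(calls, panel) == pytest.approx(1.0)

    def test_equal_frequencies_small_negative(self):
        calls = np.array(([0] * 10 + [1] * 10) * 2, dtype=np.int8)
        panel = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        fst = site_fst_wc(calls, panel)
        assert -0.1 < fst < 0.0

    def test_worked_example_against_oracle(self):
        calls = np.array([1] * 45 + [0] * 5 + [1] * 5 + [0] * 45, dtype=np.int8)
        panel = np.array(["A"] * 50 + ["B"] * 50, dtype=object)
        assert site_fst_wc(calls, panel) == pytest.approx(
            oracles.wc_fst_haploid(45, 50, 5, 50), abs=1e-9
        )

    def test_monomorphic_overall_undefined(self):
        calls = np.zeros(40, dtype=np.int8)
        panel = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        assert np.isnan(site_fst_wc(calls, panel))

    def test_label_swap_invariance(self, small_gm):
        for i in range(small_gm.n_sites):
            f1 = site_fst_wc(small_gm.calls[i], small_gm.panel)
            swapped = np.where(small_gm.panel == "A", "B", "A").astype(object)
            f2 = site_fst_wc(small_gm.calls[i], swapped)
            assert (np.isnan(f1) and np.isnan(f2)) or f1 == pytest.approx(f2, abs=1e-12)

    def test_genome_fst_fixed_differences(self):
        calls = np.tile(np.array([1] * 10 + [0] * 10, dtype=np.int8), (5, 1))
        assert genome_fst(calls, np.arange(20) < 10, np.arange(20) >= 10) == pytest.approx(1.0)


class TestBuildSFS:
    def _gm(self, calls):
        from sweepscan.io import GenotypeMatrix

        calls = np.asarray(calls, dtype=np.int8)
        n_sites, n_samples = calls.shape
        return GenotypeMatrix(
            chrom=np.array(["chr1"] * n_sites, dtype=object),
            pos=np.arange(1, n_sites + 1),
            ref=np.array(["A"] * n_sites, dtype=object),
            alt=np.array(["T"] * n_sites, dtype=object),
            calls=calls,
            samples=[f"s{i}" for i in range(n_samples)],
            panel=np.array(["A"] * n_samples, dtype=object),
        )

    def test_derived_counts(self):
        calls = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [1, 1, 1, 0]], dtype=np.int8)
        gm = self._gm(calls)
        anc = AncestralAlleles({("chr1", int(p)): "A" for p in gm.pos})
        sfs = build_sfs(gm, "A", ancestral=anc, folded=False)
        assert sfs.counts[1] == 2 and sfs.counts[3] == 1

    def test_folding(self):
        sfs = SFS(n=4, counts=np.array([0.0, 2, 0, 1, 0]), polarized=True, folded=False)
        folded = fold_sfs(sfs)
        assert folded.counts[1] == 3

    def test_projection_matches_hypergeometric_enumeration(self):
        # count 2 of n=5 projected to m=4: P(l) = C(2,l) C(3,4-l) / C(5,4)
        from math import comb

        got = project_count(2, 5, 4)
        expect = [comb(2, l) * comb(3, 4 - l) / comb(5, 4) if 4 - l <= 3 else 0
                  for l in range(5)]
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_unfolded_folds_to_folded(self):
        rng = np.random.default_rng(6)
        calls = (rng.random((60, 8)) < 0.4).astype(np.int8)
        gm = self._gm(calls)
        anc = AncestralAlleles({("chr1", int(p)): "A" for p in gm.pos})
        unf = build_sfs(gm, "A", ancestral=anc, folded=False)
        fol = build_sfs(gm, "A")
        np.testing.assert_allclose(fold_sfs(unf).counts, fol.counts, atol=1e-9)


class TestFayWuH:
    def test_worked_example_theta_sums(self):
        sfs = SFS(n=4, counts=np.array([0.0, 2, 0, 1, 0]), polarized=True, folded=False)
        h = fay_wu_h_normalized(sfs)
        # theta_pi = 1.5, theta_L = 5/3 -> numerator -1/6
        assert h == pytest.approx(oracles.fay_wu_h_norm(sfs.counts, 4), abs=1e-12)
        assert h < 0

    def test_balanced_spectrum_zero(self):
        # weights j(n-2j) at n=4 are (2, 0, -6): counts (3, s, 1) balance
        # theta_pi = theta_L exactly for any middle class s
        sfs = SFS(n=4, counts=np.array([0.0, 3, 5, 1, 0]), polarized=True, folded=False)
        assert fay_wu_h_normalized(sfs) == pytest.approx(0.0, abs=1e-12)

    def test_unpolarized_raises(self):
        sfs = SFS(n=4, counts=np.array([0.0, 2, 1, 1, 0]), polarized=False, folded=True)
        with pytest.raises(ValueError, match="polarization"):
            fay_wu_h_normalized(sfs)

    def test_sign_under_polarity_inversion(self):
        # all mass at high-frequency derived: strongly negative H; inverting
        # the polarization moves the mass to the rare classes: positive H
        high = SFS(5, np.array([0.0, 0, 0, 0, 8, 0]), True, False)
        low = SFS(5, np.array([0.0, 8, 0, 0, 0, 0]), True, False)
        assert fay_wu_h_normalized(high) < 0 < fay_wu_h_normalized(low)

    def test_neutral_spectrum_draws_center_near_zero(self):
        """Monte-Carlo: S_j proportional to 1/j draws at n=20, S=50."""
        rng = np.random.default_rng(7)
        n, S, reps = 20, 50, 2000
        probs = (1.0 / np.arange(1, n)) / np.sum(1.0 / np.arange(1, n))
        hs = []
        for _ in range(reps):
            counts = np.zeros(n + 1)
            counts[1:n] = rng.multinomial(S, probs)
            hs.append(fay_wu_h_normalized(SFS(n, counts, True, False)))
        assert -0.15 < np.mean(hs) < 0.15


class TestHaplotypeSpectrum:
    def test_counts_and_order(self, small_gm):
        spec = haplotype_spectrum(small_gm, "chr1", 100, 400)
        haps = [h for h, _ in spec]
        totals = [sum(c.values()) for _, c in spec]
        assert totals == sorted(totals, reverse=True)
        assert all(len(h) == 3 for h in haps)

    def test_all_identical_panel(self):
        from sweepscan.io import GenotypeMatrix

        gm = GenotypeMatrix(
            chrom=np.array(["chr1"] * 2, dtype=object),
            pos=np.array([10, 20]),
            ref=np.array(["A", "A"], dtype=object),
            alt=np.array(["T", "T"], dtype=object),
            calls=np.array([[0, 0, 0, 1], [1, 1, 1, 0]], dtype=np.int8),
            samples=["a", "b", "c", "d"],
            panel=np.array(["A", "A", "A", "B"], dtype=object),
        )
        spec = haplotype_spectrum(gm, "chr1", 1, 100)
        assert spec[0][0] == "01" and spec[0][1] == {"A": 3}

    def test_empty_region_raises(self, small_gm):
        with pytest.raises(ValueError, match="empty region"):
            haplotype_spectrum(small_gm, "chr1", 5000, 6000)


class TestOracleEquivalenceBattery:
    def test_hundred_random_instances(self):
        """pi, theta_W, D, FST, normalized H vs textbook oracles to 1e-9."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 21))
            S = int(rng.integers(2, 101))
            # window of S sites for one panel of n samples
            freqs = rng.beta(0.6, 0.6, S)
            calls = (rng.random((S, n)) < freqs[:, None]).astype(np.int8)
            k = calls.sum(axis=1)
            seg = (k > 0) & (k < n)
            if seg.sum() >= 2:
                pi_sum = sum(oracles.pi_pairwise(row) for row in calls[seg])
                assert tajimas_d(calls) == pytest.approx(
                    oracles.tajimas_d(pi_sum, int(seg.sum()), n), abs=1e-9)
            assert watterson_theta(S, n) == pytest.approx(oracles.watterson(S, n), abs=1e-9)
            pi_mine = pi_per_site(calls)
            for i in range(min(5, S)):
                assert pi_mine[i] == pytest.approx(oracles.pi_pairwise(calls[i]), abs=1e-9)
            # FST on a random two-panel site
            n1, n2 = int(rng.integers(2, 30)), int(rng.integers(2, 30))
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            if 0 < k1 + k2 < n1 + n2:
                site = np.array([1] * k1 + [0] * (n1 - k1) + [1] * k2 + [0] * (n2 - k2),
                                dtype=np.int8)
                panel = np.array(["A"] * n1 + ["B"] * n2, dtype=object)
                assert site_fst_wc(site, panel) == pytest.approx(
                    oracles.wc_fst_haploid(k1, n1, k2, n2), abs=1e-9)
            # normalized H on a random polarized spectrum
            counts = np.zeros(n + 1)
            counts[1:n] = rng.multinomial(S, np.ones(n - 1) / (n - 1))
            if counts[1:n].sum() >= 2:
                assert fay_wu_h_normalized(SFS(n, counts, True, False)) == pytest.approx(
                    oracles.fay_wu_h_norm(counts, n), abs=1e-9)
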