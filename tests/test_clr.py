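import numpy as np
import pytest

import oracles
from sweepscan.clr import (
    BackgroundSFS,
    _BucketTables,
    clr_scan,
    composite_log_likelihood,
    escape_probability,
    grid_points,
    sweep_site_distribution,
)
from sweepscan.io import GenotypeMatrix
from sweepscan.sfs import SFS


def _bg(n, counts=None, folded=False):
    if counts is None:
        counts = 1.0 / np.arange(1, n)
        counts = np.concatenate([[0.0], counts, [0.0]])
    return BackgroundSFS.from_sfs(SFS(n, np.asarray(counts, float), not folded, folded))


class TestEscapeProbability:
    def test_zero_alpha_or_distance(self):
        assert escape_probability(0.0, 1e6) == 0.0
        assert escape_probability(1e-4, 0.0) == 0.0

    def test_half_life(self):
        assert escape_probability(np.log(2) / 1000, 1000) == pytest.approx(0.5)

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            escape_probability(-1e-6, 100)
        with pytest.raises(ValueError):
            escape_probability(1e-6, -100)


class TestSweepSiteDistribution:
    def test_full_escape_returns_background(self):
        bg = _bg(6)
        d = sweep_site_distribution(6, 1.0, bg)
        np.testing.assert_allclose(d, bg.q, atol=1e-14)

    def test_no_escape_mass_on_monomorphic_classes(self):
        # p_e = 0: one pre-sweep lineage copied to everyone -> counts 0 or n
        bg = _bg(5)
        d = sweep_site_distribution(5, 0.0, bg)
        assert d[1:5].sum() == pytest.approx(0.0, abs=1e-14)
        assert d[0] + d[5] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    @pytest.mark.parametrize("p_e", [0.0, 0.2, 0.5, 0.8, 1.0])
    def test_matches_exhaustive_enumeration(self, n, p_e):
        rng = np.random.default_rng(n)
        counts = np.concatenate([[0.0], rng.integers(1, 9, n - 1).astype(float), [0.0]])
        bg = _bg(n, counts)
        mine = sweep_site_distribution(n, p_e, bg)
        ref = oracles.sweep_dist_enum(n, p_e, bg.q)
        np.testing.assert_allclose(mine, ref, atol=1e-12)
        assert mine.sum() == pytest.approx(1.0, abs=1e-12)

    def test_conditioned_on_segregating(self):
        bg = _bg(4, [0.0, 1, 1, 1, 0.0])
        d = sweep_site_distribution(4, 0.3, bg, condition_segregating=True)
        ref = oracles.sweep_dist_enum(4, 0.3, bg.q)
        ref[0] = ref[4] = 0.0
        ref /= ref.sum()
        np.testing.assert_allclose(d, ref, atol=1e-12)


class TestBackground:
    def test_zero_classes_floored(self):
        bg = _bg(6, [0.0, 5, 0, 3, 0, 2, 0.0])
        assert (bg.q[1:6] > 0).all()

    def test_projection_sums_to_one(self):
        bg = _bg(10)
        q5 = bg.at_n(5).q
        assert q5[1:5].sum() == pytest.approx(1.0)

    def test_folded_symmetrization_recovers_folded_null(self):
        counts = np.array([0.0, 4, 3, 0, 0, 0])  # folded at n=5: classes 1, 2
        bg = BackgroundSFS.from_sfs(SFS(5, counts, False, True))
        lp = bg.null_logprob(5)
        assert np.exp(lp[1]) == pytest.approx(4 / 7)
        assert np.exp(lp[2]) == pytest.approx(3 / 7)


class TestCompositeLogLikelihood:
    def _sites(self):
        pos = np.array([0, 1000, 2500, 4000, 8000, 12000, 20000, 30000, 45000, 60000])
        j = np.array([1, 3, 2, 1, 4, 2, 3, 1, 2, 4])
        n = np.full(10, 5)
        return pos, j, n

    def test_large_alpha_equals_null(self):
        # test position off-site so every distance is >= 500 bp: with
        # alpha = 1 all p_e exceed 0.999 and the null term applies everywhere
        bg = _bg(5)
        sites = self._sites()
        ll = composite_log_likelihood(sites, 30500, alpha=1.0, background=bg)
        null = sum(bg.null_logprob(5)[jj] for jj in sites[1])
        assert ll == pytest.approx(null, abs=1e-9)

    def test_single_site_at_center(self):
        bg = _bg(5)
        d0 = sweep_site_distribution(5, 0.0, bg, condition_segregating=True)
        ll = composite_log_likelihood(([100], [2], [5]), 100, alpha=1e-6, background=bg)
        assert ll == pytest.approx(np.log(d0[2]), abs=1e-9)

    def test_argmax_matches_brute_force_over_grid(self):
        bg = _bg(5)
        sites = self._sites()
        alphas = np.array([1e-6, 1e-5, 1e-4, 1e-3, 1e-2])
        lls = [composite_log_likelihood(sites, 8100, a, bg) for a in alphas]
        # brute force: evaluate the model distribution site by site
        brute = []
        for a in alphas:
            tot = 0.0
            for p, j, n in zip(*sites):
                pe = escape_probability(a, abs(p - 8100))
                if pe > 0.999:
                    tot += bg.null_logprob(n)[j]
                else:
                    d = oracles.sweep_dist_enum(n, pe, bg.q)
                    d[0] = d[n] = 0.0
                    tot += np.log(d[j] / d.sum())
            brute.append(tot)
        assert np.argmax(lls) == np.argmax(brute)
        np.testing.assert_allclose(lls, brute, atol=1e-9)

    def test_empty_sites_raise(self):
        with pytest.raises(ValueError, match="empty"):
            composite_log_likelihood(([], [], []), 0, 1e-5, _bg(5))


class TestBucketTablesAgainstExactPath:
    def test_loglik_close_to_exact(self):
        rng = np.random.default_rng(3)
        bg = _bg(8)
        pos = np.sort(rng.choice(2_000_000, 300, replace=False)).astype(float)
        jobs = rng.integers(1, 8, 300)
        ns = np.full(300, 8)
        tables = _BucketTables(pos, jobs, ns, bg)
        for alpha in (1e-6, 3e-5, 1e-4):
            exact = composite_log_likelihood((pos, jobs, ns), 1_000_000, alpha, bg)
            fast = tables.loglik(1_000_000.0, np.array([alpha]))[0]
            assert fast == pytest.approx(exact, rel=2e-3, abs=0.5)


class TestGridAndScan:
    def test_grid_geometry_ten_cells(self):
        pts = grid_points(1_500_000, 150_000)
        assert len(pts) == 10
        np.testing.assert_allclose(pts, 75_000 + 150_000 * np.arange(10))

    def test_partial_cell_rule(self):
        # trailing 80 kb cell (>= half of 150 kb) kept, 40 kb dropped
        assert len(grid_points(1_580_000, 150_000)) == 11
        assert len(grid_points(1_540_000, 150_000)) == 10

    def _neutral_gm(self, n_sites=4000, n=20, span=12_000_000, seed=1):
        """Sites drawn i.i.d. from a neutral background spectrum."""
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(span, n_sites, replace=False)) + 1
        w = (1.0 / np.arange(1, n)) / np.sum(1.0 / np.arange(1, n))
        j = rng.choice(np.arange(1, n), size=n_sites, p=w)
        calls = np.zeros((n_sites, n + 2), dtype=np.int8)
        for i in range(n_sites):
            carriers = rng.choice(n, j[i], replace=False)
            calls[i, carriers] = 1
        calls[:, n:] = rng.integers(0, 2, (n_sites, 2))  # 2-sample dummy panel
        return GenotypeMatrix(
            chrom=np.array(["chr1"] * n_sites, dtype=object),
            pos=pos.astype(np.int64),
            ref=np.array(["A"] * n_sites, dtype=object),
            alt=np.array(["T"] * n_sites, dtype=object),
            calls=calls,
            samples=[f"s{i}" for i in range(n + 2)],
            panel=np.array(["A"] * n + ["B"] * 2, dtype=object),
        )

    def test_null_scan_clr_nonnegative_and_small(self):
        """i.i.d. background draws: CLR >= 0 everywhere, modest upper tail."""
        gm = self._neutral_gm()
        res = clr_scan(gm, "A")
        assert len(res) >= 75
        assert (res["clr"] >= 0).all()
        assert np.quantile(res["clr"], 0.95) < 6.0

    def test_chromosome_with_too_few_sites_skipped(self):
        gm = self._neutral_gm(n_sites=40)
        res = clr_scan(gm, "A", min_sites=50)
        assert len(res) == 0
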