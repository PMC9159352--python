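import numpy as np
import pytest

from gradsweep.popgen import (Window, make_windows, pi_ratio_signal, site_pi,
                              wc_fst_site, window_fst, window_pi)

from conftest import random_panel
from oracles import pairwise_site_pi, pairwise_window_pi, wc_fst_anova


class TestSitePi:
    def test_closed_form_example(self):
        assert site_pi(2, 4) == pytest.approx(2 * 2 * 2 / 12)

    @pytest.mark.parametrize("c,n", [(0, 6), (6, 6)])
    def test_monomorphic_is_zero(self, c, n):
        assert site_pi(c, n) == 0.0

    def test_matches_pair_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            col = rng.integers(0, 2, size=n)
            assert site_pi(int(col.sum()), n) == pytest.approx(
                pairwise_site_pi(col))


class TestWindowPi:
    def test_sum_over_span(self, rng):
        panel = random_panel(rng, n_samples=4, n_sites=2, max_pos=9_000)
        windows = [Window("chr1", 0, 10_000)]
        pi, n_snps = window_pi(panel, [0, 1, 2, 3], windows)
        per_site = [pairwise_site_pi(panel.haplotypes[:, j]) for j in range(2)]
        assert n_snps[0] == 2
        assert pi[0] == pytest.approx(sum(per_site) / 10_000)

    def test_half_open_window_boundary(self):
        panel = random_panel(np.random.default_rng(0), n_samples=4, n_sites=1)
        panel.positions[:] = 10_001  # 0-based coord 10_000 = start of window 2
        windows = make_windows("chr1", 20_000)
        _, n_snps = window_pi(panel, [0, 1, 2, 3], windows)
        assert n_snps.tolist() == [0, 1]

    def test_matches_all_pairs_hamming(self, rng):
        panel = random_panel(rng, n_samples=4, n_sites=15, max_pos=9_999)
        windows = [Window("chr1", 0, 10_000)]
        pi, _ = window_pi(panel, [0, 1, 2, 3], windows)
        assert pi[0] == pytest.approx(
            pairwise_window_pi(panel.haplotypes, 10_000))

    def test_invariant_to_haplotype_row_permutation(self, rng):
        panel = random_panel(rng, n_samples=6, n_sites=20)
        windows = make_windows("chr1", 100_000)
        a, _ = window_pi(panel, [0, 1, 2], windows)
        b, _ = window_pi(panel, [2, 0, 1], windows)
        np.testing.assert_allclose(a, b)


class TestPiRatioSignal:
    def test_identity_ratio_is_zero(self):
        sig, sign, valid = pi_ratio_signal(np.array([3e-4]), np.array([3e-4]))
        assert sig[0] == 0.0 and valid[0]

    def test_low_tail_log10(self):
        sig, _, _ = pi_ratio_signal(np.array([1e-4]), np.array([1e-3]),
                                    mode="low_tail")
        assert sig[0] == pytest.approx(1.0)

    def test_zero_focal_gives_inf_ranked_on_top(self):
        sig, sign, valid = pi_ratio_signal(np.array([0.0, 1e-4]),
                                           np.array([1e-3, 1e-3]))
        assert np.isinf(sig[0]) and sign[0] == -1 and valid[0]
        assert np.argmax(sig) == 0

    def test_zero_reference_invalidates_window(self):
        _, _, valid = pi_ratio_signal(np.array([1e-4]), np.array([0.0]))
        assert not valid[0]

    def test_abs_log_ranking_matches_sort_oracle(self, rng):
        focal = rng.uniform(1e-5, 1e-3, size=40)
        ref = rng.uniform(1e-5, 1e-3, size=40)
        sig, _, _ = pi_ratio_signal(focal, ref)
        expected = np.abs(np.log10(focal / ref))
        assert np.argsort(sig).tolist() == np.argsort(expected).tolist()


class TestWcFstSite:
    def test_fixed_difference_is_one(self):
        a, b, c = wc_fst_site((10, 0, 0), (0, 0, 10))
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_identical_counts_no_among_population_variance(self):
        a, b, c = wc_fst_site((4, 4, 2), (4, 4, 2))
        assert a <= 0
        assert a / (a + b + c) <= 0

    def test_matches_anova_route(self, rng):
        for _ in range(30):
            pops = []
            counts = []
            for _ in range(2):
                n = int(rng.integers(2, 12))
                geno = rng.integers(0, 3, size=n)
                counts.append((int((geno == 0).sum()), int((geno == 1).sum()),
                               int((geno == 2).sum())))
                alleles = np.zeros((n, 2))
                alleles[geno == 1, 0] = 1
                alleles[geno == 2] = 1
                pops.append(alleles)
            # skip sites where the overall variance vanishes
            a, b, c = wc_fst_site(counts[0], counts[1])
            oa, ob, oc = wc_fst_anova(pops)
            assert a == pytest.approx(oa, abs=1e-10)
            assert b == pytest.approx(ob, abs=1e-10)
            assert c == pytest.approx(oc, abs=1e-10)


class TestWindowFst:
    def _panel(self, rng, n_samples=8, n_sites=30):
        return random_panel(rng, n_samples=n_samples, n_sites=n_sites,
                            max_pos=99_999)

    def test_fixed_difference_window_is_one(self):
        panel = random_panel(np.random.default_rng(1), n_samples=6, n_sites=5,
                             max_pos=9_999)
        panel.haplotypes[:6] = 0   # pop1: 3 samples all ref
        panel.haplotypes[6:] = 1   # pop2: 3 samples all alt
        fst, _ = window_fst(panel, [0, 1, 2], [3, 4, 5],
                            [Window("chr1", 0, 10_000)])
        assert fst[0] == pytest.approx(1.0)

    def test_single_site_window_reduces_to_site_ratio(self, rng):
        panel = self._panel(rng, n_sites=1)
        dosage = panel.haplotypes[0::2] + panel.haplotypes[1::2]
        pops = ([0, 1, 2, 3], [4, 5, 6, 7])
        counts = []
        for idx in pops:
            d = dosage[list(idx), 0]
            counts.append((int((d == 0).sum()), int((d == 1).sum()),
                           int((d == 2).sum())))
        a, b, c = wc_fst_site(*counts)
        fst, _ = window_fst(panel, pops[0], pops[1],
                            [Window("chr1", 0, 100_000)])
        assert fst[0] == pytest.approx(a / (a + b + c))

    def test_random_halves_of_one_pool_near_zero(self, rng):
        vals = []
        for _ in range(30):
            panel = self._panel(rng, n_samples=16, n_sites=40)
            perm = rng.permutation(16)
            fst, _ = window_fst(panel, perm[:8], perm[8:],
                                [Window("chr1", 0, 100_000)])
            vals.append(fst[0])
        assert abs(float(np.mean(vals))) < 0.02  # Monte-Carlo tolerance

    def test_never_exceeds_one(self, rng):
        for _ in range(20):
            panel = self._panel(rng)
            fst, used = window_fst(panel, [0, 1, 2, 3], [4, 5, 6, 7],
                                   make_windows("chr1", 100_000))
            assert np.nanmax(fst) <= 1.0 + 1e-12

    def test_ratio_of_sums_differs_from_mean_of_ratios(self):
        # constructed 2-site window pinning the chosen estimator
        panel = random_panel(np.random.default_rng(3), n_samples=8, n_sites=2,
                             max_pos=9_999)
        panel.haplotypes[:, 0] = [0, 0, 0, 0, 0, 0, 0, 1] + [1] * 8
        panel.haplotypes[:, 1] = [0, 1] * 4 + [0, 0, 1, 1, 0, 1, 0, 0]
        pop1, pop2 = [0, 1, 2, 3], [4, 5, 6, 7]
        dosage = panel.haplotypes[0::2] + panel.haplotypes[1::2]
        comps = []
        for j in range(2):
            counts = []
            for idx in (pop1, pop2):
                d = dosage[idx, j]
                counts.append((int((d == 0).sum()), int((d == 1).sum()),
                               int((d == 2).sum())))
            comps.append(wc_fst_site(*counts))
        ratio_of_sums = sum(x[0] for x in comps) / sum(sum(x) for x in comps)
        mean_of_ratios = np.mean([x[0] / sum(x) for x in comps])
        fst, _ = window_fst(panel, pop1, pop2, [Window("chr1", 0, 10_000)])
        assert fst[0] == pytest.approx(ratio_of_sums)
        assert fst[0] != pytest.approx(mean_of_ratios)


def test_merged_group_pi_not_below_min_subgroup():
    # statistical sanity on diverged demes, not an identity: pooling two
    # differentiated groups adds between-group diversity
    from gradsweep.simulate import SimConfig, merge_panels, simulate_panel

    cfg = SimConfig(seed=7, n_diploid=60, n_generations=80,
                    split_generation=20, n_sites=200, region_length=200_000,
                    s=0.0, sample_focal=20, sample_ref=20)
    pf, pr, _ = simulate_panel(cfg)
    panel = merge_panels(pf, pr)
    wins = make_windows("chr1", 200_000)
    merged, _ = window_pi(panel, list(range(40)), wins)
    sub1, _ = window_pi(panel, list(range(20)), wins)
    sub2, _ = window_pi(panel, list(range(20, 40)), wins)
    frac = np.mean(merged >= np.minimum(sub1, sub2) - 1e-12)
    assert frac >= 0.9
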