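import numpy as np
import pandas as pd
import pytest

from gradsweep.genes import (annotate_snps, annotate_windows, de_call,
                             known_gene_venn, simple_de, size_factors,
                             stage_exclusion)
from gradsweep.io_formats import GeneFeature
from gradsweep.popgen import Window

from oracles import bh_bruteforce


def gene(symbol, start, end, chrom="chr1"):
    return GeneFeature(symbol, symbol, chrom, start, end)


class TestAnnotateWindows:
    def test_one_bp_overlap_included_and_touching_excluded(self):
        genes = [gene("in", 19_999, 25_000), gene("out", 20_000, 25_000)]
        hits = annotate_windows([Window("chr1", 10_000, 20_000)], genes)
        assert hits == {"in"}

    def test_cross_chromosome_never_matches(self):
        genes = [gene("g", 10_000, 20_000, chrom="chr2")]
        assert annotate_windows([Window("chr1", 0, 100_000)], genes) == set()

    def test_matches_quadratic_interval_oracle(self, rng):
        windows = [Window("chr1", int(s), int(s) + 5_000)
                   for s in rng.integers(0, 200_000, size=15)]
        genes = [gene(f"g{i}", int(s), int(s) + 3_000)
                 for i, s in enumerate(rng.integers(0, 200_000, size=30))]
        expected = {
            g.symbol for g in genes
            if any(g.start < w.end and w.start < g.end for w in windows)
        }
        assert annotate_windows(windows, genes) == expected

    def test_invariant_to_list_order(self, rng):
        windows = [Window("chr1", int(s), int(s) + 5_000)
                   for s in rng.integers(0, 100_000, size=10)]
        genes = [gene(f"g{i}", int(s), int(s) + 2_000)
                 for i, s in enumerate(rng.integers(0, 100_000, size=20))]
        a = annotate_windows(windows, genes)
        b = annotate_windows(windows[::-1], genes[::-1])
        assert a == b


class TestAnnotateSnps:
    def test_snp_in_gene_body(self):
        assert annotate_snps([("chr1", 15_000)],
                             [gene("g", 10_000, 20_000)]) == {"g"}

    def test_flank_boundary(self):
        g = [gene("g", 50_000, 60_000)]
        # 1-based position 40_000 -> coord 39_999 -> 10_001 bp upstream
        assert annotate_snps([("chr1", 40_000)], g, flank_bp=10_000) == set()
        assert annotate_snps([("chr1", 40_001)], g, flank_bp=10_000) == {"g"}

    def test_intergenic_snp_hits_both_flanking_genes(self):
        genes = [gene("left", 0, 10_000), gene("right", 15_000, 25_000)]
        hits = annotate_snps([("chr1", 12_000)], genes, flank_bp=10_000)
        assert hits == {"left", "right"}


class TestSimpleDe:
    def test_size_factors_closed_form_for_scaled_sample(self, rng):
        c1 = rng.integers(50, 500, size=30)
        counts = pd.DataFrame({"s1": c1, "s2": 2 * c1})
        sf = size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_scaled_sample_gives_zero_log2fc(self, rng):
        c1 = rng.integers(100, 500, size=20)
        counts = pd.DataFrame({
            "a1": c1, "a2": c1, "b1": 2 * c1, "b2": 2 * c1,
        }, index=[f"g{i}" for i in range(20)])
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        table = simple_de(counts, groups, ("A", "B"))
        assert np.allclose(table.log2fc.abs().max(), 0.0, atol=0.01)

    def test_bh_adjustment_matches_bruteforce(self, rng):
        pvals = rng.uniform(size=200)
        from statsmodels.stats.multitest import multipletests

        got = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(got, bh_bruteforce(pvals), atol=1e-12)

    def test_bh_worked_example(self):
        np.testing.assert_allclose(bh_bruteforce(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_group_with_single_sample_rejected(self):
        counts = pd.DataFrame({"a1": [1], "b1": [2], "b2": [3]})
        groups = pd.Series({"a1": "A", "b1": "B", "b2": "B"})
        with pytest.raises(ValueError):
            simple_de(counts, groups, ("A", "B"))

    def test_planted_eightfold_genes_enriched_in_calls(self):
        from gradsweep.simulate import SimConfig, simulate_counts

        cfg = SimConfig(seed=9, de_log2_effect=3.0)
        counts, groups, truth = simulate_counts(cfg)
        table = simple_de(counts, groups, ("PRE_REF", "PRE_QP"))
        called = de_call(table)
        planted = set(truth.breed_genes)
        recall = len(called & planted) / len(planted)
        null_rate = len(called - planted - set(truth.stage_genes)) / (
            cfg.n_genes - len(planted) - len(truth.stage_genes))
        assert recall > 0.5
        assert null_rate < 0.01

    def test_type_i_error_near_nominal_on_null_counts(self):
        """Raw p-values on no-effect NB counts reject at about the nominal
        rate (20 replicate datasets, binomial tolerance)."""
        from gradsweep.simulate import SimConfig, simulate_counts

        alpha = 0.05
        n_tests = 0
        n_reject = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_genes=200, n_breed_genes=0,
                            n_stage_genes=0)
            counts, groups, _ = simulate_counts(cfg)
            table = simple_de(counts, groups, ("PRE_REF", "PRE_QP"))
            n_tests += len(table)
            n_reject += int((table.pvalue < alpha).sum())
        rate = n_reject / n_tests
        se = np.sqrt(alpha * (1 - alpha) / n_tests)
        assert abs(rate - alpha) < 4 * se + 0.01


class TestDeCall:
    def test_strict_boundaries(self):
        table = pd.DataFrame({
            "log2fc": [1.1, 1.0, 2.0],
            "padj": [5e-4, 5e-4, 1e-3],
        }, index=["called", "fc_boundary", "padj_boundary"])
        assert de_call(table) == {"called"}


class TestStageExclusion:
    def test_set_difference_and_union(self):
        per_stage, final = stage_exclusion(
            {"PRE": {"A", "B", "C"}, "PAR": {"C", "D"}},
            [{"B"}, {"D"}],
        )
        assert per_stage == {"PRE": {"A", "C"}, "PAR": {"C"}}
        assert final == {"A", "C"}

    def test_output_disjoint_from_stage_genes(self, rng):
        pool = [f"g{i}" for i in range(50)]
        breed = {s: set(rng.choice(pool, size=20, replace=False))
                 for s in ("PRE", "PAR")}
        stages = [set(rng.choice(pool, size=10, replace=False))
                  for _ in range(2)]
        _, final = stage_exclusion(breed, stages)
        assert not final & set().union(*stages)

    def test_planted_breed_block_recovered(self):
        from gradsweep.pipeline import run_de_setlogic
        from gradsweep.simulate import SimConfig, simulate_counts

        recovered = 0
        total = 0
        for seed in range(3):
            cfg = SimConfig(seed=seed)
            counts, groups, truth = simulate_counts(cfg)
            de = run_de_setlogic(counts, groups, "QP", "REF")
            recovered += len(de["de_genes"] & set(truth.breed_genes))
            total += len(truth.breed_genes)
        assert recovered / total >= 0.8


class TestKnownGeneVenn:
    def test_worked_example(self):
        out = known_gene_venn({"A", "B"}, {"B", "C"}, {"B"})
        assert out.known_overlap == {"B"}
        assert sum(out.venn.values()) == 3
        assert out.venn["all_three"] == 1

    def test_empty_known_list(self):
        out = known_gene_venn({"A"}, {"B"}, set())
        assert out.known_overlap == set()

    def test_counts_match_tabulation_oracle(self, rng):
        pool = [f"G{i}" for i in range(100)]
        s = set(rng.choice(pool, 40, replace=False))
        d = set(rng.choice(pool, 40, replace=False))
        k = set(rng.choice(pool, 40, replace=False))
        out = known_gene_venn(s, d, k)
        regions = {
            "sweep_only": len([g for g in pool if g in s and g not in d and g not in k]),
            "de_only": len([g for g in pool if g in d and g not in s and g not in k]),
            "known_only": len([g for g in pool if g in k and g not in s and g not in d]),
            "sweep&de": len([g for g in pool if g in s and g in d and g not in k]),
            "sweep&known": len([g for g in pool if g in s and g in k and g not in d]),
            "de&known": len([g for g in pool if g in d and g in k and g not in s]),
            "all_three": len([g for g in pool if g in s and g in d and g in k]),
        }
        assert out.venn == regions
        assert sum(out.venn.values()) == len(s | d | k)

    def test_case_insensitive_duplicates_collapse_with_warning(self):
        with pytest.warns(UserWarning):
            out = known_gene_venn(["Egfr", "EGFR"], set(), {"egfr"})
        assert out.known_overlap == {"EGFR"}
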