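"""GWAS, interval mapping, thresholds, QTL intervals, TRM selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trmgs as t
from trmgs.binmap import BinMap
from trmgs.mapping import _f2_cond_table, lod_support_interval


class TestPCA:
    def test_scores_orthogonal(self, natural_panel):
        geno, _ = natural_panel
        pcs = t.pca_matrix(geno, 5)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_zero_components(self, natural_panel):
        geno, _ = natural_panel
        assert t.pca_matrix(geno, 0).shape == (geno.n_individuals, 0)

    def test_constant_matrix_rejected(self, natural_panel):
        geno, _ = natural_panel
        flat = geno.take_markers(np.arange(3))
        flat.values[:] = 2
        with pytest.raises(ValueError):
            t.pca_matrix(flat, 1)

    def test_pc1_separates_subpopulations(self, natural_panel):
        geno, labels = natural_panel
        pcs = t.pca_matrix(geno, 1)
        r = np.corrcoef(pcs[:, 0], labels)[0, 1]
        assert abs(r) > 0.9


class TestGwas:
    def test_matches_ols_with_identity_kinship(self, natural_panel):
        geno, _ = natural_panel
        rng = np.random.default_rng(1)
        y = rng.normal(size=geno.n_individuals)
        scan = t.gwas_scan(y, geno)
        n = geno.n_individuals
        for j in [0, 100, 999]:
            x = geno.values[:, j].astype(float)
            X = np.column_stack([np.ones(n), x])
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = ((y - X @ b) ** 2).sum()
            rss0 = ((y - y.mean()) ** 2).sum()
            F = (rss0 - rss) / (rss / (n - 2))
            p_ols = stats.f.sf(F, 1, n - 2)
            assert abs(scan["pvalue"].iloc[j] - p_ols) < 1e-6

    def test_perfect_signal_marker_attains_maximum(self, natural_panel):
        geno, _ = natural_panel
        y = geno.values[:, 42].astype(float)
        scan = t.gwas_scan(y, geno)
        assert scan["stat"].idxmax() == 42

    def test_null_pvalues_uniform(self, natural_panel):
        geno, _ = natural_panel
        y = np.random.default_rng(2).normal(size=geno.n_individuals)
        scan = t.gwas_scan(y, geno)
        assert stats.kstest(scan["pvalue"], "uniform").pvalue > 0.01

    def test_structured_scan_runs_with_kinship(self, natural_panel):
        geno, labels = natural_panel
        y = np.random.default_rng(3).normal(size=geno.n_individuals) + labels
        scan = t.gwas_scan(y, geno, pcs=t.pca_matrix(geno, 3),
                           K=t.vanraden_kinship(geno))
        assert np.isfinite(scan["stat"]).all()

    def test_significant_hits_threshold(self):
        scan = pd.DataFrame({"marker": ["a", "b", "c"], "stat": [3.9, 4.2, 0.5]})
        assert t.significant_hits(scan, 4.0) == ["b"]
        assert t.significant_hits(scan.assign(stat=[3.9, 3.8, 0.5]), 4.0) == []


def _toy_binmap(cm, genotypes, population="F2"):
    n_bins = len(cm)
    bins = pd.DataFrame({"bin": [f"b{k}" for k in range(n_bins)], "chrom": "c1",
                         "start": np.arange(n_bins) * 1000 + 1,
                         "end": np.arange(n_bins) * 1000 + 999,
                         "n_snps": 1, "cm": np.asarray(cm, dtype=float)})
    return BinMap(bins=bins, genotypes=np.asarray(genotypes, dtype=np.int8),
                  ids=[f"i{k}" for k in range(len(genotypes))],
                  population=population)


class TestGenotypeExpectation:
    def test_at_genotyped_bin(self):
        bm = _toy_binmap([0.0, 10.0], [[0, 0], [2, 2], [1, 1]])
        a, d = t.im_genotype_expectation(bm, 0.0, "c1")
        assert a[0] == pytest.approx(1.0) and d[0] == pytest.approx(0.0)
        assert a[1] == pytest.approx(-1.0)
        assert d[2] == pytest.approx(1.0)

    def test_midpoint_between_opposite_homs_is_symmetric(self):
        bm = _toy_binmap([0.0, 10.0], [[0, 2]])
        a, d = t.im_genotype_expectation(bm, 5.0, "c1")
        assert a[0] == pytest.approx(0.0, abs=1e-12)

    def test_f2_het_flanks_match_markov_oracle(self):
        """Double-het flanks at r = 0.1 per side against an explicit
        two-chromatid Markov-chain enumeration."""
        r = 0.1
        d_cm = t.kosambi_cm(r)
        bm = _toy_binmap([0.0, 2 * d_cm], [[1, 1]])
        a, dom = t.im_genotype_expectation(bm, d_cm, "c1")

        # oracle: enumerate chromatid paths (allele_L, allele_Q, allele_R)
        T = np.array([[1 - r, r], [r, 1 - r]])
        probs = np.zeros(3)
        for l1 in (0, 1):
            for l2 in (0, 1):
                if l1 + l2 != 1:  # left genotype must be het
                    continue
                for r1 in (0, 1):
                    for r2 in (0, 1):
                        if r1 + r2 != 1:  # right genotype must be het
                            continue
                        w = 0.25 * T[l1, r1] * T[l2, r2]
                        for q1 in (0, 1):
                            for q2 in (0, 1):
                                pq = (T[l1, q1] * T[q1, r1] / T[l1, r1]
                                      * T[l2, q2] * T[q2, r2] / T[l2, r2])
                                probs[q1 + q2] += w * pq
        probs /= probs.sum()
        assert a[0] == pytest.approx(probs[0] - probs[2], abs=1e-10)
        assert dom[0] == pytest.approx(probs[1], abs=1e-10)

    def test_position_outside_chromosome_rejected(self):
        bm = _toy_binmap([0.0, 10.0], [[0, 2]])
        with pytest.raises(ValueError):
            t.im_genotype_expectation(bm, 99.0, "c1")


class TestCimScan:
    def test_constant_phenotype_gives_zero_lod(self, f2_binmap):
        scan = t.cim_scan(np.zeros(len(f2_binmap.ids)), f2_binmap)
        assert (scan["stat"] == 0).all()

    def test_zero_cofactors_equals_interval_mapping_oracle(self, f2_binmap):
        rng = np.random.default_rng(7)
        y = rng.normal(size=len(f2_binmap.ids))
        scan = t.cim_scan(y, f2_binmap, n_cofactors=0, step_cm=5.0)
        n = len(y)
        rss0 = ((y - y.mean()) ** 2).sum()
        for _, row in scan.sample(25, random_state=0).iterrows():
            a, d = t.im_genotype_expectation(f2_binmap, row["pos_cm"], row["chrom"])
            X = np.column_stack([np.ones(n), a, d - d.mean()])
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = ((y - X @ b) ** 2).sum()
            lod = n / 2 * np.log10(rss0 / rss1)
            assert row["stat"] == pytest.approx(max(lod, 0.0), abs=1e-8)

    def test_single_qtl_peak_located(self, founders_2chr):
        """One bin QTL explaining 30% of variance at n=300: LOD peak within
        5 cM of the true position in at least 18 of 20 seeded replicates."""
        f2 = t.make_f2_population(founders_2chr, 300, seed=88)
        binmap = t.make_binmap(f2)
        rng_pick = np.random.default_rng(8)
        j = int(rng_pick.integers(50, binmap.n_bins - 50))
        w = binmap.genotypes[:, j].astype(float)
        w = w - w.mean()
        true_cm = binmap.bins["cm"].iloc[j]
        true_chrom = binmap.bins["chrom"].iloc[j]
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = w * np.sqrt(0.3 / w.var()) + rng.normal(0, np.sqrt(0.7), len(w))
            scan = t.cim_scan(y, binmap, n_cofactors=3)
            peak = scan.loc[scan["stat"].idxmax()]
            if peak["chrom"] == true_chrom and abs(peak["pos_cm"] - true_cm) <= 5.0:
                hits += 1
        assert hits >= 18

    def test_too_many_cofactors_rejected(self, f2_binmap):
        y = np.random.default_rng(9).normal(size=len(f2_binmap.ids))
        with pytest.raises(ValueError):
            t.cim_scan(y, f2_binmap, n_cofactors=len(y) - 2)


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self, f2_binmap):
        y = np.random.default_rng(10).normal(size=len(f2_binmap.ids))
        thr = t.permutation_threshold(y, f2_binmap, n_perm=30, alpha=1.0, seed=1)
        thr05 = t.permutation_threshold(y, f2_binmap, n_perm=30, alpha=0.05, seed=1)
        assert thr <= thr05

    def test_seeded_threshold_reproducible(self, f2_binmap):
        y = np.random.default_rng(11).normal(size=len(f2_binmap.ids))
        a = t.permutation_threshold(y, f2_binmap, n_perm=25, seed=3)
        b = t.permutation_threshold(y, f2_binmap, n_perm=25, seed=3)
        assert a == b

    def test_minimum_permutations_enforced(self, f2_binmap):
        with pytest.raises(ValueError):
            t.permutation_threshold(np.zeros(len(f2_binmap.ids)), f2_binmap, n_perm=10)


class TestSupportInterval:
    def test_rule_application(self):
        lod = [1.0, 3.0, 5.0, 4.2, 3.4, 2.0]
        assert lod_support_interval(lod, 2, drop=1.5) == (1, 4)

    def test_clipped_at_chromosome_end(self):
        lod = [5.0, 4.0, 3.0, 2.0]
        assert lod_support_interval(lod, 0, drop=1.5) == (0, 2)

    def test_flat_profile_spans_everything(self):
        lod = [2.0] * 6
        assert lod_support_interval(lod, 3, drop=1.5) == (0, 5)


class TestPqtlIntegration:
    def _qtl(self, trait, chrom, lo, hi):
        return t.QTLRecord(trait=trait, chrom=chrom, peak_cm=0, peak_bp=(lo + hi) / 2,
                           lod=5, interval_bp=(lo, hi), interval_cm=(0, 1),
                           pve=10, effect_a=1.0)

    def test_overlapping_intervals_merge(self):
        groups = t.integrate_pqtl([self._qtl("PH", "c1", 10e6, 20e6),
                                   self._qtl("GYP", "c1", 15e6, 30e6)])
        assert len(groups) == 1
        assert groups[0]["interval_bp"] == (10e6, 30e6)

    def test_disjoint_intervals_do_not_group(self):
        groups = t.integrate_pqtl([self._qtl("PH", "c1", 10e6, 20e6),
                                   self._qtl("GYP", "c1", 25e6, 30e6)])
        assert groups == []

    def test_transitive_chaining(self):
        groups = t.integrate_pqtl([self._qtl("PH", "c1", 0, 10),
                                   self._qtl("GYP", "c1", 8, 20),
                                   self._qtl("EH", "c1", 18, 30)])
        assert len(groups) == 1 and groups[0]["n_qtl"] == 3

    def test_single_trait_group_not_pleiotropic(self):
        groups = t.integrate_pqtl([self._qtl("PH", "c1", 0, 10),
                                   self._qtl("PH", "c1", 5, 20)])
        assert groups == []


class TestTrmSelection:
    def _scan(self, stats_):
        m = len(stats_)
        return pd.DataFrame({"marker": [f"m{j}" for j in range(m)],
                             "chrom": "c1", "pos": np.arange(m), "stat": stats_})

    def test_top_k_matches_sort_oracle(self):
        rng = np.random.default_rng(12)
        stats_ = rng.permutation(100).astype(float)
        trms = t.select_trms(self._scan(stats_), 10)
        expected = [f"m{j}" for j in np.argsort(-stats_)[:10]]
        assert trms.markers == expected

    def test_nested_in_k(self):
        stats_ = np.random.default_rng(13).normal(size=50)
        small = set(t.select_trms(self._scan(stats_), 5).markers)
        large = set(t.select_trms(self._scan(stats_), 20).markers)
        assert small <= large

    def test_all_markers(self):
        scan = self._scan(np.arange(7.0))
        assert set(t.select_trms(scan, 7).markers) == set(scan["marker"])

    def test_ties_broken_deterministically(self):
        scan = self._scan(np.ones(10))
        a = t.select_trms(scan, 4).markers
        b = t.select_trms(scan.sample(frac=1, random_state=0).reset_index(drop=True), 4).markers
        assert a == b

    def test_random_selection_seeded(self):
        ids = [f"m{j}" for j in range(100)]
        a = t.select_random_markers(ids, 10, seed=5).markers
        b = t.select_random_markers(ids, 10, seed=5).markers
        assert a == b and len(set(a)) == 10

    def test_overlap(self):
        s1 = t.select_random_markers([f"m{j}" for j in range(20)], 20, seed=1)
        s2 = t.select_random_markers([f"m{j}" for j in range(20)], 20, seed=2)
        assert set(t.overlap_trms([s1, s2])) == {f"m{j}" for j in range(20)}
        assert t.overlap_trms([["a", "b", "x"], ["b", "x", "c"], ["x", "b"]]) == ["b", "x"]
        assert t.overlap_trms([["a"], ["b"]]) == []
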