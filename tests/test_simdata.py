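"""Population and phenotype simulators: segregation laws, map laws, variance targets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trmgs as t


class TestFounders:
    def test_parents_homozygous_and_opposite(self, founders_2chr):
        assert (founders_2chr.parent_a == 0).all()
        assert (founders_2chr.parent_b == 2).all()

    def test_positions_strictly_increasing(self, founders_2chr):
        for _, sub in founders_2chr.markers.groupby("chrom"):
            assert (np.diff(sub["pos"]) > 0).all()

    def test_seeded_determinism(self):
        ch = [t.ChromSpec("c1", 1_000_000, 50.0)]
        a = t.simulate_founders(100, ch, seed=5)
        b = t.simulate_founders(100, ch, seed=5)
        pd.testing.assert_frame_equal(a.markers, b.markers)
        assert np.array_equal(a.ancestral_freq, b.ancestral_freq)

    def test_zero_marker_chromosome_rejected(self):
        with pytest.raises(ValueError):
            t.simulate_founders(1, [("c1", 10_000, 1.0), ("c2", 10_000, 1.0)])

    def test_maf_law_bounds_enforced(self):
        with pytest.raises(ValueError):
            t.simulate_founders(10, [t.ChromSpec("c1", 10_000, 1.0)], maf_law=0.7)

    def test_point_mass_half_maf_in_panel(self):
        """Point mass at 0.5 and weak structure: mean MAF within 3 SE of 0.5
        (folding at 0.5 biases downward by less than binomial noise)."""
        founders = t.simulate_founders(
            1000, [t.ChromSpec("c1", 10_000_000, 50.0)], maf_law=0.5, seed=7
        )
        geno, _ = t.make_natural_population(founders, 2, 500, 1e-3, seed=8)
        maf = np.minimum(geno.values.mean(axis=0) / 2, 1 - geno.values.mean(axis=0) / 2)
        se = np.sqrt(0.25 / geno.n_individuals)
        assert abs(maf.mean() - 0.5) < 3 * se


class TestMeiosis:
    def _diplotype(self, m):
        return np.stack([np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8)])

    def test_zero_map_length_never_recombines(self):
        ch = [t.ChromSpec("c1", 1000, 0.0)]
        markers = pd.DataFrame({"marker": ["a", "b"], "chrom": "c1",
                                "pos": [1, 999], "cm": [0.0, 0.0]})
        rng = np.random.default_rng(1)
        for _ in range(200):
            g = t.simulate_meiosis(self._diplotype(2), markers, ch, rng)
            assert g[0] == g[1]

    def test_haldane_recombination_at_one_centimorgan(self):
        ch = [t.ChromSpec("c1", 1_000_000, 1.0)]
        markers = pd.DataFrame({"marker": ["a", "b"], "chrom": "c1",
                                "pos": [1, 1_000_000], "cm": [1e-6, 1.0]})
        rng = np.random.default_rng(2)
        n = 50_000
        rec = sum(
            (lambda g: g[0] != g[1])(t.simulate_meiosis(self._diplotype(2), markers, ch, rng))
            for _ in range(n)
        ) / n
        expected = (1 - np.exp(-0.02)) / 2
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec - expected) < 3 * se

    def test_negative_map_length_rejected(self):
        with pytest.raises(ValueError):
            t.ChromSpec("c1", 1000, -1.0)


class TestRIL:
    def test_residual_heterozygosity_vanishes_at_f21(self):
        ch = [t.ChromSpec("c1", 10_000_000, 50.0)]
        founders = t.simulate_founders(1000, ch, seed=3)
        ril = t.make_ril_population(founders, 200, 20, seed=4)
        assert (ril.values == 1).mean() < 1e-4

    def test_unlinked_loci_independent(self, ril_pop):
        # first marker of each chromosome
        idx = ril_pop.markers.groupby("chrom").head(1).index.to_numpy()
        a = ril_pop.values[:, idx[0]].astype(float)
        b = ril_pop.values[:, idx[1]].astype(float)
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 3 / np.sqrt(ril_pop.n_individuals)

    def test_tightly_linked_loci_concordant(self, ril_pop):
        cm = ril_pop.markers["cm"].to_numpy()
        chrom = ril_pop.markers["chrom"].to_numpy()
        gaps = np.where(chrom[1:] == chrom[:-1], np.diff(cm), np.inf)
        j = int(np.argmin(gaps))
        assert gaps[j] < 0.5
        a, b = ril_pop.values[:, j], ril_pop.values[:, j + 1]
        ok = (a != 1) & (b != 1)
        assert (a[ok] == b[ok]).mean() > 0.95

    def test_too_few_generations_rejected(self, founders_2chr):
        with pytest.raises(ValueError):
            t.make_ril_population(founders_2chr, 10, 4)

    def test_heterozygous_parents_rejected(self, founders_2chr):
        import dataclasses
        bad = dataclasses.replace(
            founders_2chr, parent_a=np.ones(founders_2chr.n_markers, dtype=np.int8)
        )
        with pytest.raises(ValueError):
            t.make_ril_population(bad, 10, 6)


class TestF2:
    def test_one_locus_segregates_1_2_1(self):
        ch = [t.ChromSpec("c1", 1000, 0.5)]
        founders = t.simulate_founders(1, ch, seed=5)
        f2 = t.make_f2_population(founders, 10_000, seed=6)
        counts = np.bincount(f2.values[:, 0], minlength=3)
        chi2 = (((counts - np.array([2500, 5000, 2500])) ** 2)
                / np.array([2500, 5000, 2500])).sum()
        assert stats.chi2.sf(chi2, 2) > 0.01

    def test_heterozygosity_near_half(self, f2_pop):
        het = (f2_pop.values == 1).mean()
        se = 0.5 / np.sqrt(f2_pop.n_individuals * f2_pop.n_markers / 50)  # loose (LD)
        assert abs(het - 0.5) < 3 * se + 0.02

    def test_monomorphic_parent_locus_stays_monomorphic(self, founders_2chr):
        import dataclasses
        pb = founders_2chr.parent_b.copy()
        pb[0] = 0  # parents now identical at locus 0
        founders = dataclasses.replace(founders_2chr, parent_b=pb)
        f2 = t.make_f2_population(founders, 50, seed=7)
        assert (f2.values[:, 0] == 0).all()

    def test_minimum_population_size(self, founders_2chr):
        with pytest.raises(ValueError):
            t.make_f2_population(founders_2chr, 1)


class TestNaturalPanel:
    def test_fst_bounds_rejected(self, founders_2chr):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                t.make_natural_population(founders_2chr, 2, 10, bad)

    def test_vanishing_fst_equalizes_subpop_frequencies(self, founders_2chr):
        geno, labels = t.make_natural_population(founders_2chr, 2, 300, 1e-6, seed=9)
        p1 = geno.values[labels == 0].mean(axis=0) / 2
        p2 = geno.values[labels == 1].mean(axis=0) / 2
        # only binomial sampling noise remains
        assert np.mean(np.abs(p1 - p2)) < 4 * np.sqrt(0.25 / 300)

    def test_hudson_fst_matches_target(self):
        founders = t.simulate_founders(
            5000, [t.ChromSpec("c1", 50_000_000, 100.0)],
            maf_law=lambda rng, size: rng.uniform(0.1, 0.5, size), seed=10,
        )
        geno, labels = t.make_natural_population(founders, 2, 200, 0.2, seed=11)
        n1 = n2 = 200.0  # inbred lines behave as haploid samples
        p1 = geno.values[labels == 0].mean(axis=0) / 2
        p2 = geno.values[labels == 1].mean(axis=0) / 2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num.sum() / den.sum()
        assert abs(fst - 0.2) < 0.05

    def test_pca_recovers_structure(self, natural_panel):
        geno, labels = natural_panel
        pcs = t.pca_matrix(geno, 1)
        sign_agreement = max(
            ((pcs[:, 0] > np.median(pcs[:, 0])) == (labels == 1)).mean(),
            ((pcs[:, 0] > np.median(pcs[:, 0])) == (labels == 0)).mean(),
        )
        assert sign_agreement > 0.95


class TestPhenotypes:
    def test_pure_noise_variance_components(self, f2_pop):
        arch = t.TraitArchitecture(fa=0, fd=0, faa=0, var_env=0.2, var_gxe=0.1,
                                   var_rep=0.05, var_resid=0.25)
        records, truth = t.simulate_phenotypes(f2_pop, arch, 3, 2, seed=40)
        assert np.allclose(truth["g_total"], 0.0)
        total = records["value"].var()
        assert abs(total - 0.6) < 0.25  # sampling noise on 3x2 env draws

    def test_realized_fractions_match_targets(self, f2_pop):
        arch = t.random_architecture(f2_pop.n_markers, 20, 10, 5,
                                     fa=0.35, fd=0.2, faa=0.1, seed=41)
        _, truth = t.simulate_phenotypes(f2_pop, arch, 2, 2, seed=42)
        vp = truth["phenotypic_variance"]
        assert abs(truth["g_additive"].var() / vp - 0.35) < 0.02
        assert abs(truth["g_dominance"].var() / vp - 0.20) < 0.02
        assert abs(truth["g_epistatic"].var() / vp - 0.10) < 0.02

    def test_additive_value_explains_target_share(self, f2_pop):
        arch = t.random_architecture(f2_pop.n_markers, 20, fa=0.5, seed=43,
                                     var_env=0, var_gxe=0, var_rep=0, var_resid=1.0)
        records, truth = t.simulate_phenotypes(f2_pop, arch, 1, 1, seed=44)
        y = records.set_index("individual")["value"].reindex(f2_pop.ids).to_numpy()
        r2 = np.corrcoef(y, truth["g_additive"])[0, 1] ** 2
        assert abs(r2 - 0.5) < 0.1

    def test_seeded_records_identical(self, f2_pop, f2_trait):
        arch, records, _ = f2_trait
        again, _ = t.simulate_phenotypes(f2_pop, arch, 2, 2, seed=32)
        pd.testing.assert_frame_equal(records, again)

    def test_dominance_in_homozygous_population_rejected(self):
        ch = [t.ChromSpec("c1", 10_000_000, 50.0)]
        founders = t.simulate_founders(200, ch, seed=45)
        ril = t.make_ril_population(founders, 80, 20, seed=46)
        arch = t.random_architecture(200, 10, 5, 0, fa=0.3, fd=0.2, seed=47)
        if not (ril.values == 1).any():
            with pytest.raises(ValueError):
                t.simulate_phenotypes(ril, arch, 2, 2, seed=48)

    def test_missing_and_error_injection_rates(self, f2_pop):
        miss = t.inject_missing(f2_pop, 0.02, seed=49)
        assert abs((miss.values == t.MISSING).mean() - 0.02) < 0.005
        err = t.inject_errors(f2_pop, 0.005, seed=50)
        changed = (err.values != f2_pop.values).mean()
        assert abs(changed - 0.005) < 0.002
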