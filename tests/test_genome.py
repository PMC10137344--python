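"""Genome map, founders, traits, inheritance, genetic values, phenotypes."""

import numpy as np
import pytest
from scipy import stats

import kisbreed as kb
from kisbreed.exceptions import (
    CalibrationError,
    ConfigurationError,
    DataShapeError,
)
from kisbreed.genome import _sample_sources


class TestMakeGenome:
    def test_degenerate_single_marker(self):
        g = kb.make_genome(1, 1.0, 1, 0.5, seed=1)
        assert g.n_markers == 1
        assert g.positions[0] == 0.0
        assert g.founder_freqs[0] == 0.5

    def test_grid_dimensions(self):
        g = kb.make_genome(10, 1.0, 500, (0.05, 0.95), seed=7)
        assert g.n_markers == 5000
        assert np.all(np.bincount(g.chrom) == 500)
        assert np.all((g.founder_freqs >= 0.05) & (g.founder_freqs <= 0.95))

    def test_seed_determinism(self):
        g1 = kb.make_genome(2, 1.0, 10, seed=3)
        g2 = kb.make_genome(2, 1.0, 10, seed=3)
        g3 = kb.make_genome(2, 1.0, 10, seed=4)
        assert np.array_equal(g1.founder_freqs, g2.founder_freqs)
        assert not np.array_equal(g1.founder_freqs, g3.founder_freqs)

    @pytest.mark.parametrize("bad", [dict(n_chromosomes=0), dict(markers_per_chromosome=0)])
    def test_invalid_counts(self, bad):
        with pytest.raises(ConfigurationError):
            kb.make_genome(**{"n_chromosomes": 1, "markers_per_chromosome": 1, **bad})

    def test_marker_id_round_trip(self, small_genome):
        ids = small_genome.marker_ids()
        for idx in (0, 49, 50, small_genome.n_markers - 1):
            assert small_genome.marker_index(ids[idx]) == idx


class TestFounders:
    def test_balanced_sexes(self, small_genome):
        pop = kb.simulate_founders(small_genome, 200, seed=1)
        assert len(pop.males()) == 100
        assert len(pop.females()) == 100
        assert pop.generation[0] == "hist0"

    def test_fixed_frequency_forces_dosage(self):
        g = kb.make_genome(1, 1.0, 5, 1.0, seed=0)
        pop = kb.simulate_founders(g, 10, seed=1)
        assert np.all(pop.dosages() == 2)

    def test_observed_frequency_within_binomial_ci(self):
        g = kb.make_genome(1, 1.0, 1, 0.3, seed=0)
        pop = kb.simulate_founders(g, 2000, seed=5)
        count = int(pop.dosages().sum())  # out of 4000 gametes
        lo, hi = stats.binom.interval(0.9999, 4000, 0.3)
        assert lo <= count <= hi

    def test_odd_count_rejected(self, small_genome):
        with pytest.raises(ConfigurationError):
            kb.simulate_founders(small_genome, 201, seed=1)

    def test_dosages_in_range(self, small_founders):
        assert np.isin(small_founders.dosages(), (0, 1, 2)).all()


class TestAssignTrait:
    def test_disjoint_traits(self, small_traits):
        t1, t2 = small_traits
        overlap = np.intersect1d(t1.qtl_indices, t2.qtl_indices)
        assert len(overlap) == 0
        assert len(np.union1d(t1.qtl_indices, t2.qtl_indices)) == 60

    def test_founder_variance_calibrated_to_one(self, small_founders, small_traits):
        for arch in small_traits:
            tbv = kb.true_breeding_value(small_founders.dosages(), arch)
            assert np.var(tbv, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_single_qtl_variance_matches_2pqa2(self):
        # Hardy-Weinberg founders, one QTL: additive variance = 2 p q a^2
        p, a, n = 0.4, 0.7, 60_000
        g = kb.make_genome(1, 1.0, 1, p, seed=0)
        founders = kb.simulate_founders(g, n, seed=9)
        z = founders.dosages()[:, 0].astype(float)
        raw_var = np.var(z * a, ddof=1)
        assert raw_var == pytest.approx(2 * p * (1 - p) * a**2, rel=0.05)

    def test_monomorphic_qtls_raise(self):
        g = kb.make_genome(1, 1.0, 3, 1.0, seed=0)
        founders = kb.simulate_founders(g, 20, seed=1)
        with pytest.raises(CalibrationError):
            kb.assign_trait(g, 3, founders, seed=2)


class TestAddNonadditive:
    def test_zero_proportion_is_identity(self, small_founders, small_traits):
        arch = small_traits[0]
        assert kb.add_nonadditive(arch, 0.0, "both", small_founders) is arch

    def test_dominance_count(self, small_founders, small_traits):
        out = kb.add_nonadditive(small_traits[0], 0.1, "dominance", small_founders, seed=3)
        assert np.count_nonzero(out.dominance) == 2  # 10% of 20 QTLs

    def test_epistasis_pairs_disjoint(self, small_founders, small_traits):
        arch = small_traits[1]  # 40 QTLs
        out = kb.add_nonadditive(arch, 0.2, "epistasis", small_founders, seed=4)
        members = np.concatenate([out.epi_a, out.epi_b])
        assert len(out.epi_effect) == 8
        assert len(np.unique(members)) == 16

    def test_recalibrated_total_variance(self, small_founders, small_traits):
        out = kb.add_nonadditive(small_traits[0], 0.3, "both", small_founders, seed=5)
        g = kb.genotypic_value(small_founders.dosages(), out)
        assert np.var(g, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_proportion(self, small_founders, small_traits):
        with pytest.raises(ConfigurationError):
            kb.add_nonadditive(small_traits[0], 1.5, "both", small_founders)


class TestMeiosis:
    def test_zero_length_chromosome_returns_parental_haplotype(self):
        g = kb.make_genome(1, 0.0, 1, 0.5, seed=0)
        parent = np.array([[1], [0]], dtype=np.uint8)
        gametes = {int(kb.meiosis(parent, g, seed=s)[0]) for s in range(20)}
        assert gametes == {0, 1}  # whole haplotypes, both reachable

    def test_homozygous_parent_gives_fixed_gamete(self, small_genome):
        hap = np.ones(small_genome.n_markers, dtype=np.uint8)
        parent = np.stack([hap, hap])
        assert np.array_equal(kb.meiosis(parent, small_genome, seed=1), hap)

    def test_recombinant_fraction_matches_haldane(self):
        # two markers d Morgans apart; empirical recombinant fraction within
        # 3 binomial standard errors of (1 - exp(-2d)) / 2
        n = 100_000
        rng = np.random.default_rng(17)
        for d in (0.05, 0.2, 0.5):
            g = kb.make_genome(1, 2 * d, 2, 0.5, seed=0)
            src = _sample_sources(g, n, rng)
            r_emp = np.mean(src[:, 0] != src[:, 1])
            r_th = 0.5 * (1 - np.exp(-2 * d))
            se = np.sqrt(r_th * (1 - r_th) / n)
            assert abs(r_emp - r_th) < 3 * se

    def test_shape_mismatch(self, small_genome):
        with pytest.raises(DataShapeError):
            kb.meiosis(np.zeros((2, 3), dtype=np.uint8), small_genome, seed=0)


class TestProduceOffspring:
    def test_balanced_design_counts(self, small_genome, small_founders):
        sires = small_founders.subset(small_founders.males()[:5])
        dams = small_founders.subset(small_founders.females()[:20])
        off = kb.produce_offspring(sires, dams, 200, small_genome, "hist1", seed=1)
        assert off.n == 200
        assert len(off.males()) == 100 and len(off.females()) == 100
        dam_counts = np.unique(off.dam, return_counts=True)[1]
        assert np.all(dam_counts == 10)
        sire_dams = {
            s: len(np.unique(off.dam[off.sire == s])) for s in np.unique(off.sire)
        }
        assert set(sire_dams.values()) == {4}

    def test_single_pair_pedigree(self, small_genome, small_founders):
        sire = small_founders.subset(small_founders.males()[:1])
        dam = small_founders.subset(small_founders.females()[:1])
        off = kb.produce_offspring(sire, dam, 2, small_genome, "x", seed=2)
        assert np.all(off.sire == sire.ids[0]) and np.all(off.dam == dam.ids[0])

    def test_mendelian_consistency_exhaustive(self, small_genome, small_founders):
        # no offspring allele that is absent from the transmitting parent
        sire = small_founders.subset(small_founders.males()[:1])
        dam = small_founders.subset(small_founders.females()[:1])
        off = kb.produce_offspring(sire, dam, 40, small_genome, "x", seed=3)
        for hap, parent in ((0, sire), (1, dam)):
            alleles = off.haplotypes[:, hap, :]
            p_haps = parent.haplotypes[0]
            ok = (alleles == p_haps[0]) | (alleles == p_haps[1])
            assert ok.all()

    def test_indivisible_counts_rejected_when_strict(self, small_genome, small_founders):
        sires = small_founders.subset(small_founders.males()[:3])
        dams = small_founders.subset(small_founders.females()[:7])
        with pytest.raises(ConfigurationError):
            kb.produce_offspring(sires, dams, 200, small_genome, "x", seed=1)
        off = kb.produce_offspring(
            sires, dams, 200, small_genome, "x", seed=1, strict=False
        )
        dam_counts = np.unique(off.dam, return_counts=True)[1]
        assert dam_counts.max() - dam_counts.min() <= 1


class TestGeneticValues:
    def test_tbv_direct_dot_product(self):
        arch = kb.TraitArchitecture(
            "t", np.array([0, 1, 2]), np.array([0.5, -1.0, 2.0]),
            np.zeros(3), np.array([], dtype=int), np.array([], dtype=int),
            np.array([]), scale=1.0,
        )
        Z = np.array([[2, 1, 0], [0, 0, 0]])
        tbv = kb.true_breeding_value(Z, arch)
        assert tbv[0] == pytest.approx(2 * 0.5 + 1 * -1.0)
        assert tbv[1] == 0.0

    def test_tbv_linearity_in_effects(self, small_founders, small_traits):
        from dataclasses import replace

        arch = small_traits[0]
        doubled = replace(arch, additive=2 * arch.additive)
        Z = small_founders.dosages()
        assert np.allclose(
            kb.true_breeding_value(Z, doubled), 2 * kb.true_breeding_value(Z, arch)
        )

    def test_genotypic_value_reduces_to_tbv(self, small_founders, small_traits):
        Z = small_founders.dosages()
        assert np.allclose(
            kb.genotypic_value(Z, small_traits), kb.true_breeding_value(Z, small_traits)
        )

    def test_single_het_dominance(self):
        arch = kb.TraitArchitecture(
            "t", np.array([0]), np.array([0.0]), np.array([0.4]),
            np.array([], dtype=int), np.array([], dtype=int), np.array([]), 1.0,
        )
        assert kb.genotypic_value(np.array([[1]]), arch)[0] == pytest.approx(0.4)
        assert kb.genotypic_value(np.array([[2]]), arch)[0] == 0.0

    def test_genotypic_value_brute_force_oracle(self, rng):
        n_qtl, n_ind = 8, 30
        qtl = np.sort(rng.choice(20, n_qtl, replace=False))
        a = rng.normal(size=n_qtl)
        d = rng.normal(size=n_qtl)
        pair_members = rng.choice(qtl, 4, replace=False)
        arch = kb.TraitArchitecture(
            "t", qtl, a, d, pair_members[:2], pair_members[2:],
            rng.normal(size=2), scale=1.3,
        )
        Z = rng.integers(0, 3, size=(n_ind, 20))
        got = kb.genotypic_value(Z, arch)
        # independent term-by-term summation
        expect = np.zeros(n_ind)
        for i in range(n_ind):
            s = 0.0
            for j, q in enumerate(qtl):
                s += Z[i, q] * a[j]
                if Z[i, q] == 1:
                    s += d[j]
            for k in range(2):
                s += (
                    arch.epi_effect[k]
                    * (Z[i, arch.epi_a[k]] - 1)
                    * (Z[i, arch.epi_b[k]] - 1)
                )
            expect[i] = 1.3 * s
        assert np.allclose(got, expect)

    def test_missing_qtl_columns(self, small_traits):
        with pytest.raises(DataShapeError):
            kb.true_breeding_value(np.zeros((3, 5)), small_traits[1])


class TestPhenotype:
    def test_h2_one_is_noise_free(self, rng):
        g = rng.normal(size=50)
        assert np.array_equal(kb.phenotype(g, 1.0, seed=1), g)

    def test_h2_half_regression_slope_and_r2(self, rng):
        g = rng.normal(size=20_000)
        y = kb.phenotype(g, 0.5, seed=2)
        slope, _, r, *_ = stats.linregress(g, y)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert r**2 == pytest.approx(0.5, abs=0.03)

    def test_seed_reproducibility(self, rng):
        g = rng.normal(size=100)
        assert np.array_equal(kb.phenotype(g, 0.3, seed=7), kb.phenotype(g, 0.3, seed=7))

    def test_invalid_h2(self, rng):
        with pytest.raises(ConfigurationError):
            kb.phenotype(rng.normal(size=5), 0.0)
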