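import numpy as np
import pytest

from agpopgen import synthetic_data as sd
from agpopgen.core_io import MISSING, VariantDataset, build_cohorts
from agpopgen.population_structure import (
    cityblock_distance,
    cohort_allele_counts,
    diversity_stats,
    hudson_fst,
    nj_tree,
    pca,
    tajima_constants,
)
from tests.conftest import make_dataset, random_additive_tree


class TestCityblockDistance:
    def test_identical_samples_zero(self):
        ds = make_dataset([[0, 1, 2], [0, 1, 2]])
        dm = cityblock_distance(ds)
        assert dm[0, 1] == 0.0

    def test_opposite_homozygotes(self):
        ds = make_dataset([[0, 2], [2, 0]])
        assert cityblock_distance(ds)[0, 1] == 4.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(5, 20)).astype(np.int8)
        ds = make_dataset(g)
        dm = cityblock_distance(ds)
        for i in range(5):
            for j in range(5):
                assert dm[i, j] == float(np.abs(g[i] - g[j]).sum())

    def test_missing_genotypes_rejected(self):
        ds = make_dataset([[0, MISSING], [1, 1]])
        with pytest.raises(ValueError, match="missing"):
            cityblock_distance(ds)


class TestPca:
    def test_duplicated_sample_identical_scores(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        g[5] = g[0]
        res = pca(make_dataset(g), n_components=3)
        assert np.allclose(res.scores[0], res.scores[5])

    def test_scores_mean_centred_and_variance_ordered(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        res = pca(make_dataset(g), n_components=4)
        assert np.all(np.abs(res.scores.mean(axis=0)) < 1e-8)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_two_deme_separation_on_pc1(self):
        cfg = sd.SimulationConfig(seed=13, samples_per_deme=40, n_variants=3000,
                                  target_fst=0.01)
        ds, _, _ = sd.simulate_two_deme_genotypes(cfg)
        res = pca(ds, n_components=2)
        demes = cfg.deme_of_samples()
        sign = np.sign(res.scores[:, 0])
        # PC1 sign should separate the demes almost perfectly
        agreement = max((sign[demes == 0] > 0).mean(), (sign[demes == 0] < 0).mean())
        assert agreement > 0.95

    def test_degenerate_input_rejected(self):
        g = np.ones((4, 10), dtype=np.int8)
        with pytest.raises(ValueError):
            pca(make_dataset(g), n_components=2)

    def test_too_many_components_rejected(self):
        ds = make_dataset(np.zeros((3, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            pca(ds, n_components=5)


class TestNjTree:
    def test_three_leaf_closed_form(self):
        import skbio

        # d(ab)=3, d(ac)=8, d(bc)=9 -> a=(3+8-9)/2=1, b=3-1=2, c=8-1=7
        dm = skbio.DistanceMatrix([[0, 3, 8], [3, 0, 9], [8, 9, 0]], ids=list("abc"))
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 7.0}

    def test_fewer_than_three_leaves_rejected(self):
        import skbio

        dm = skbio.DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_additive_five_leaf_exact_recovery(self):
        rng = np.random.default_rng(7)
        true = random_additive_tree(5, rng)
        dm = true.tip_tip_distances()
        est = nj_tree(dm)
        assert est.compare_rfd(true) == 0.0
        back = est.tip_tip_distances()
        assert np.allclose(back.filter(dm.ids).data, dm.data, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_eight_leaf_topology_recovery(self, seed):
        rng = np.random.default_rng(seed)
        true = random_additive_tree(8, rng)
        est = nj_tree(true.tip_tip_distances())
        assert est.compare_rfd(true) == 0.0

    def test_two_deme_samples_form_clades(self):
        cfg = sd.SimulationConfig(seed=15, samples_per_deme=8, n_variants=2000,
                                  target_fst=0.05)
        ds, _, _ = sd.simulate_two_deme_genotypes(cfg)
        tree = nj_tree(cityblock_distance(ds))
        demes = dict(zip(ds.sample_ids, cfg.deme_of_samples()))
        # root on the longest internal edge: the two resulting subtrees
        # should split the samples by deme
        internal = max(
            (n for n in tree.non_tips(include_self=False)), key=lambda n: n.length or 0
        )
        clade = {t.name for t in internal.tips()}
        labels = {demes[s] for s in clade}
        other = {demes[s] for s in set(ds.sample_ids) - clade}
        assert len(labels) == 1 and len(other) == 1 and labels != other


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        ac1 = np.array([[0, 20]])  # p1 = 1
        ac2 = np.array([[20, 0]])  # p2 = 0
        assert hudson_fst(ac1, ac2).fst == 1.0

    def test_single_variant_worked_example(self):
        # p1=0.5 (20 copies), p2=0.25 (20 copies):
        # N = 0.25^2 - 0.25/19 - 0.1875/19 = 3/76; D = 0.5; fst = 3/38
        ac1 = np.array([[10, 10]])
        ac2 = np.array([[15, 5]])
        res = hudson_fst(ac1, ac2)
        assert res.fst == pytest.approx(3 / 38, abs=1e-12)

    def test_matches_per_site_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n1 = int(rng.integers(2, 41))
            n2 = int(rng.integers(2, 41))
            m = int(rng.integers(1, 101))
            a1 = rng.integers(0, n1 + 1, size=m)
            a2 = rng.integers(0, n2 + 1, size=m)
            ac1 = np.stack([n1 - a1, a1], axis=1)
            ac2 = np.stack([n2 - a2, a2], axis=1)
            num = den = 0.0
            for v in range(m):
                p1, p2 = a1[v] / n1, a2[v] / n2
                num += (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
                den += p1 * (1 - p2) + p2 * (1 - p1)
            if den == 0:
                continue
            assert hudson_fst(ac1, ac2).fst == pytest.approx(num / den, abs=1e-12)

    def test_self_comparison_numerator_negative(self):
        rng = np.random.default_rng(5)
        a = rng.integers(1, 20, size=50)
        ac = np.stack([20 - a, a], axis=1)
        res = hudson_fst(ac, ac)
        assert res.numerators.sum() < 0  # finite-sample correction

    def test_panmictic_estimate_is_small(self):
        cfg = sd.SimulationConfig(seed=17, samples_per_deme=30, n_variants=5000,
                                  target_fst=1e-6)
        ds, _, _ = sd.simulate_two_deme_genotypes(cfg)
        demes = cfg.deme_of_samples()
        ids = np.asarray(ds.sample_ids)
        res = hudson_fst(
            cohort_allele_counts(ds, list(ids[demes == 0])),
            cohort_allele_counts(ds, list(ids[demes == 1])),
        )
        assert abs(res.fst) < 2 / 60  # 2 / min cohort copies bound

    def test_between_demes_exceeds_within_deme(self):
        higher = 0
        for seed in range(10):
            cfg = sd.SimulationConfig(seed=seed, samples_per_deme=40,
                                      n_variants=4000, target_fst=0.005)
            ds, _, _ = sd.simulate_two_deme_genotypes(cfg)
            demes = cfg.deme_of_samples()
            ids = np.asarray(ds.sample_ids)
            between = hudson_fst(
                cohort_allele_counts(ds, list(ids[demes == 0])),
                cohort_allele_counts(ds, list(ids[demes == 1])),
            ).fst
            rng = np.random.default_rng(seed)
            perm = rng.permutation(np.flatnonzero(demes == 0))
            within = hudson_fst(
                cohort_allele_counts(ds, list(ids[perm[:20]])),
                cohort_allele_counts(ds, list(ids[perm[20:]])),
            ).fst
            higher += between > within
        assert higher >= 9

    def test_undefined_denominator_flagged(self):
        ac = np.array([[20, 0]])
        with pytest.raises(ZeroDivisionError):
            hudson_fst(ac, ac)


class TestDiversity:
    def _four_haplotype_dataset(self):
        # haplotypes {000, 001, 011, 111} as two diploids
        hap = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=np.int8)
        g = hap[0::2] + hap[1::2]
        return VariantDataset(
            "c", np.array([10, 20, 30]), list("AAA"), list("TTT"), g,
            ["s1", "s2"], haplotypes=hap,
        )

    def test_worked_example(self):
        ds = self._four_haplotype_dataset()
        s = diversity_stats(ds, ds.sample_ids, accessible_sites=3)
        assert s.theta_pi * 3 == pytest.approx(10 / 6, abs=1e-12)
        assert s.theta_w * 3 == pytest.approx(3 / (11 / 6), abs=1e-12)
        assert s.tajima_d == pytest.approx(0.16766, abs=5e-5)

    def test_monomorphic_cohort(self):
        ds = make_dataset(np.zeros((5, 4), dtype=np.int8))
        s = diversity_stats(ds, ds.sample_ids, accessible_sites=100)
        assert s.theta_pi == 0 and s.theta_w == 0 and s.tajima_d is None

    def test_constants_consistency(self):
        # a1 at n=4 is the harmonic number 1 + 1/2 + 1/3
        c = tajima_constants(4)
        assert c["a1"] == pytest.approx(11 / 6, abs=1e-15)
        assert c["a2"] == pytest.approx(1 + 1 / 4 + 1 / 9, abs=1e-15)


class TestCohortIntegration:
    def test_pairwise_fst_long_format(self):
        import pandas as pd
        from agpopgen.population_structure import pairwise_fst

        cfg = sd.SimulationConfig(seed=19, samples_per_deme=12, n_variants=1000)
        ds, samples, _ = sd.simulate_two_deme_genotypes(cfg)
        cohorts = build_cohorts(samples, min_size=10)
        table = pairwise_fst(ds, cohorts)
        assert list(table.columns) == ["cohort1", "cohort2", "fst", "n_variants"]
        assert len(table) == 1
        assert table["fst"].iloc[0] < 1
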