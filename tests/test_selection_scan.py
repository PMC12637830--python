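import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from agpopgen import synthetic_data as sd
from agpopgen.selection_scan import (
    calibrate_window_size,
    detect_peaks,
    diplotype_cluster,
    h12,
    h12_scan,
    low_het_clusters,
)
from tests.conftest import make_dataset


def _haps_from_counts(counts, n_snps=6):
    """Distinct haplotype patterns replicated to the given counts."""
    n_patterns = len(counts)
    patterns = (
        np.arange(n_patterns)[:, None] >> np.arange(n_snps)[None, :]
    ) & 1
    return np.repeat(patterns, counts, axis=0).astype(np.int8)


class TestH12:
    def test_identical_haplotypes(self):
        assert h12(np.zeros((8, 5), dtype=np.int8)) == (1.0, 1.0)

    def test_ten_distinct_haplotypes(self):
        hap = _haps_from_counts([1] * 10)
        v, h1 = h12(hap)
        assert v == pytest.approx(0.12, abs=1e-15)  # (0.2)^2 + 8 * 0.01
        assert h1 == pytest.approx(0.10, abs=1e-15)

    def test_spectrum_4_3_2_1(self):
        hap = _haps_from_counts([4, 3, 2, 1])
        v, h1 = h12(hap)
        assert v == pytest.approx(0.54, abs=1e-15)  # 0.7^2 + 0.04 + 0.01
        assert h1 == pytest.approx(0.30, abs=1e-15)

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            h12(np.zeros((1, 5), dtype=np.int8))

    def test_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(3)
        hap = rng.integers(0, 2, size=(30, 12)).astype(np.int8)
        base = h12(hap)
        assert h12(hap[rng.permutation(30)]) == base
        assert h12(hap[:, rng.permutation(12)]) == base

    def test_h12_at_least_h1_with_equality_iff_monomorphic(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            hap = rng.integers(0, 2, size=(12, 4)).astype(np.int8)
            v, h1 = h12(hap)
            assert v >= h1 - 1e-15
            n_distinct = np.unique(hap, axis=0).shape[0]
            if n_distinct == 1:
                assert v == h1 == 1.0
            else:
                assert v > h1


class TestH12Scan:
    def test_window_count(self):
        hap = np.random.default_rng(0).integers(0, 2, (10, 3000)).astype(np.int8)
        pos = np.arange(1, 3001) * 10
        profile = h12_scan(hap, pos, window_size=1500)
        assert len(profile) == 2
        assert profile.start[0] == 10 and profile.end[0] == 15000

    def test_too_few_snps_warns_and_is_empty(self):
        hap = np.zeros((4, 10), dtype=np.int8)
        with pytest.warns(UserWarning):
            profile = h12_scan(hap, np.arange(1, 11), window_size=100)
        assert len(profile) == 0

    def test_sweep_located_at_planted_window(self):
        cfg = sd.SimulationConfig(
            seed=33, n_variants=15_000,
            sweep=sd.SweepSpec(start_snp=6000, end_snp=7499, swept_fraction=0.6),
        )
        hap, pos, _ = sd.simulate_sweep_haplotypes(cfg, n_haplotypes=50)
        profile = h12_scan(hap, pos, window_size=1500)
        top = int(np.argmax(profile.h12))
        assert profile.h12[top] >= 0.36
        assert abs(top - 4) <= 1  # planted window index 4


class TestCalibration:
    def test_degenerate_data_has_no_qualifying_size(self):
        hap = np.zeros((10, 5000), dtype=np.int8)
        with pytest.raises(ValueError, match="no candidate"):
            calibrate_window_size(hap, np.arange(1, 5001), [200, 500, 1000])

    def test_unsorted_candidates_rejected(self):
        hap = np.zeros((10, 100), dtype=np.int8)
        with pytest.raises(ValueError, match="sorted"):
            calibrate_window_size(hap, np.arange(1, 101), [500, 200])

    def test_window_of_one_rejected(self):
        hap = np.zeros((10, 100), dtype=np.int8)
        with pytest.raises(ValueError):
            calibrate_window_size(hap, np.arange(1, 101), [1])

    def test_neutral_choice_and_monotone_percentiles(self):
        cfg = sd.SimulationConfig(seed=11, n_variants=30_000)
        hap, pos, _ = sd.simulate_sweep_haplotypes(cfg, n_haplotypes=50, neutral=True)
        chosen, table = calibrate_window_size(
            hap, pos, [100, 200, 500, 1000, 1500, 2000]
        )
        values = table["h12_percentile"].to_numpy()
        assert np.all(np.diff(values) <= 1e-12)  # non-increasing in size
        assert chosen in {100, 200, 500}
        # every candidate at least as large as the chosen one qualifies
        assert np.all(values[table["window_size"] >= chosen] < 0.1)


class TestDetectPeaks:
    def test_flat_profile_no_peaks(self):
        hap = np.random.default_rng(1).integers(0, 2, (20, 2000)).astype(np.int8)
        profile = h12_scan(hap, np.arange(1, 2001) * 10, window_size=100)
        profile.h12[:] = 0.05
        assert detect_peaks(profile).empty

    def test_planted_sweep_single_annotated_peak(self):
        cfg = sd.SimulationConfig(
            seed=37, n_variants=30_000,
            sweep=sd.SweepSpec(start_snp=15_000, end_snp=16_499, swept_fraction=0.7),
        )
        hap, pos, _ = sd.simulate_sweep_haplotypes(cfg, n_haplotypes=60)
        profile = h12_scan(hap, pos, window_size=1500, contig="3L")
        loci = pd.DataFrame(
            [{"name": "Vgsc", "contig": "3L",
              "start": int(pos[15_000]), "end": int(pos[16_499])}]
        )
        peaks = detect_peaks(profile, loci, percentile=95)
        assert len(peaks) == 1
        assert peaks["annotation"].iloc[0] == "Vgsc"
        assert peaks["start"].iloc[0] <= pos[16_499]
        assert peaks["end"].iloc[0] >= pos[15_000]

    def test_neutral_peak_fraction_bounded(self):
        cfg = sd.SimulationConfig(seed=41, n_variants=40_000)
        hap, pos, _ = sd.simulate_sweep_haplotypes(cfg, n_haplotypes=40, neutral=True)
        profile = h12_scan(hap, pos, window_size=200)
        peaks = detect_peaks(profile, percentile=99)
        n_peak_windows = peaks["n_windows"].sum() if len(peaks) else 0
        assert n_peak_windows <= np.ceil(0.01 * len(profile))

    def test_empty_profile_rejected(self):
        from agpopgen.selection_scan import H12Profile

        empty = H12Profile("3L", 100, np.array([], int), np.array([], int),
                           np.array([]), np.array([]))
        with pytest.raises(ValueError):
            detect_peaks(empty)


class TestDiplotypeCluster:
    def test_identical_diplotypes_merge_first_at_zero(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(6, 30)).astype(np.int8)
        g[1] = g[0]
        d = diplotype_cluster(make_dataset(g))
        first = d.merge[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 0.0

    def test_homozygous_cluster_heterozygosity_zero(self):
        g = np.array([[0, 2, 0, 2], [2, 0, 2, 0], [1, 1, 1, 1]], dtype=np.int8)
        d = diplotype_cluster(make_dataset(g))
        assert d.heterozygosity[0] == 0.0
        assert d.heterozygosity[2] == 1.0

    def test_swept_cluster_enriched_for_marker(self):
        rng = np.random.default_rng(43)
        n, m = 40, 60
        g = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        core = rng.integers(0, 2, size=m).astype(np.int8) * 2  # homozygous core
        swept = np.arange(12)
        g[swept] = core  # identical low-het diplotypes
        marker = np.zeros((n, 1), dtype=np.int8)
        marker[swept] = 2
        g = np.hstack([g, marker])
        ds = make_dataset(g)
        ann = pd.DataFrame(
            [{"contig": ds.contig, "position": int(ds.positions[-1]), "alt": "T",
              "gene_id": "G", "aa_change": "A1T", "effect": "non-synonymous"}]
        )
        d = diplotype_cluster(ds, annotation=ann)
        clusters = low_het_clusters(d, ds, cut_height=1.0, het_max=0.2)
        assert clusters, "swept cluster not found"
        best = min(clusters, key=lambda c: c["mean_heterozygosity"])
        in_cluster = np.array([s in set(best["sample_ids"]) for s in ds.sample_ids])
        carries = np.array([bool(d.substitutions[s]) for s in ds.sample_ids])
        table = [
            [int((in_cluster & carries).sum()), int((in_cluster & ~carries).sum())],
            [int((~in_cluster & carries).sum()), int((~in_cluster & ~carries).sum())],
        ]
        odds, _ = fisher_exact(table)
        assert odds > 1
        assert int(ds.positions[-1]) in best["distinguishing_positions"]

    def test_full_heterozygosity_gives_no_low_het_clusters(self):
        g = np.ones((6, 10), dtype=np.int8)
        ds = make_dataset(g)
        d = diplotype_cluster(ds)
        assert low_het_clusters(d, ds, cut_height=100.0, het_max=0.0) == []

    def test_cut_at_zero_yields_no_clusters_of_size_two(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(8, 20)).astype(np.int8)  # all distinct
        ds = make_dataset(g)
        d = diplotype_cluster(ds)
        assert low_het_clusters(d, ds, cut_height=0.0, het_max=1.0) == []

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            diplotype_cluster(make_dataset([[0, 1]]))

    def test_newick_serialisation_contains_all_leaves(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=(5, 20)).astype(np.int8)
        d = diplotype_cluster(make_dataset(g))
        nwk = d.to_newick()
        assert nwk.endswith(";")
        for s in d.sample_ids:
            assert s in nwk
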