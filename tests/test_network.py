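import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from mcca.network import (
    NetworkError,
    RasterMatrix,
    bin_raster,
    compare_groups,
    distance_correlation_fit,
    pair_class,
    pair_table,
    pairwise_distances,
    pearson_matrix,
    population_summary,
    shuffle_events,
    shuffle_raster,
    spatial_clustering_test,
    subgroup_pair_summary,
)
from mcca.synthetic import GeneratorConfig, generate_population, sample_event_train


class TestBinRaster:
    def test_events_in_same_328ms_bin(self):
        r = bin_raster([np.array([0.1, 0.2])], duration_s=10.0)
        assert r.occupancy[:, 0].sum() == 1
        assert r.occupancy[0, 0]

    def test_event_at_04s_lands_in_bin_one(self):
        r = bin_raster([np.array([0.4])], duration_s=10.0)
        assert r.occupancy[1, 0]

    def test_bin_count_drops_trailing_partial_bin(self):
        r = bin_raster([np.array([])], duration_s=32.8)
        assert r.n_bins == 100

    def test_event_beyond_duration_rejected(self):
        with pytest.raises(NetworkError, match="duration"):
            bin_raster([np.array([12.0])], duration_s=10.0)


class TestPearson:
    def test_identical_rasters_correlate_perfectly(self, rng):
        occ = rng.uniform(size=(200, 1)) < 0.2
        r, kept = pearson_matrix(RasterMatrix(np.hstack([occ, occ])))
        assert r[0, 1] == pytest.approx(1.0)

    def test_complementary_rasters_anticorrelate_perfectly(self):
        a = np.zeros((100, 1), dtype=bool)
        a[::2] = True
        r, _ = pearson_matrix(RasterMatrix(np.hstack([a, ~a])))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_independent_rasters_have_null_mean(self, rng):
        occ = rng.uniform(size=(1100, 160)) < 0.1
        r, kept = pearson_matrix(RasterMatrix(occ))
        iu = np.triu_indices(kept.size, 1)
        assert iu[0].size >= 10_000
        assert abs(float(np.mean(r[iu]))) < 0.005

    def test_silent_cells_excluded(self, rng):
        occ = rng.uniform(size=(100, 3)) < 0.2
        occ[:, 1] = False
        r, kept = pearson_matrix(RasterMatrix(occ))
        assert kept.tolist() == [0, 2]

    def test_invariant_under_relabeling_and_joint_bin_permutation(self, rng):
        occ = rng.uniform(size=(300, 6)) < 0.15
        r, _ = pearson_matrix(RasterMatrix(occ))
        perm_cells = rng.permutation(6)
        r2, _ = pearson_matrix(RasterMatrix(occ[:, perm_cells]))
        np.testing.assert_allclose(r2, r[np.ix_(perm_cells, perm_cells)], atol=1e-12)
        perm_bins = rng.permutation(300)
        r3, _ = pearson_matrix(RasterMatrix(occ[perm_bins]))
        np.testing.assert_allclose(r3, r, atol=1e-12)


class TestShuffle:
    def _trains(self, rng, n=20):
        return [sample_event_train(rng.uniform(0.3, 4.0), 360.0, 1.0, rng)
                for _ in range(n)]

    def test_per_cell_counts_conserved_by_time_shuffle(self, rng):
        trains = self._trains(rng)
        out = shuffle_events(trains, 360.0, mode="shuffle_times", rng=rng)
        assert [t.size for t in out] == [t.size for t in trains]

    def test_identity_permutation_is_a_bijection(self, rng):
        trains = self._trains(rng)
        out = shuffle_events(trains, 360.0, mode="permute_identity", rng=rng)
        assert sorted(t.size for t in out) == sorted(t.size for t in trains)

    def test_shuffled_gaps_at_least_one_second(self, rng):
        trains = self._trains(rng)
        out = shuffle_events(trains, 360.0, mode="full", rng=rng)
        for t in out:
            if t.size > 1:
                assert np.diff(t).min() >= 1.0

    def test_seeded_reproducibility(self, rng):
        trains = self._trains(rng)
        a = shuffle_events(trains, 360.0, rng=np.random.default_rng(5))
        b = shuffle_events(trains, 360.0, rng=np.random.default_rng(5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_infeasible_separation_names_the_cell(self):
        with pytest.raises(NetworkError, match="cell 0"):
            shuffle_events([np.linspace(0, 9, 20)], 10.0, mode="shuffle_times",
                           rng=np.random.default_rng(0))

    def test_unknown_mode_rejected(self):
        with pytest.raises(NetworkError):
            shuffle_events([np.array([1.0])], 10.0, mode="bogus")


class TestDistances:
    def test_pythagorean_triple(self):
        d = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_coincident_points(self):
        d = pairwise_distances(np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert d[0, 1] == 0.0

    def test_triangle_inequality_on_random_fixture(self, rng):
        xy = rng.uniform(0, 440, size=(100, 2))
        d = pairwise_distances(xy)
        i, j, k = rng.integers(0, 100, size=(3, 500))
        assert np.all(d[i, k] <= d[i, j] + d[j, k] + 1e-9)


class TestDistanceFit:
    def test_constant_r_gives_exactly_zero_slope(self):
        pairs = pd.DataFrame(
            {"cell_i": ["a", "a", "b"], "cell_j": ["b", "c", "c"],
             "pearson_r": [0.1, 0.1, 0.1], "distance_um": [10.0, 50.0, 90.0],
             "pair_class": ["MM"] * 3}
        )
        fit = distance_correlation_fit(pairs)
        assert fit.slope == 0.0

    def test_too_few_pairs_rejected(self):
        pairs = pd.DataFrame(
            {"cell_i": ["a"], "cell_j": ["b"], "pearson_r": [0.1],
             "distance_um": [10.0], "pair_class": ["MM"]}
        )
        with pytest.raises(NetworkError):
            distance_correlation_fit(pairs)

    def test_local_ensembles_give_negative_significant_slope(self):
        cfg = GeneratorConfig(
            n_cells=100, silent_fraction=0.0, astrocyte_fraction=0.0,
            class_weights=(0.0, 1.0, 0.0), class_rates_per_min=(0.15, 1.5, 4.0),
            n_ensembles=6, ensemble_rate_per_min=2.0, p_participate=0.9,
            ensemble_sigma_um=50.0, seed=17,
        )
        rec, truth = generate_population(cfg)
        raster = bin_raster(truth.event_times_s, cfg.duration_s)
        pairs = pair_table(raster, truth.activity_class, rec.roi_xy_um)
        fit = distance_correlation_fit(pairs)
        assert fit.slope < 0 and fit.p_value < 0.01
        # the same data after the two-step randomization has no distance trend
        sr = shuffle_raster(truth.event_times_s, cfg.duration_s, mode="full",
                            rng=np.random.default_rng(18))
        sfit = distance_correlation_fit(
            pair_table(sr, truth.activity_class, rec.roi_xy_um)
        )
        assert sfit.p_value > 0.05


class TestSubgroupPairs:
    def test_pair_class_is_order_normalised(self):
        assert pair_class("medium", "low") == "LM"
        assert pair_class("hyper", "silent") == "SH"

    def test_combinatorics_of_two_low_one_medium(self):
        occ = np.zeros((50, 3), dtype=bool)
        occ[::5, 0] = occ[::7, 1] = occ[::3, 2] = True
        pairs = pair_table(
            RasterMatrix(occ), ["low", "low", "medium"],
            np.array([[0.0, 0], [10, 0], [20, 0]]),
        )
        counts = pairs["pair_class"].value_counts()
        assert counts.get("LL", 0) == 1
        assert counts.get("LM", 0) == 2
        assert "MM" not in counts

    def test_no_hyper_cells_means_no_hyper_pair_classes(self, rng):
        occ = rng.uniform(size=(200, 6)) < 0.2
        pairs = pair_table(
            RasterMatrix(occ), ["low", "low", "medium", "medium", "low", "medium"],
            rng.uniform(0, 440, size=(6, 2)),
        )
        summary = subgroup_pair_summary(pairs)
        assert set(summary["pair_class"]) == {"LL", "LM", "MM"}

    def test_shared_ensembles_raise_within_class_synchrony(self, rng):
        n_bins = 1000
        shared = rng.uniform(size=n_bins) < 0.1
        occ = np.zeros((n_bins, 6), dtype=bool)
        for c in range(3):  # medium cells share events
            occ[:, c] = shared | (rng.uniform(size=n_bins) < 0.02)
        for c in range(3, 6):  # low cells are independent
            occ[:, c] = rng.uniform(size=n_bins) < 0.05
        pairs = pair_table(
            RasterMatrix(occ),
            ["medium"] * 3 + ["low"] * 3,
            rng.uniform(0, 440, size=(6, 2)),
        )
        summary = subgroup_pair_summary(pairs).set_index("pair_class")
        assert summary.loc["MM", "median_r"] > summary.loc["LL", "median_r"]


class TestSpatialClustering:
    def test_single_class_yields_empty_result(self, rng):
        res = spatial_clustering_test(["medium"] * 10,
                                      rng.uniform(0, 440, (10, 2)),
                                      n_permutations=100, rng=rng)
        assert len(res) == 0

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(NetworkError):
            spatial_clustering_test(["low", "medium"], np.zeros((2, 2)),
                                    n_permutations=10, rng=rng)

    def test_planted_cluster_detected(self):
        rng = np.random.default_rng(21)
        xy = rng.uniform(0, 440, size=(60, 2))
        hyper = rng.choice(60, 8, replace=False)
        xy[hyper] = np.array([220.0, 220.0]) + rng.normal(0, 20, size=(8, 2))
        labels = np.array(["medium"] * 60, dtype=object)
        labels[hyper] = "hyper"
        res = spatial_clustering_test(labels, np.clip(xy, 0, 440),
                                      n_permutations=999, rng=rng)
        hh = res[res.pair_class == "HH"]
        assert float(hh.p_value.iloc[0]) < 0.01

    def test_random_labels_give_unremarkable_p(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 440, size=(40, 2))
        labels = rng.choice(["low", "medium"], size=40)
        res = spatial_clustering_test(labels, xy, n_permutations=499, rng=rng)
        assert set(res.pair_class) == {"LL", "LM", "MM"}
        assert (res.p_value > 0.01).all()


def _cells_frame(n_silent, freqs, kinds=None):
    rows = []
    i = 0
    for _ in range(n_silent):
        rows.append((f"c{i}", "neuron", 0.0, "silent", 0, np.nan))
        i += 1
    for f in freqs:
        cls = "low" if f < 0.3 else ("medium" if f <= 3 else "hyper")
        rows.append((f"c{i}", "neuron", f, cls, max(1, int(f * 6)), 40.0))
        i += 1
    df = pd.DataFrame(rows, columns=[
        "cell_id", "kind", "frequency_trans_per_min", "activity_class",
        "n_events", "mean_auc"])
    if kinds is not None:
        df["kind"] = kinds
    return df


class TestPopulationSummary:
    def test_density_from_counted_cells_and_field(self):
        cells = _cells_frame(100, [1.0] * 171)
        s = population_summary(cells, field_um=440.0)
        assert s["density_cells_per_mm2"] == pytest.approx(271 / 0.44**2)

    def test_active_fraction_percent(self):
        s = population_summary(_cells_frame(20, [1.0] * 80), field_um=440.0)
        assert s["fraction_active_pct"] == pytest.approx(80.0)

    def test_subgroup_proportions_sum_to_hundred(self):
        s = population_summary(
            _cells_frame(10, [0.1, 0.2, 1.0, 2.0, 3.5]), field_um=440.0
        )
        assert sum(s["subgroup_pct_of_active"].values()) == pytest.approx(100.0)

    def test_zero_neurons_rejected(self):
        cells = _cells_frame(0, [1.0], kinds=["astrocyte"])
        with pytest.raises(NetworkError):
            population_summary(cells, field_um=440.0)


class TestCompareGroups:
    def _summaries(self, rng, mean_rate, n_rec, n_cells=60):
        out = []
        for _ in range(n_rec):
            freqs = 60 * rng.poisson(mean_rate * 6, size=n_cells) / 360.0
            out.append(
                population_summary(_cells_frame(10, list(freqs)), field_um=440.0)
            )
        return out

    def test_identical_groups_rarely_significant(self):
        rejections = 0
        n_sims = 40
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            rep = compare_groups(self._summaries(rng, 1.0, 8),
                                 self._summaries(rng, 1.0, 6))
            p = rep["metrics"]["mean_frequency_trans_per_min"]["p_value"]
            rejections += p < 0.05
        assert rejections <= max(2, int(0.1 * n_sims))

    def test_reported_effect_size_is_detected(self):
        rng = np.random.default_rng(1)
        rep = compare_groups(self._summaries(rng, 0.74, 8),
                             self._summaries(rng, 1.2, 6))
        m = rep["metrics"]["mean_frequency_trans_per_min"]
        assert m["p_value"] < 0.05

    def test_single_recording_group_flagged_not_testable(self, rng):
        rep = compare_groups(self._summaries(rng, 1.0, 1),
                             self._summaries(rng, 1.0, 6))
        assert rep["testable"] is False

    def test_anova_and_chi2_sections_present(self):
        rng = np.random.default_rng(2)
        rep = compare_groups(self._summaries(rng, 0.74, 8),
                             self._summaries(rng, 1.2, 6))
        assert rep["cumulative_anova"]["testable"]
        assert rep["subgroup_chi2"]["testable"]
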