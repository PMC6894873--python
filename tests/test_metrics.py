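"""Metric formulas, the registry, data-frame builders and their
FRAGSTATS-consistency invariants."""

import numpy as np
import pandas as pd
import pytest

import patchstats as ps
from patchstats import metrics as m


class TestFormulas:
    @pytest.mark.parametrize(
        "n_cells, sides, expected",
        [(115, 106, 2.409091), (13, 26, 1.625), (2, 6, 1.0)],
    )
    def test_shape_index(self, n_cells, sides, expected):
        assert m.shape_index(n_cells, sides) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize(
        "perimeter, area, expected",
        [
            (10600, 1_150_000, 1.129654),
            (600, 20_000, 1.011893),
            (2600, 130_000, 1.100096),
        ],
    )
    def test_fractal_dimension(self, perimeter, area, expected):
        assert m.fractal_dimension(perimeter, area) == pytest.approx(expected, abs=1e-6)

    def test_fractal_dimension_degenerate_unit_area(self):
        assert np.isnan(m.fractal_dimension(4.0, 1.0))

    @pytest.mark.parametrize(
        "perimeter, area, expected",
        [(10600, 115, 92.173913), (2600, 13, 200.0), (400, 1, 400.0)],
    )
    def test_perimeter_area_ratio(self, perimeter, area, expected):
        assert m.perimeter_area_ratio(perimeter, area) == pytest.approx(expected, abs=1e-6)

    def test_proportion_of_landscape(self):
        assert m.proportion_of_landscape(24729, 321075) == pytest.approx(7.701939, abs=1e-6)
        assert m.proportion_of_landscape(24729, 321075, percent=False) == pytest.approx(
            0.077019, abs=1e-6
        )
        assert m.proportion_of_landscape(5, 5) == 100

    def test_patch_density(self):
        assert m.patch_density(193, 321075) == pytest.approx(0.060111, abs=1e-6)
        assert m.patch_density(206, 321075) == pytest.approx(0.064159, abs=1e-6)
        assert m.patch_density(0, 100) == 0

    def test_edge_density(self):
        assert m.edge_density(1431600, 321075) == pytest.approx(4.458771, abs=1e-6)
        assert m.edge_density(0, 100) == 0

    def test_edge_density_m2_is_exact_decimal_shift(self):
        ha = m.edge_density(2203800.0, 321075)
        assert m.edge_density(2203800.0, 321075, hectares=False) == ha / 1e4

    def test_landscape_shape_index(self):
        assert m.landscape_shape_index(22038, 321075) == pytest.approx(9.716931, abs=1e-6)

    def test_largest_patch_index(self):
        assert m.largest_patch_index([1, 3], 4) == 75
        assert m.largest_patch_index([7], 7) == 100

    def test_shannon_diversity(self):
        assert m.shannon_diversity_index([1.0]) == 0
        # proportions of the worked 2-class example landscape
        assert m.shannon_diversity_index([0.07701939, 0.92298061]) == pytest.approx(
            0.27142863, abs=1e-6
        )
        assert m.shannon_diversity_index([0.25] * 4) == pytest.approx(np.log(4))

    @pytest.mark.parametrize(
        "values, weights, stat, expected",
        [
            ((1, 3), (1, 1), "am", 2.0),
            ((1, 3), (0.1, 0.9), "am", 2.8),
            ((1, 3), None, "mn", 2.0),
            ((1, 2, 10), None, "md", 2.0),
            ((1, 2, 10), None, "ra", 9.0),
            ((5, 5, 5), None, "sd", 0.0),
            ((5, 5, 5), None, "cv", 0.0),
            ((2, 4), None, "sd", 1.0),  # population sd, not sample
        ],
    )
    def test_distribution_statistics(self, values, weights, stat, expected):
        assert m.distribution_statistic(values, weights, stat) == pytest.approx(expected)

    def test_distribution_statistic_drops_nan_and_all_nan_is_nan(self):
        assert m.distribution_statistic([np.nan, 4.0], [1, 1], "mn") == 4.0
        assert np.isnan(m.distribution_statistic([np.nan, np.nan], None, "mn"))


class TestContagion:
    def test_aggregated_halves_exceed_interspersed_mosaic(self):
        halves = np.ones((60, 60), int)
        halves[:, 30:] = 2
        aggregated = ps.Landscape(halves, res=(100, 100)).contagion()
        interspersed = ps.random_mosaic((60, 60), (0.5, 0.5), seed=2).contagion()
        assert 0 <= interspersed < aggregated <= 100

    def test_equal_share_random_mosaic_approaches_zero(self):
        # with m equal classes arranged at random, every of the m^2 adjacency
        # states is equally likely and the contagion entropy saturates
        ls = ps.random_mosaic((150, 150), (0.25,) * 4, seed=3)
        assert ls.contagion() < 1.0

    def test_single_class_undefined(self):
        ls = ps.landscape_from_array([[1, 1]], res=(100, 100))
        assert np.isnan(ls.contagion())

    def test_matches_direct_summation_oracle(self, mosaic):
        ls = mosaic(13)
        adj = ls.adjacency
        counts = adj.data_adjacency_counts().astype(float)
        areas = np.array([(ls.cells == c).sum() for c in ls.classes], float)
        p = areas / areas.sum()
        expected = 0.0
        ordered = counts + np.diag(np.diag(counts))
        for g in range(len(p)):
            row = ordered[g].sum()
            for k in range(len(p)):
                pgk = p[g] * ordered[g, k] / row
                if pgk > 0:
                    expected += pgk * np.log(pgk)
        expected = (1 + expected / (2 * np.log(len(p)))) * 100
        assert ls.contagion() == pytest.approx(expected, rel=1e-12)


class TestTotalEdge:
    def test_two_cell_grid_with_and_without_boundary(self):
        ls = ps.landscape_from_array([[1, 2]], res=(100, 100))
        assert ls.total_edge() == 100
        assert ls.total_edge(count_boundary=True) == 100 + 600

    def test_two_class_landscape_class_edges_equal_landscape_edge(self, mosaic):
        ls = mosaic(5, probs=(0.5, 0.5))
        te = ls.total_edge()
        assert ls.total_edge(class_val=1) == te
        assert ls.total_edge(class_val=2) == te

    def test_class_sum_double_counts_landscape_total(self, mosaic):
        ls = mosaic(29)
        class_sum = sum(ls.total_edge(class_val=c) for c in ls.classes)
        assert class_sum == pytest.approx(2 * ls.total_edge())

    def test_unknown_class_rejected(self, mosaic):
        with pytest.raises(ValueError):
            mosaic(3).total_edge(class_val=99)


class TestRegistry:
    def test_exposes_95_level_qualified_labels(self):
        assert ps.num_level_labels() == 95
        assert len(ps.PATCH_METRICS) == 6
        assert len(ps.CLASS_METRICS) == 44
        assert len(ps.LANDSCAPE_METRICS) == 45

    def test_labels_unique_and_snake_case(self):
        labels = list(ps.REGISTRY)
        assert len(labels) == len(set(labels))
        assert all(label == label.lower() and " " not in label for label in labels)

    def test_every_label_computes_on_a_three_class_mosaic(self):
        ls = ps.random_mosaic((50, 50), (0.4, 0.35, 0.25), seed=97)
        patch_df = ls.compute_patch_metrics_df()
        class_df = ls.compute_class_metrics_df()
        land_df = ls.compute_landscape_metrics_df()
        assert list(patch_df.columns) == ["class_val", *ps.PATCH_METRICS]
        assert list(class_df.columns) == list(ps.CLASS_METRICS)
        assert list(land_df.columns) == list(ps.LANDSCAPE_METRICS)
        # aggregate + distribution columns are all finite here
        assert np.isfinite(land_df.drop(columns=["contagion"]).to_numpy()).all()


class TestDataFrames:
    def test_patch_table_layout(self, reference_patches):
        df = reference_patches.compute_patch_metrics_df()
        assert df.index.name == "patch_id"
        assert list(df.columns) == [
            "class_val",
            "area",
            "perimeter",
            "perimeter_area_ratio",
            "shape_index",
            "fractal_dimension",
            "euclidean_nearest_neighbor",
        ]
        assert len(df) == 3

    def test_patch_metric_subset(self, reference_patches):
        df = reference_patches.compute_patch_metrics_df(metrics=["area"])
        assert list(df.columns) == ["class_val", "area"]

    def test_patch_rejects_class_level_label(self, reference_patches):
        with pytest.raises(ValueError, match="total_edge"):
            reference_patches.compute_patch_metrics_df(metrics=["total_edge"])

    def test_class_table_drops_landscape_only_labels(self, mosaic):
        df = mosaic(1).compute_class_metrics_df(
            metrics=["proportion_of_landscape", "shannon_diversity_index"]
        )
        assert list(df.columns) == ["proportion_of_landscape"]

    def test_landscape_table_drops_class_only_labels(self, mosaic):
        df = mosaic(1).compute_landscape_metrics_df(
            metrics=["proportion_of_landscape", "shannon_diversity_index"]
        )
        assert list(df.columns) == ["shannon_diversity_index"]

    def test_class_subset_single_row(self, mosaic):
        df = mosaic(1).compute_class_metrics_df(classes=[1])
        assert list(df.index) == [1]

    def test_absent_class_rejected(self, mosaic):
        with pytest.raises(ValueError):
            mosaic(1).compute_class_metrics_df(classes=[9])

    def test_metrics_kws_fractional_pland(self, mosaic):
        ls = mosaic(1)
        df = ls.compute_class_metrics_df(
            metrics_kws={"proportion_of_landscape": {"percent": False}}
        )
        percent = ls.compute_class_metrics_df()["proportion_of_landscape"]
        assert np.allclose(df["proportion_of_landscape"] * 100, percent)

    def test_metrics_kws_invalid_keyword_rejected(self, mosaic):
        with pytest.raises(ValueError):
            mosaic(1).compute_class_metrics_df(
                metrics_kws={"total_area": {"percent": True}}
            )
        with pytest.raises(ValueError):
            mosaic(1).compute_class_metrics_df(metrics_kws={"no_such": {}})

    def test_subsetting_never_changes_values(self, mosaic):
        ls = mosaic(37)
        full = ls.compute_class_metrics_df()
        sub = ls.compute_class_metrics_df(metrics=["edge_density", "area_am"])
        pd.testing.assert_frame_equal(sub, full[["edge_density", "area_am"]])

    def test_landscape_np_is_class_sum(self, mosaic):
        ls = mosaic(43)
        cdf, ldf = ls.compute_class_metrics_df(), ls.compute_landscape_metrics_df()
        assert ldf["number_of_patches"].iloc[0] == cdf["number_of_patches"].sum()

    def test_single_class_grid_shdi_zero(self):
        ls = ps.landscape_from_array(np.ones((5, 5), int), res=(100, 100))
        assert ls.compute_landscape_metrics_df()["shannon_diversity_index"].iloc[0] == 0


class TestInvariantsOnSeededMosaics:
    @pytest.mark.parametrize("seed", range(20))
    def test_fragstats_consistency_identities(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(rng.integers(2, 5)))
        ls = ps.random_mosaic((30, 30), probs, seed=seed + 1000)
        cdf = ls.compute_class_metrics_df(
            metrics=[
                "proportion_of_landscape",
                "total_edge",
                "number_of_patches",
                "largest_patch_index",
            ]
        )
        ldf = ls.compute_landscape_metrics_df(
            metrics=["total_edge", "number_of_patches", "largest_patch_index"]
        )
        assert cdf["proportion_of_landscape"].sum() == pytest.approx(100)
        assert cdf["total_edge"].sum() == pytest.approx(2 * ldf["total_edge"].iloc[0])
        assert cdf["number_of_patches"].sum() == ldf["number_of_patches"].iloc[0]
        assert cdf["largest_patch_index"].max() == pytest.approx(
            ldf["largest_patch_index"].iloc[0]
        )
        ed_ha = ls.edge_density()
        assert ls.edge_density(hectares=False) == ed_ha / 1e4

    def test_shape_index_at_least_one_and_fd_in_range(self, mosaic):
        df = mosaic(3, canvas=(50, 50)).compute_patch_metrics_df(
            metrics=["shape_index", "fractal_dimension", "area"]
        )
        assert (df["shape_index"] >= 1).all()
        multi = df[df["area"] > 0.01]  # multi-cell patches
        assert multi["fractal_dimension"].between(0.9, 2.0).all()


class TestRectangularCells:
    def test_side_count_metrics_are_nan_with_warning(self):
        ls = ps.landscape_from_array([[1, 1], [1, 2]], res=(50, 100))
        with pytest.warns(UserWarning, match="square cells"):
            df = ls.compute_patch_metrics_df(metrics=["shape_index"])
        assert df["shape_index"].isna().all()
        with pytest.warns(UserWarning, match="square cells"):
            assert np.isnan(ls.landscape_shape_index())

    def test_length_based_metrics_still_defined(self):
        ls = ps.landscape_from_array([[1, 1], [1, 2]], res=(50, 100))
        # 600 m of raster border plus the two interior unlike sides
        # (one vertical at 100 m, one horizontal at 50 m)
        assert ls.total_edge(count_boundary=True) == 600 + 100 + 50
        assert ls.total_area() == 4 * 50 * 100 / 1e4


class TestEnnStatistics:
    def test_undefined_enn_excluded_with_warning(self):
        # two classes: class 1 has two patches, class 2 a single patch
        cells = np.array([[1, 0, 1], [0, 2, 0]])
        ls = ps.landscape_from_array(cells, res=(100, 100))
        cdf = ls.compute_class_metrics_df(metrics=["euclidean_nearest_neighbor_mn"])
        assert cdf.loc[1, "euclidean_nearest_neighbor_mn"] == pytest.approx(200.0)
        with pytest.warns(UserWarning, match="nearest-neighbor"):
            ls.compute_metric("euclidean_nearest_neighbor_mn", class_val=2)
        assert np.isnan(cdf.loc[2, "euclidean_nearest_neighbor_mn"])
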