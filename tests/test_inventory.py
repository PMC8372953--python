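"""Inventory I/O, structure statistics, diversity and IVI conventions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_plot
from forestcarbon.inventory import (
    InventoryFormatError,
    TreeRecord,
    class_distribution,
    density_and_basal_area,
    importance_values,
    jaccard_similarity,
    one_way_anova,
    plot_weighted_mean,
    read_inventory,
    sampling_intensity,
    shannon_index,
    write_inventory,
)


class TestRecords:
    def test_census_threshold_enforced(self):
        with pytest.raises(ValueError):
            TreeRecord(plot_id="p", species="s", dbh=4.9, height=5.0)

    def test_basal_area_of_10cm_stem(self):
        r = TreeRecord(plot_id="p", species="s", dbh=10.0, height=5.0)
        assert r.basal_area_m2 == pytest.approx(math.pi * 0.05**2)


class TestIO:
    def test_round_trip(self, small_stand, tmp_path):
        path = tmp_path / "inv.csv"
        write_inventory(small_stand, path)
        back = read_inventory(path)
        assert [p.plot_id for p in back] == [p.plot_id for p in small_stand]
        for a, b in zip(back, small_stand):
            assert a.records == b.records

    def test_threshold_filter_logged(self, tmp_path, caplog):
        path = tmp_path / "inv.csv"
        path.write_text(
            "plot,species,dbh,height\np1,a,10,8\np1,b,4.9,3\np1,c,6,5\n"
        )
        with caplog.at_level("INFO"):
            plots = read_inventory(path)
        assert sum(p.n_trees for p in plots) == 2
        assert "rejected 1" in caplog.text

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "inv.csv"
        path.write_text("plot,species,dbh,height\n")
        assert read_inventory(path) == []

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "inv.csv"
        path.write_text("plot,species,dbh\np1,a,10\n")
        with pytest.raises(InventoryFormatError, match="height"):
            read_inventory(path)

    def test_non_numeric_row_reports_line(self, tmp_path):
        path = tmp_path / "inv.csv"
        path.write_text("plot,species,dbh,height\np1,a,10,8\np1,b,oops,3\n")
        with pytest.raises(InventoryFormatError, match="line 3"):
            read_inventory(path)

    def test_tab_delimiter_autodetected(self, tmp_path):
        path = tmp_path / "inv.tsv"
        path.write_text("plot\tspecies\tdbh\theight\np1\ta\t10\t8\n")
        plots = read_inventory(path)
        assert plots[0].records[0].dbh == 10.0


class TestSamplingIntensity:
    @pytest.mark.parametrize(
        "z,sigma,e,expected",
        [(1.96, 7.0, 7.0, 4), (1.96, 20.0, 10.0, 16), (1.0, 1.0, 1.0, 1)],
    )
    def test_examples(self, z, sigma, e, expected):
        assert sampling_intensity(z, sigma, e).n_required == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            sampling_intensity(1.96, 0.0, 5.0)


class TestStructure:
    def test_density_direct_ratio(self):
        plot = make_plot("p1", [(f"s{i}", 10.0, 8.0) for i in range(16)])
        s = density_and_basal_area([plot])
        assert s.density == pytest.approx(100.0)

    def test_basal_area_per_ha(self):
        plot = make_plot("p1", [("a", 10.0, 8.0)], area_ha=1.0)
        s = density_and_basal_area([plot])
        assert s.basal_area == pytest.approx(0.007854, abs=1e-6)

    def test_plot_weighted_pooling(self):
        assert plot_weighted_mean([890.48, 1214.06], [21, 4]) == pytest.approx(
            942.25, abs=0.005
        )

    def test_per_stratum_summaries(self):
        plots = [
            make_plot("p1", [("a", 10, 8)] * 4, stratum="DDF"),
            make_plot("p2", [("a", 10, 8)] * 8, stratum="DDF"),
            make_plot("p3", [("a", 10, 8)] * 2, stratum="MDF"),
        ]
        s = density_and_basal_area(plots)
        mean, sd, n = s.per_stratum["DDF"]["density"]
        assert n == 2
        assert mean == pytest.approx((4 / 0.16 + 8 / 0.16) / 2)


class TestShannon:
    def test_single_species_zero(self):
        assert shannon_index([17]) == 0.0

    def test_uniform_four_species(self):
        assert shannon_index([3, 3, 3, 3]) == pytest.approx(2.0)

    def test_hand_summation(self):
        # -(0.5 log2 0.5 + 0.3 log2 0.3 + 0.2 log2 0.2)
        assert shannon_index([5, 3, 2]) == pytest.approx(1.48548, abs=1e-4)

    def test_zero_counts_ignored(self):
        assert shannon_index([5, 0, 3, 0, 2]) == pytest.approx(shannon_index([5, 3, 2]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])

    @given(
        st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=30)
    )
    @settings(deadline=None, max_examples=50)
    def test_bounded_by_log_richness(self, counts):
        h = shannon_index(counts)
        assert -1e-9 <= h <= math.log2(len(counts)) + 1e-9


class TestJaccard:
    def test_reported_total_convention(self):
        a = {f"x{i}" for i in range(93)}
        b = {f"x{i}" for i in range(37)} | {f"y{i}" for i in range(35)}
        assert jaccard_similarity(a, b, "paper_total", total_override=129) == pytest.approx(
            28.68, abs=0.005
        )

    def test_standard_union(self):
        a = {f"x{i}" for i in range(93)}
        b = {f"x{i}" for i in range(37)} | {f"y{i}" for i in range(35)}
        assert jaccard_similarity(a, b) == pytest.approx(100 * 37 / 128, abs=1e-9)

    def test_disjoint_is_zero_and_symmetric(self):
        assert jaccard_similarity({"a"}, {"b"}) == 0.0
        assert jaccard_similarity({"a", "b"}, {"b", "c"}) == jaccard_similarity(
            {"b", "c"}, {"a", "b"}
        )

    def test_paper_total_needs_override(self):
        with pytest.raises(ValueError):
            jaccard_similarity({"a"}, {"a"}, "paper_total")


class TestImportanceValues:
    def test_single_species_totals(self):
        plot = make_plot("p1", [("only", 10, 8)] * 5)
        assert importance_values([plot], convention="paper_100")["ivi"].sum() == pytest.approx(100.0)
        assert importance_values([plot], convention="standard_300")["ivi"].sum() == pytest.approx(300.0)

    @pytest.mark.parametrize(
        "convention,component_total,ivi_total",
        [("paper_100", 100 / 3, 100.0), ("standard_300", 100.0, 300.0)],
    )
    def test_normalisation_invariants(self, small_stand, convention, component_total, ivi_total):
        table = importance_values(small_stand, convention=convention)
        for col in ("relative_density", "relative_frequency", "relative_dominance"):
            assert table[col].sum() == pytest.approx(component_total, abs=0.1)
        assert table["ivi"].sum() == pytest.approx(ivi_total, abs=0.1)

    def test_component_sum_is_ivi(self, small_stand):
        table = importance_values(small_stand)
        np.testing.assert_allclose(
            table[["relative_density", "relative_frequency", "relative_dominance"]].sum(axis=1),
            table["ivi"],
        )

    def test_subplot_quadrat_changes_frequency(self):
        plot = make_plot(
            "p1",
            [("a", 10, 8), ("a", 10, 8), ("b", 10, 8)],
            subplots=["s1", "s2", "s1"],
        )
        by_subplot = importance_values([plot], quadrat="subplot", convention="standard_300")
        by_plot = importance_values([plot], quadrat="plot", convention="standard_300")
        assert by_subplot.loc["a", "relative_frequency"] == pytest.approx(100 * 2 / 3)
        assert by_plot.loc["a", "relative_frequency"] == pytest.approx(50.0)

    def test_unknown_quadrat_rejected(self, small_stand):
        with pytest.raises(ValueError):
            importance_values(small_stand, quadrat="transect")


class TestClassDistribution:
    def test_all_in_one_class(self):
        records = [TreeRecord("p", "a", 7.0, 5.0)] * 5
        table = class_distribution(records, "dbh", edges=[5, 10, 20])
        assert table["percent"].iloc[0] == pytest.approx(100.0)

    def test_percents_sum_to_100(self, small_stand):
        records = [r for p in small_stand for r in p.records]
        table = class_distribution(records, "dbh")
        assert table["percent"].sum() == pytest.approx(100.0, abs=0.01)

    def test_below_range_bucket(self):
        records = [TreeRecord("p", "a", 6.0, 0.5), TreeRecord("p", "a", 6.0, 7.0)]
        table = class_distribution(records, "height", edges=[1.3, 5, 10])
        assert table.attrs["below_range"] == 1
        assert table["count"].sum() == 1

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            class_distribution([TreeRecord("p", "a", 6.0, 5.0)], "dbh", edges=[5, 5, 10])


class TestAnova:
    def test_identical_groups_zero(self):
        f, p = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0)

    def test_hand_computation(self):
        f, p = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert f == pytest.approx(13.5)
        assert 0 < p < 0.05

    def test_location_invariance(self):
        f1, _ = one_way_anova([[1, 2, 3], [4, 6, 8]])
        f2, _ = one_way_anova([[101, 102, 103], [104, 106, 108]])
        assert f1 == pytest.approx(f2)

    def test_degenerate_all_equal(self):
        f, p = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert f == 0.0 and p == 1.0
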