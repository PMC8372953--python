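"""Change detection, transition estimation, Markov/CA projection, accuracy."""

import numpy as np
import pytest

from forestcarbon.lulc import (
    LandCoverMap,
    TransitionMatrix,
    accuracy_from_confusion,
    accuracy_metrics,
    ca_allocate,
    classify_change,
    estimate_transition,
    largest_remainder_round,
    markov_project,
    ndvi,
    read_grid,
    write_grid,
    CHANGE_CODES,
)

LEGEND2 = {0: "forest", 1: "nonforest"}


def lc(grid, legend=LEGEND2, cell_area=1.0):
    return LandCoverMap(grid=np.asarray(grid), legend=legend, cell_area_ha=cell_area)


class TestNdvi:
    def test_basic_values(self):
        assert ndvi(0.6, 0.2) == pytest.approx(0.5)
        assert ndvi(0.3, 0.3) == 0.0

    def test_both_zero_is_nodata(self):
        assert np.isnan(ndvi(0.0, 0.0))

    def test_bounded(self):
        rng = np.random.default_rng(0)
        nir, red = rng.random(100), rng.random(100)
        out = ndvi(nir, red)
        assert np.nanmax(np.abs(out)) <= 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ndvi(-0.1, 0.2)


class TestClassifyChange:
    def test_no_change(self):
        m = lc([[0, 1], [1, 0]])
        cm = classify_change(m, m, {0})
        assert cm.areas_ha["degraded"] == 0.0
        assert cm.areas_ha["restored"] == 0.0

    def test_single_cell_cleared(self):
        m1 = lc([[0]], cell_area=0.09)
        m2 = lc([[1]], cell_area=0.09)
        cm = classify_change(m1, m2, {0})
        assert cm.areas_ha["degraded"] == pytest.approx(0.09)

    def test_areas_match_brute_force_count(self, two_class_pair):
        m1, m2 = two_class_pair
        cm = classify_change(m1, m2, {0})
        g1, g2 = m1.grid, m2.grid
        assert cm.areas_ha["degraded"] == pytest.approx(
            np.sum((g1 == 0) & (g2 == 1)) * m1.cell_area_ha
        )
        assert cm.areas_ha["restored"] == pytest.approx(
            np.sum((g1 == 1) & (g2 == 0)) * m1.cell_area_ha
        )
        assert cm.areas_ha["retained"] == pytest.approx(
            np.sum((g1 == 0) & (g2 == 0)) * m1.cell_area_ha
        )
        total = sum(cm.areas_ha.values())
        assert total == pytest.approx(g1.size * m1.cell_area_ha)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_change(lc([[0]]), lc([[0, 1]]), {0})


class TestEstimateTransition:
    def test_identity_for_identical_maps(self):
        m = lc([[0, 1], [1, 0]])
        t = estimate_transition(m, m)
        np.testing.assert_allclose(t.probabilities, np.eye(2))

    def test_hand_cross_tab(self):
        m1 = lc([[0, 0], [1, 1]])
        m2 = lc([[0, 1], [1, 1]])
        t = estimate_transition(m1, m2)
        np.testing.assert_allclose(t.probabilities, [[0.5, 0.5], [0.0, 1.0]])

    def test_rows_sum_to_one(self, two_class_pair):
        t = estimate_transition(*two_class_pair)
        np.testing.assert_allclose(t.probabilities.sum(axis=1), 1.0)

    def test_absent_class_gets_identity_row(self):
        m1 = lc([[0, 0]], legend={0: "a", 1: "b"})
        m2 = lc([[0, 1]], legend={0: "a", 1: "b"})
        t = estimate_transition(m1, m2)
        np.testing.assert_allclose(t.probabilities[1], [0.0, 1.0])


class TestMarkovProject:
    def test_identity_unchanged(self):
        t = TransitionMatrix(classes=(0, 1), probabilities=np.eye(2))
        out = markov_project({0: 10.0, 1: 5.0}, t, 3)
        assert out == {0: 10.0, 1: 5.0}

    def test_hand_multiplication(self):
        t = TransitionMatrix(classes=(0, 1), probabilities=np.array([[0.5, 0.5], [0.0, 1.0]]))
        out = markov_project({0: 100.0, 1: 0.0}, t, 1)
        assert out[0] == pytest.approx(50.0)
        assert out[1] == pytest.approx(50.0)

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_total_area_conserved(self, k):
        rng = np.random.default_rng(4)
        p = rng.random((3, 3))
        p /= p.sum(axis=1, keepdims=True)
        t = TransitionMatrix(classes=(0, 1, 2), probabilities=p)
        areas = {0: 992.0, 1: 140.0, 2: 2793.0}
        out = markov_project(areas, t, k)
        assert sum(out.values()) == pytest.approx(3925.0, rel=1e-9)

    def test_stationary_distribution_is_fixed_point(self):
        rng = np.random.default_rng(8)
        p = rng.random((3, 3)) + 0.1
        p /= p.sum(axis=1, keepdims=True)
        # eigen-oracle: left eigenvector for eigenvalue 1
        w, v = np.linalg.eig(p.T)
        stat = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        stat = stat / stat.sum() * 1000.0
        t = TransitionMatrix(classes=(0, 1, 2), probabilities=p)
        out = markov_project(stat, t, 1)
        np.testing.assert_allclose([out[c] for c in (0, 1, 2)], stat, rtol=1e-9)


class TestCaAllocate:
    def test_identity_matrix_is_noop(self, two_class_pair):
        m1, _ = two_class_pair
        t = TransitionMatrix(classes=(0, 1), probabilities=np.eye(2))
        out = ca_allocate(m1, t, n_periods=1, filter_size=3)
        np.testing.assert_array_equal(out.grid, m1.grid)

    def test_counts_meet_largest_remainder_targets(self, two_class_pair):
        m1, m2 = two_class_pair
        t = estimate_transition(m1, m2)
        out = ca_allocate(m2, t, n_periods=1, filter_size=5)
        counts = np.array([np.sum(m2.grid == c) for c in (0, 1)], dtype=float)
        projected = np.array([markov_project(counts, t, 1)[c] for c in (0, 1)])
        targets = largest_remainder_round(projected, m2.grid.size)
        observed = np.array([np.sum(out.grid == c) for c in (0, 1)])
        np.testing.assert_array_equal(observed, targets)
        assert out.grid.size == m2.grid.size

    def test_deterministic(self, two_class_pair):
        m1, m2 = two_class_pair
        t = estimate_transition(m1, m2)
        a = ca_allocate(m2, t, n_periods=1, seed=1)
        b = ca_allocate(m2, t, n_periods=1, seed=99)
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_hand_allocation_on_3x3(self):
        # one B cell in the centre; B must grow to 3 cells with a 3x3 filter.
        # Corner neighbours of the B cell see 1 B in a 4-cell window (0.25),
        # edge neighbours 1 in 6 (0.167), so the two claimed cells are the
        # first two corners in row-major order: cells (0,0) and (0,2).
        grid = np.zeros((3, 3), dtype=int)
        grid[1, 1] = 1
        m = lc(grid, legend={0: "A", 1: "B"})
        p = np.array([[6 / 8, 2 / 8], [0.0, 1.0]])  # targets: A 6, B 3
        t = TransitionMatrix(classes=(0, 1), probabilities=p)
        out = ca_allocate(m, t, n_periods=1, filter_size=3)
        expected = grid.copy()
        expected[0, 0] = 1
        expected[0, 2] = 1
        np.testing.assert_array_equal(out.grid, expected)

    def test_even_filter_rejected(self, two_class_pair):
        m1, m2 = two_class_pair
        t = estimate_transition(m1, m2)
        with pytest.raises(ValueError):
            ca_allocate(m2, t, filter_size=4)


class TestAccuracy:
    def test_identical_maps_perfect(self, two_class_pair):
        m1, _ = two_class_pair
        oa, kappa, conf = accuracy_metrics(m1, m1)
        assert oa == 1.0 and kappa == 1.0
        assert np.trace(conf.to_numpy()) == m1.grid.size

    def test_hand_confusion(self):
        oa, kappa = accuracy_from_confusion([[40, 10], [5, 45]])
        assert oa == pytest.approx(0.85)
        assert kappa == pytest.approx(0.70)
        assert kappa < oa

    def test_single_class_degenerate(self):
        oa, kappa = accuracy_from_confusion([[9, 0], [0, 0]])
        assert oa == 1.0 and kappa == 1.0


class TestGridIO:
    def test_round_trip(self, tmp_path, two_class_pair):
        m1, _ = two_class_pair
        path = tmp_path / "grid.txt"
        write_grid(m1, path)
        back = read_grid(path, m1.legend, m1.cell_area_ha)
        np.testing.assert_array_equal(back.grid, m1.grid)

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            lc([[0, 7]])
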