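import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from markspat.capture_data import DEFAULT_GEOMETRY
from markspat.point_pattern import (
    PointPattern,
    border_distance,
    clark_evans_r,
    cross_nnd,
    donnelly_expected_nnd,
    default_r_grid,
    estimate_g,
    g_hat_km,
    g_theoretical,
    mad_statistic,
)

G = DEFAULT_GEOMETRY


def lattice_points():
    rows, cols = np.meshgrid(np.arange(6), np.arange(8), indexing="ij")
    return np.column_stack([(cols.ravel() + 0.5) * 1.5, (rows.ravel() + 0.5) * 1.5])


class TestCrossNnd:
    def test_three_four_five_triangle(self):
        nnd, _ = cross_nnd([(1.0, 1.0)], [(4.0, 5.0)], G)
        assert nnd[0] == pytest.approx(5.0)

    def test_border_distance_of_corner_cell_center(self):
        _, border = cross_nnd([(0.75, 0.75)], [(4.0, 5.0)], G)
        assert border[0] == pytest.approx(0.75)

    def test_self_distances_excluded_for_same_pattern(self):
        pts = [(1.0, 1.0), (2.0, 1.0), (5.0, 5.0)]
        nnd, _ = cross_nnd(pts, pts, G)
        assert nnd[0] == pytest.approx(1.0)  # not 0

    def test_kdtree_agrees_with_brute_force(self, rng):
        f = rng.uniform((0, 0), (12, 9), (100, 2))
        t = rng.uniform((0, 0), (12, 9), (100, 2))
        nnd, _ = cross_nnd(f, t, G)
        brute = np.sqrt(((f[:, None, :] - t[None, :, :]) ** 2).sum(-1)).min(axis=1)
        np.testing.assert_allclose(nnd, brute, rtol=1e-12)

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            cross_nnd([(1.0, 1.0)], np.empty((0, 2)), G)


class TestClarkEvansR:
    def test_lattice_r_follows_donnelly_formula(self):
        # 48 points on the regular cell-center lattice: every NND is exactly
        # 1.5 m; the Donnelly expectation at n=48, A=108, P=42 is 0.80015 m
        pts = lattice_points()
        res = clark_evans_r(pts, pts, G)
        assert res.mean_observed_nnd == pytest.approx(1.5)
        assert res.expected_nnd == pytest.approx(0.8001531, abs=1e-6)
        assert res.r_value == pytest.approx(1.5 / 0.8001531, rel=1e-6)

    def test_coincident_points_give_r_zero(self):
        f = np.array([(2.0, 2.0), (7.0, 5.0)])
        res = clark_evans_r(f, f.copy(), G, same_pattern=False)
        assert res.r_value == 0.0

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            clark_evans_r(np.empty((0, 2)), [(1.0, 1.0)], G)

    def test_relabeling_and_rigid_motion_invariance(self, rng):
        f = rng.uniform((0, 0), (6, 6), (15, 2))
        t = rng.uniform((0, 0), (6, 6), (20, 2))
        base = clark_evans_r(f, t, G, same_pattern=False).r_value
        perm = clark_evans_r(f[rng.permutation(15)], t[rng.permutation(20)], G, same_pattern=False)
        assert perm.r_value == pytest.approx(base)
        shifted = clark_evans_r(f + 2.0, t + 2.0, G, same_pattern=False)
        assert shifted.r_value == pytest.approx(base)

    def test_csr_calibration_mean_r_near_one(self, rng):
        # the purpose of the edge correction: random patterns score ~1
        vals = []
        for _ in range(400):
            f = rng.uniform((0, 0), (12, 9), (20, 2))
            t = rng.uniform((0, 0), (12, 9), (20, 2))
            vals.append(clark_evans_r(f, t, G, same_pattern=False).r_value)
        assert 0.95 <= np.mean(vals) <= 1.03


class TestGTheoretical:
    def test_closed_form_values(self):
        r = np.array([0.0, 1.0, 50.0])
        g = g_theoretical(r, 1.0 / np.pi)
        assert g[0] == 0.0
        assert g[1] == pytest.approx(1.0 - np.exp(-1.0))
        assert g[2] == pytest.approx(1.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            g_theoretical(np.array([-0.1]), 1.0)


class TestGHatKm:
    def test_no_censoring_reduces_to_ecdf(self, rng):
        nnd = rng.uniform(0.1, 2.0, 40)
        border = np.full(40, 10.0)
        grid = np.linspace(0, 3, 200)
        g = g_hat_km(nnd, border, grid)
        ecdf = (nnd[None, :] <= grid[:, None]).mean(axis=1)
        np.testing.assert_allclose(g, ecdf, atol=1e-12)

    def test_all_censored_gives_zero(self):
        g = g_hat_km(np.array([2.0, 3.0]), np.array([1.0, 1.5]), np.linspace(0, 5, 50))
        assert (g == 0).all()

    def test_agrees_with_independent_survival_fit(self, rng):
        lifelines = pytest.importorskip("lifelines")
        nnd = rng.exponential(1.0, 30)
        border = rng.uniform(0.2, 2.0, 30)
        d = np.minimum(nnd, border)
        event = nnd <= border
        grid = np.sort(np.unique(d))
        km = lifelines.KaplanMeierFitter().fit(d, event_observed=event)
        ref = 1.0 - km.survival_function_at_times(grid).to_numpy()
        ours = g_hat_km(nnd, border, grid)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(min_value=1, max_value=60), st.integers(min_value=0, max_value=2**31 - 1))
    def test_monotone_and_bounded_under_any_censoring(self, n, seed):
        r = np.random.default_rng(seed)
        nnd = r.exponential(1.0, n)
        border = r.uniform(0.01, 3.0, n)
        g = g_hat_km(nnd, border, np.linspace(0, 4, 101))
        assert (np.diff(g) >= -1e-12).all()
        assert g[0] == 0.0 or nnd.min() == 0.0
        assert (g >= 0).all() and (g <= 1).all()


class TestMad:
    def test_identical_curves_give_zero(self):
        r = np.linspace(0, 2, 50)
        g = g_theoretical(r, 0.2)
        assert mad_statistic(g, g, r).u_statistic == 0.0

    def test_constant_offset_recovered_with_direction(self):
        r = np.linspace(0, 2, 50)
        g = g_theoretical(r, 0.2)
        res = mad_statistic(np.clip(g + 0.2, 0, 1.2), g, r)
        assert res.u_statistic == pytest.approx(0.2)
        assert res.direction == 1

    def test_grid_refinement_changes_u_only_by_resolution(self, rng):
        f = rng.uniform((0, 0), (12, 9), (25, 2))
        t = rng.uniform((0, 0), (12, 9), (25, 2))
        coarse = default_r_grid(G, 512)
        fine = np.linspace(0, coarse[-1], 8192)
        u_c = mad_statistic(*_curves(f, t, coarse), coarse).u_statistic
        u_f = mad_statistic(*_curves(f, t, fine), fine).u_statistic
        # Ĝ jumps by at most 1/n between grid nodes; the reference curve is
        # smooth, so refining the grid moves u by less than one jump
        assert abs(u_f - u_c) <= 1.0 / 25 + 1e-9

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mad_statistic(np.zeros(5), np.zeros(5), np.zeros(4))


def _curves(f, t, grid):
    est = estimate_g(f, t, G, grid, same_pattern=False)
    return est.g_hat, est.g_theo


class TestPointPattern:
    def test_points_outside_window_rejected(self):
        with pytest.raises(ValueError):
            PointPattern(np.array([(13.0, 1.0)]), np.array(["J"]), G)

    def test_label_subset(self):
        pat = PointPattern(
            np.array([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]), np.array(["J", "RF", "J"]), G
        )
        assert len(pat.subset("J")) == 2
        assert len(pat.subset({"J", "RF"})) == 3
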