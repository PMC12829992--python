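"""Localisation clustering: percent-clustered, scans, Welch test, generator."""

import numpy as np
import pytest

from dopasim import (
    LocalisationTable,
    ParameterError,
    parameter_scan,
    percent_clustered,
    read_localisations,
    region_compare,
    synth_localisations,
)


def brute_force_percent_clustered(points, radius, min_points):
    """O(n²) reference: a point is clustered iff it is a core point (>=
    min_points neighbours within radius, itself included) or lies within
    radius of one — independent of visiting order."""
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    within = d2 <= radius**2
    core = within.sum(1) >= min_points
    clustered = core | within[:, core].any(1)
    return 100.0 * clustered.mean()


class TestPercentClustered:
    def test_coincident_points_fully_clustered(self):
        tab = LocalisationTable(np.zeros((50, 2)))
        assert percent_clustered(tab, 10.0, 40) == 100.0

    def test_sparse_grid_all_noise(self):
        g = np.arange(10) * 500.0
        pts = np.array([(x, y) for x in g for y in g])
        assert percent_clustered(LocalisationTable(pts), 100.0, 3) == 0.0

    def test_matches_brute_force_reference(self):
        tab = synth_localisations(3, 15.0, 100, background_per_um2=25.0,
                                  field_size_um=2.0, seed=7)
        got = percent_clustered(tab, 40.0, 40)
        ref = brute_force_percent_clustered(tab.points, 40.0, 40)
        assert got == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_across_parameters(self, seed):
        tab = synth_localisations(4, 25.0, 60, background_per_um2=40.0, seed=seed)
        for radius, mp in ((20.0, 10), (80.0, 40), (150.0, 100)):
            got = percent_clustered(tab, radius, mp)
            ref = brute_force_percent_clustered(tab.points, radius, mp)
            assert got == pytest.approx(ref, abs=1e-9), (radius, mp)

    def test_rigid_motion_invariance(self):
        tab = synth_localisations(3, 15.0, 80, seed=2)
        base = percent_clustered(tab, 50.0, 30)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = LocalisationTable(tab.points @ R.T + np.array([1e4, -2e3]))
        assert percent_clustered(moved, 50.0, 30) == pytest.approx(base, abs=1e-9)

    def test_monotone_in_radius(self):
        tab = synth_localisations(3, 20.0, 80, background_per_um2=30.0, seed=4)
        vals = [percent_clustered(tab, r, 20) for r in (20, 40, 80, 160)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_parameter_validation(self):
        tab = LocalisationTable(np.zeros((5, 2)))
        with pytest.raises(ParameterError):
            percent_clustered(tab, 0.0, 10)
        with pytest.raises(ParameterError):
            percent_clustered(tab, 10.0, 1)


class TestGenerator:
    def test_background_only_scores_near_zero(self):
        tab = synth_localisations(0, 15.0, 0, background_per_um2=50.0, seed=0)
        # CSR at 50/µm²: expected neighbours in r=40 nm is ~0.25, far below 10
        assert percent_clustered(tab, 40.0, 10) < 2.0

    def test_tight_clusters_only_score_near_hundred(self):
        tab = synth_localisations(3, 5.0, 100, background_per_um2=0.0, seed=1)
        assert percent_clustered(tab, 40.0, 40) == pytest.approx(100.0)

    def test_reproducible(self):
        a = synth_localisations(seed=9)
        b = synth_localisations(seed=9)
        np.testing.assert_array_equal(a.points, b.points)

    def test_recovery_of_ground_truth_fraction(self):
        tab = synth_localisations(4, 10.0, 150, background_per_um2=5.0,
                                  field_size_um=3.0, seed=11)
        est = percent_clustered(tab, 60.0, 30)
        assert est == pytest.approx(tab.clustered_fraction_truth(), abs=5.0)


class TestRegionCompare:
    def test_identical_groups(self):
        t, p = region_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_computed_welch_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 10.0
        t, p = region_compare(a, b)
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert t == pytest.approx((a.mean() - b.mean()) / se, rel=1e-12)

    def test_swapping_groups_flips_sign_only(self):
        a, b = [1.0, 2.0, 4.0], [5.0, 6.5, 9.0]
        t1, p1 = region_compare(a, b)
        t2, p2 = region_compare(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_needs_two_values_per_group(self):
        with pytest.raises(ParameterError):
            region_compare([1.0], [1.0, 2.0])


class TestScan:
    def test_identical_regions_zero_difference(self):
        tabs = [synth_localisations(seed=s) for s in (0, 1)]
        res = parameter_scan({"A": tabs, "B": tabs}, [30, 60], [20, 40])
        np.testing.assert_allclose(res.difference, 0.0)

    def test_more_clustered_region_positive_difference(self):
        ds_like = [synth_localisations(3, 15.0, 60, background_per_um2=60.0,
                                       seed=s) for s in range(4)]
        vs_like = [synth_localisations(6, 15.0, 90, background_per_um2=20.0,
                                       seed=10 + s) for s in range(4)]
        res = parameter_scan({"DS": ds_like, "VS": vs_like},
                             [20, 50, 100, 200], [20, 40])
        assert np.all(res.difference > 0)

    def test_single_cell_scan_reduces_to_percent_difference(self):
        a = synth_localisations(seed=3)
        b = synth_localisations(5, 10.0, 120, seed=4)
        res = parameter_scan({"A": [a], "B": [b]}, [40.0], [40])
        direct = percent_clustered(b, 40.0, 40) - percent_clustered(a, 40.0, 40)
        assert res.difference[0, 0] == pytest.approx(direct)


def test_read_localisations_round_trip(tmp_path):
    tab = synth_localisations(2, 10.0, 30, background_per_um2=10.0, seed=5)
    p = tmp_path / "locs.txt"
    p.write_text("x,y\n" + "\n".join(f"{x:.3f},{y:.3f}" for x, y in tab.points))
    back = read_localisations(p)
    np.testing.assert_allclose(back.points, np.round(tab.points, 3))
    with pytest.raises(ParameterError):
        read_localisations(p, x_col="missing")
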