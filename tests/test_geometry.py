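"""Neighborhood segmentation, base radius and histogram extraction."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from vegsynth import (
    Element,
    GridIndex,
    NeighborhoodGeometry,
    VectorPattern,
    assign_to_grid,
    bin_index,
    compute_histograms,
    connectivity_radius,
    estimate_base_radius,
    representative_point,
)
from vegsynth.geometry import neighbor_pairs, sample_histogram_table

from conftest import random_pattern


class TestBaseRadius:
    def test_single_pair(self):
        p = VectorPattern(
            [Element(0, 0.0, 0.0), Element(1, 0.0, 1.0)], (-1, -1, 2, 2)
        )
        assert estimate_base_radius(p) == 1.0

    def test_lattice_minimum_spacing(self, lattice):
        assert estimate_base_radius(lattice) == pytest.approx(0.125)

    def test_matches_all_pairs_bruteforce(self):
        rng = np.random.default_rng(42)
        p = random_pattern(rng, n=50)
        xy = p.xy
        brute = min(
            float(np.hypot(*(xy[i] - xy[j])))
            for i in range(50)
            for j in range(i + 1, 50)
        )
        assert estimate_base_radius(p) == pytest.approx(brute, abs=0)

    def test_too_small_and_coincident(self):
        with pytest.raises(ValueError, match="too small"):
            estimate_base_radius(
                VectorPattern([Element(0, 0.5, 0.5)], (0, 0, 1, 1))
            )
        dup = VectorPattern(
            [Element(0, 0.5, 0.5), Element(1, 0.5, 0.5), Element(2, 0, 0)],
            (0, 0, 1, 1),
        )
        with pytest.raises(ValueError, match="[Cc]oincident"):
            estimate_base_radius(dup)


class TestGridAssignment:
    def test_on_axis_first_shell(self, geom):
        g = assign_to_grid((0, 0), (0.5 * geom.r0, 0), geom)
        assert (g.shell, g.sector) == (0, 0)

    def test_mid_shell_100_degrees(self, geom):
        # radius 1.5*r0 lies in [r0, 2r0); 100 degrees lies in [90, 135)
        r = 1.5 * geom.r0
        pt = (r * np.cos(np.radians(100)), r * np.sin(np.radians(100)))
        g = assign_to_grid((0, 0), pt, geom)
        assert (g.shell, g.sector) == (1, 2)

    def test_outside_outer_radius(self, geom):
        assert assign_to_grid((0, 0), (3.5 * geom.r0, 0), geom) is None
        # boundary itself is excluded (half-open shells)
        assert assign_to_grid((0, 0), (3.0 * geom.r0, 0), geom) is None

    def test_self_assignment_rejected(self, geom):
        with pytest.raises(ValueError, match="self"):
            assign_to_grid((0.3, 0.4), (0.3, 0.4), geom)

    @settings(derandomize=True, deadline=None)
    @given(
        radius=st.floats(0.01, 0.374),
        angle=st.floats(0.0, 2 * np.pi - 1e-9),
    )
    def test_rotation_by_sector_width_increments_sector(self, radius, angle):
        geom = NeighborhoodGeometry(r0=0.125)
        # stay off the sector boundaries, where float rounding of
        # cos/sin/arctan2 can legitimately flip the floor either way
        frac = (angle / geom.sector_width) % 1.0
        assume(1e-6 < frac < 1.0 - 1e-6)
        p1 = (radius * np.cos(angle), radius * np.sin(angle))
        a2 = angle + geom.sector_width
        p2 = (radius * np.cos(a2), radius * np.sin(a2))
        g1 = assign_to_grid((0, 0), p1, geom)
        g2 = assign_to_grid((0, 0), p2, geom)
        assert g1.shell == g2.shell
        assert g2.sector == (g1.sector + 1) % geom.n_sectors

    @settings(derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_partition_every_interior_point_maps_to_one_bin(self, k):
        geom = NeighborhoodGeometry(r0=1.0)
        rng = np.random.default_rng(k)
        r = rng.uniform(1e-6, geom.outer_radius * 0.999999)
        a = rng.uniform(0, 2 * np.pi)
        g = assign_to_grid((0, 0), (r * np.cos(a), r * np.sin(a)), geom)
        assert g is not None
        b = bin_index(g, geom)
        assert 0 <= b < geom.n_bins
        # bin decomposes back into the same (shell, sector)
        assert (b // geom.n_sectors, b % geom.n_sectors) == (g.shell, g.sector)


class TestBinIndex:
    @pytest.mark.parametrize(
        "shell,sector,expected", [(1, 1, 9), (0, 0, 0), (2, 7, 23)]
    )
    def test_flattening(self, geom, shell, sector, expected):
        assert bin_index(GridIndex(shell, sector), geom) == expected

    def test_out_of_range(self, geom):
        with pytest.raises(ValueError):
            bin_index(GridIndex(3, 0), geom)
        with pytest.raises(ValueError):
            bin_index(GridIndex(0, 8), geom)

    def test_default_segmentation_has_24_bins(self, geom):
        assert geom.n_bins == 24


class TestRepresentativePoint:
    def test_polar_midpoints(self):
        geom = NeighborhoodGeometry(r0=1.0)
        x, y = representative_point(GridIndex(0, 0), geom)
        assert (x, y) == pytest.approx(
            (0.5 * np.cos(np.radians(22.5)), 0.5 * np.sin(np.radians(22.5)))
        )
        x, y = representative_point(GridIndex(2, 4), geom)
        assert (x, y) == pytest.approx(
            (2.5 * np.cos(np.radians(202.5)), 2.5 * np.sin(np.radians(202.5)))
        )

    def test_roundtrip_through_assignment(self, geom):
        center = (3.7, -1.2)
        for shell in range(geom.n_shells):
            for sector in range(geom.n_sectors):
                pt = representative_point(GridIndex(shell, sector), geom, center)
                g = assign_to_grid(center, pt, geom)
                assert (g.shell, g.sector) == (shell, sector)


class TestHistograms:
    def test_isolated_element_all_zero(self, geom):
        p = VectorPattern(
            [Element(0, 0.5, 0.5), Element(1, 5.0, 5.0)], (0, 0, 6, 6)
        )
        hs = compute_histograms(p, p.element(0), geom)
        assert all(c.sum() == 0 for c in hs.counts.values())
        assert hs.mask.all()

    def test_single_neighbor_lands_in_bin_8(self, geom):
        r = 1.5 * geom.r0
        nbr = (0.5 + r * np.cos(np.radians(10)), 0.5 + r * np.sin(np.radians(10)))
        p = VectorPattern(
            [Element(0, 0.5, 0.5, type_id=3),
             Element(1, nbr[0], nbr[1], type_id=3)],
            (0, 0, 1, 1),
        )
        hs = compute_histograms(p, p.element(0), geom)
        expected = np.zeros(24)
        expected[8] = 1  # shell 1, sector 0
        np.testing.assert_array_equal(hs.counts[3], expected)

    @pytest.mark.parametrize("n_types", [1, 3])
    def test_bruteforce_double_loop_agreement(self, geom, n_types):
        rng = np.random.default_rng(7 + n_types)
        p = random_pattern(rng, n=80, n_types=n_types)
        for idx in range(0, 80, 9):
            e = p.element(idx)
            hs = compute_histograms(p, e, geom)
            brute = {t: np.zeros(24, dtype=int) for t in p.type_ids}
            for other in p:
                if other.id == e.id:
                    continue
                g = assign_to_grid((e.x, e.y), (other.x, other.y), geom)
                if g is not None:
                    brute[other.type_id][bin_index(g, geom)] += 1
            for t in p.type_ids:
                np.testing.assert_array_equal(hs.counts[t], brute[t])

    def test_totals_conserve_neighbor_counts(self, geom):
        rng = np.random.default_rng(11)
        p = random_pattern(rng, n=60, n_types=2)
        xy, types = p.xy, p.type_id_array
        for idx in (0, 17, 59):
            e = p.element(idx)
            hs = compute_histograms(p, e, geom)
            d = np.hypot(xy[:, 0] - e.x, xy[:, 1] - e.y)
            for t in p.type_ids:
                inside = (d > 0) & (d < geom.outer_radius) & (types == t)
                assert hs.counts[t].sum() == inside.sum()

    def test_table_matches_per_element_histograms(self, geom):
        rng = np.random.default_rng(3)
        p = random_pattern(rng, n=50, n_types=2)
        table = sample_histogram_table(p, geom)
        for i in range(p.n):
            hs = compute_histograms(p, p.element(i), geom)
            for k, t in enumerate(p.type_ids):
                np.testing.assert_array_equal(table[i, k], hs.counts[t])


class TestPeriodicNeighborhoods:
    def test_wrapped_pair_found_with_minimum_image_offset(self):
        p = VectorPattern(
            [Element(0, 0.05, 0.5), Element(1, 0.95, 0.5)], (0, 0, 1, 1)
        )
        pairs, offsets = neighbor_pairs(p, 0.2, periodic=True)
        assert len(pairs) == 1
        # across the seam the displacement is -0.1, not +0.9
        assert abs(abs(offsets[0, 0]) - 0.1) < 1e-12
        pairs_plain, _ = neighbor_pairs(p, 0.2, periodic=False)
        assert len(pairs_plain) == 0

    def test_periodic_lattice_histograms_are_uniform(self, lattice):
        geom = NeighborhoodGeometry(r0=0.125)
        table = sample_histogram_table(lattice, geom, periodic=True)
        # on the torus every lattice element sees the identical neighborhood
        assert np.all(table == table[0])
        # rings at s, s*sqrt2, 2s, s*sqrt5, 2s*sqrt2 inside 3s: 4+4+4+8+4
        assert table[0].sum() == 24

    def test_radius_too_large_for_torus(self, lattice):
        with pytest.raises(ValueError, match="half"):
            neighbor_pairs(lattice, 0.5, periodic=True)


def test_connectivity_radius_is_max_mst_edge_bruteforce():
    rng = np.random.default_rng(5)
    p = random_pattern(rng, n=25)
    # Prim's algorithm on the complete graph as the independent oracle
    xy = p.xy
    n = len(xy)
    dist = np.hypot(
        xy[:, 0][:, None] - xy[:, 0][None, :],
        xy[:, 1][:, None] - xy[:, 1][None, :],
    )
    in_tree = np.zeros(n, bool)
    in_tree[0] = True
    best = dist[0].copy()
    longest = 0.0
    for _ in range(n - 1):
        best[in_tree] = np.inf
        j = int(np.argmin(best))
        longest = max(longest, best[j])
        in_tree[j] = True
        best = np.minimum(best, dist[j])
    assert connectivity_radius(p) == pytest.approx(longest, rel=1e-12)
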