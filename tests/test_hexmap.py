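"""Hexagonal density maps: geometry, conservation, loci, colocalization."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from mcspatial.errors import GridMismatchError
from mcspatial.hexmap import (
    DEFAULT_HEX_AREA,
    assign_counts,
    build_grid,
    colocalization_classes,
    colocalization_summary,
    flag_loci,
    side_from_area,
)
from mcspatial.synthetic import SimulationConfig, simulate_sample

from conftest import toy_sample


def _shoelace(v):
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestGridGeometry:
    def test_side_length_closed_form(self):
        assert side_from_area(8660.0) == pytest.approx(
            math.sqrt(2 * 8660.0 / (3 * math.sqrt(3.0)))
        )
        assert side_from_area(8660.0) == pytest.approx(57.735, abs=5e-3)

    def test_side_scales_as_sqrt_of_area(self):
        assert side_from_area(4 * 8660.0) == pytest.approx(2 * side_from_area(8660.0))

    @pytest.mark.parametrize("orientation", ["pointy", "flat"])
    def test_every_hexagon_area_matches_nominal(self, orientation):
        region = box(0, 0, 1000, 1000)
        grid = build_grid(region, orientation=orientation)
        for q, r in grid.indices:
            area = _shoelace(grid.vertices(q, r))
            assert abs(area - DEFAULT_HEX_AREA) / DEFAULT_HEX_AREA < 1e-6

    def test_grid_covers_region(self):
        region = box(0, 0, 1000, 1000)
        grid = build_grid(region)
        # every random point inside the region maps to a retained hexagon
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1000, size=(500, 2))
        qr = grid.to_axial(pts)
        assert all(tuple(k) in grid for k in qr)

    def test_degenerate_region_rejected(self):
        with pytest.raises(ValueError):
            build_grid(box(0, 0, 0, 0))


class TestAssignCounts:
    def test_point_at_hexagon_center_maps_to_it(self):
        region = box(0, 0, 1000, 1000)
        grid = build_grid(region)
        q, r = grid.indices[len(grid) // 2]
        cx, cy = grid.centers(np.array([[q, r]]))[0]
        s = toy_sample([(cx, cy, "MC")], region=region)
        dmap = assign_counts(s, grid)
        assert dmap.counts.loc[(q, r), "MC"] == 1

    def test_counts_conserved_per_phenotype(self, rng):
        region = box(0, 0, 1000, 1000)
        grid = build_grid(region)
        pts = rng.uniform(0, 1000, size=(1000, 2))
        phenos = np.where(rng.random(1000) < 0.4, "MC", "CD8")
        s = toy_sample([(x, y, p) for (x, y), p in zip(pts, phenos)], region=region)
        dmap = assign_counts(s, grid)
        for p in ("MC", "CD8"):
            assert dmap.counts[p].sum() + dmap.overflow[p] == (phenos == p).sum()
            assert dmap.overflow[p] == 0

    def test_clustered_pattern_is_overdispersed(self):
        # Thomas-process MCs: per-hex count variance exceeds Poisson variance
        cfg = SimulationConfig(
            region_width=2000.0, region_height=2000.0, total_cell_density=2000.0,
            mc_fraction=0.25, cluster_mean_offspring=8.0, cluster_radius_sd=40.0,
            partner_fractions={}, coupling={},
        )
        s = simulate_sample(cfg, seed=5)
        grid = build_grid(s.region)
        counts = assign_counts(s, grid).counts["MC"].to_numpy(dtype=float)
        dispersion = counts.var() / counts.mean()
        assert dispersion > 1.5


class TestLoci:
    def test_single_loaded_hexagon_is_the_locus(self):
        region = box(0, 0, 1000, 1000)
        grid = build_grid(region)
        q, r = grid.indices[len(grid) // 3]
        cx, cy = grid.centers(np.array([[q, r]]))[0]
        s = toy_sample([(cx, cy, "MC")] * 12, region=region)
        flags = flag_loci(assign_counts(s, grid), "MC")
        assert flags.flags.sum() == 1
        assert flags.flags.loc[(q, r)]
        assert len(flags.loci) == 1
        assert flags.loci[0].area_um2 == pytest.approx(DEFAULT_HEX_AREA)

    def test_uniform_counts_flag_only_ties_of_max(self):
        region = box(0, 0, 500, 500)
        grid = build_grid(region)
        centers = grid.centers()
        inside = [i for i, c in enumerate(centers)
                  if 0 <= c[0] <= 500 and 0 <= c[1] <= 500]
        s = toy_sample([(centers[i][0], centers[i][1], "MC") for i in inside],
                       region=region)
        flags = flag_loci(assign_counts(s, grid), "MC")
        # every occupied hexagon holds exactly one cell: all are ties at the max
        assert flags.flags.sum() == len(inside)

    def test_empty_map_has_no_flags(self):
        region = box(0, 0, 500, 500)
        grid = build_grid(region)
        s = toy_sample([(10, 10, "CD8")], region=region)
        flags = flag_loci(assign_counts(s, grid, phenotypes=["MC", "CD8"]), "MC")
        assert not flags.flags.any()
        assert flags.loci == []

    def test_flagging_monotone_in_quantile(self, rng):
        region = box(0, 0, 1000, 1000)
        grid = build_grid(region)
        pts = rng.uniform(0, 1000, size=(400, 2))
        s = toy_sample([(x, y, "MC") for x, y in pts], region=region)
        dmap = assign_counts(s, grid)
        n_flagged = [flag_loci(dmap, "MC", quantile=q).flags.sum()
                     for q in (0.5, 0.7, 0.9, 0.97)]
        assert n_flagged == sorted(n_flagged, reverse=True)

    def test_synthetic_cluster_locus_contains_cluster_site(self):
        # all MCs concentrated near one known site -> a flagged locus covers it
        region = box(0, 0, 2000, 2000)
        grid = build_grid(region)
        rng = np.random.default_rng(3)
        site = np.array([700.0, 1100.0])
        pts = site + rng.normal(0, 30, size=(60, 2))
        s = toy_sample([(x, y, "MC") for x, y in pts], region=region)
        flags = flag_loci(assign_counts(s, grid), "MC")
        site_hex = tuple(grid.to_axial(site[None, :])[0])
        locus_hexes = {h for loc in flags.loci for h in loc.hexes}
        assert site_hex in locus_hexes


class TestColocalization:
    def _two_layer_map(self, pts_a, pts_b, size=1000):
        region = box(0, 0, size, size)
        grid = build_grid(region)
        s = toy_sample([(x, y, "MC") for x, y in pts_a]
                       + [(x, y, "CD163_M2") for x, y in pts_b], region=region)
        dmap = assign_counts(s, grid, phenotypes=["MC", "CD163_M2"])
        return dmap, flag_loci(dmap, "MC"), flag_loci(dmap, "CD163_M2")

    def test_disjoint_loci_have_no_both_class(self):
        dmap, fa, fb = self._two_layer_map([(100, 100)] * 10, [(800, 800)] * 10)
        classes = colocalization_classes(fa, fb)
        assert (classes["class"] == "both").sum() == 0
        assert (classes["class"] == "A_only").sum() >= 1
        assert (classes["class"] == "B_only").sum() >= 1

    def test_identical_loci_are_all_both(self):
        dmap, fa, fb = self._two_layer_map([(500, 500)] * 10, [(500, 500)] * 10)
        classes = colocalization_classes(fa, fb)
        flagged = classes["class"] != "neither"
        assert (classes.loc[flagged, "class"] == "both").all()
        summary = colocalization_summary(classes, dmap.grid.hex_area)
        assert summary.loc["both", "area_um2"] == pytest.approx(DEFAULT_HEX_AREA)

    def test_mismatched_grids_rejected(self):
        _, fa, _ = self._two_layer_map([(100, 100)], [(800, 800)])
        region2 = box(0, 0, 600, 600)
        grid2 = build_grid(region2)
        s2 = toy_sample([(50, 50, "CD163_M2")], region=region2)
        fb2 = flag_loci(assign_counts(s2, grid2, phenotypes=["CD163_M2"]), "CD163_M2")
        with pytest.raises(GridMismatchError):
            colocalization_classes(fa, fb2)

    def test_coupled_simulation_increases_shared_locus_area(self):
        # M2 placed on the MC cluster sites vs far away: "both" area larger
        rng = np.random.default_rng(9)
        sites = rng.uniform(200, 1800, size=(4, 2))
        mc = np.vstack([s + rng.normal(0, 25, size=(25, 2)) for s in sites])
        m2_coupled = np.vstack([s + rng.normal(0, 25, size=(25, 2)) for s in sites])
        m2_far = rng.uniform(0, 200, size=(100, 2))
        both_area = []
        for m2 in (m2_far, m2_coupled):
            dmap, fa, fb = self._two_layer_map(mc, m2, size=2000)
            classes = colocalization_classes(fa, fb)
            both_area.append((classes["class"] == "both").sum())
        assert both_area[1] > both_area[0]
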