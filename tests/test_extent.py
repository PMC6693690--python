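"""Thresholding, polygonization, inventory append, seaward boundaries,
override merging, and extent monotonicity."""

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon, box

from conftest import make_grid
from oracles import rasterized_area

from ebeem.core import ExtentPolygon, parse_nwi_code
from ebeem.extent import (
    DepthClip,
    MouthLine,
    append_nwi_tidal,
    apply_seaward_boundary,
    mask_to_polygons,
    merge_overrides,
    threshold_extent,
    threshold_mask,
    total_area,
)
from ebeem.surfaces import DatumSurface


def _const(shape, value, datum="NAVD88"):
    return make_grid(np.full(shape, float(value)), datum=datum)


class TestThreshold:
    def test_dem_everywhere_at_or_above_surface_gives_empty_extent(self):
        dem = _const((5, 5), 2.0)
        ex50 = _const((5, 5), 2.0)
        assert threshold_extent(dem, ex50) == []

    def test_equality_excluded_strict_inequality(self):
        vals = np.full((3, 3), 2.0)
        vals[1, 1] = 1.999999
        dem = make_grid(vals, datum="NAVD88")
        mask = threshold_mask(dem, _const((3, 3), 2.0))
        assert mask.sum() == 1 and mask[1, 1]

    def test_nodata_in_either_raster_excludes_cell(self):
        dem_vals = np.full((2, 2), 1.0)
        dem_vals[0, 0] = -9999.0
        dem = make_grid(dem_vals)
        ex_vals = np.full((2, 2), 2.0)
        ex_vals[1, 1] = -9999.0
        mask = threshold_mask(dem, make_grid(ex_vals))
        assert mask.tolist() == [[False, True], [True, False]]

    def test_datum_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="datum"):
            threshold_mask(_const((2, 2), 1.0, "NAVD88"), _const((2, 2), 2.0, "MLLW"))

    def test_ramp_dem_area_matches_cell_count_oracle(self):
        """A planar-ramp DEM against a constant 2.0 m surface: polygon area
        equals cell_size^2 times the number of below-surface cell centers."""
        n = 20
        ramp = np.linspace(0.0, 4.0, n)[None, :] * np.ones((n, 1))
        dem = make_grid(ramp)
        ex50 = _const((n, n), 2.0)
        extent = threshold_extent(dem, ex50)
        count = int((ramp < 2.0).sum())
        assert total_area(extent) == pytest.approx(
            dem.cell_size ** 2 * count, rel=1e-12)

    def test_four_connectivity_separates_diagonal_basins(self):
        vals = np.full((4, 4), 3.0)
        vals[0, 0] = vals[1, 1] = 0.0  # touch only at a corner
        mask = threshold_mask(make_grid(vals), _const((4, 4), 1.0))
        polys = mask_to_polygons(mask, make_grid(vals))
        assert len(polys) == 2


class TestAppendNwi:
    def _extent(self):
        return [ExtentPolygon(box(0, 0, 100, 100), "below_ex50")]

    def _rec(self, code, geom):
        return parse_nwi_code(code).with_geometry(geom)

    def test_estuarine_class_outside_contour_appended(self):
        out = append_nwi_tidal(self._extent(),
                               [self._rec("E2US2N", box(200, 0, 300, 100))])
        assert any(e.provenance == "nwi_appended" for e in out)

    def test_nontidal_palustrine_not_appended(self):
        out = append_nwi_tidal(self._extent(),
                               [self._rec("PEM1C", box(200, 0, 300, 100))])
        assert all(e.provenance != "nwi_appended" for e in out)

    def test_riverine_with_tidal_modifier_appended(self):
        out = append_nwi_tidal(self._extent(),
                               [self._rec("R1UB2V", box(200, 0, 300, 100))])
        assert any(e.provenance == "nwi_appended" for e in out)

    def test_only_part_outside_is_appended_and_area_never_removed(self):
        base = self._extent()
        out = append_nwi_tidal(base, [self._rec("E2EM1N", box(50, 0, 150, 100))])
        appended = [e for e in out if e.provenance == "nwi_appended"]
        assert len(appended) == 1
        assert appended[0].polygon.area == pytest.approx(50 * 100)
        assert total_area(out) >= total_area(base)

    def test_invalid_geometry_skipped_with_report(self):
        bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        errors = []
        with pytest.warns(UserWarning):
            out = append_nwi_tidal(self._extent(),
                                   [self._rec("E2EM1N", bowtie)], errors=errors)
        assert len(errors) == 1
        assert total_area(out) == pytest.approx(100 * 100)


class TestSeawardBoundary:
    def test_mouth_line_keeps_declared_landward_half(self):
        extent = [ExtentPolygon(box(0, 0, 100, 100), "below_ex50")]
        # west->east line through the middle; north (left of travel) landward
        line = MouthLine((0, 50), (100, 50), landward="left")
        out = apply_seaward_boundary(extent, line)
        assert total_area(out) == pytest.approx(100 * 50)
        assert out[0].polygon.centroid.y > 50

    def test_depth_clip_removes_only_beds_deeper_than_4m_below_mllw(self):
        bathy_vals = np.array([[-5.0, -3.0]])  # bed elevations vs MLLW=0
        bathy = make_grid(bathy_vals, datum="NAVD88")
        mllw = DatumSurface(make_grid(np.zeros((1, 2)), datum="NAVD88"),
                            np.ones((1, 2), dtype=bool))
        extent = [ExtentPolygon(box(0, 0, 20, 10), "below_ex50")]
        out = apply_seaward_boundary(extent, DepthClip(bathy, mllw, depth_m=4.0))
        # cell 0 (bed -5 < -4) removed; cell 1 (bed -3) kept
        assert total_area(out) == pytest.approx(10 * 10)
        assert out[0].polygon.centroid.x > 10

    def test_non_intersecting_line_leaves_extent_unchanged(self):
        extent = [ExtentPolygon(box(0, 0, 10, 10), "below_ex50")]
        far = MouthLine((0, 500), (10, 500), landward="left")
        with pytest.warns(UserWarning, match="unchanged"):
            out = apply_seaward_boundary(extent, far)
        assert total_area(out) == pytest.approx(100)

    def test_trimming_never_adds_area(self):
        extent = [ExtentPolygon(box(0, 0, 100, 100), "below_ex50")]
        for landward in ("left", "right"):
            out = apply_seaward_boundary(
                extent, MouthLine((20, 0), (80, 100), landward=landward))
            assert total_area(out) <= total_area(extent) + 1e-9


class TestMergeOverrides:
    def test_empty_override_set_is_identity(self):
        extent = [ExtentPolygon(box(0, 0, 10, 10), "below_ex50")]
        assert merge_overrides(extent, [], "regional_override") == extent

    def test_disjoint_override_appended_with_requested_provenance(self):
        extent = [ExtentPolygon(box(0, 0, 10, 10), "below_ex50")]
        out = merge_overrides(extent, [box(20, 0, 30, 10)], "lagoon_supplied")
        provs = sorted(e.provenance for e in out)
        assert provs == ["below_ex50", "lagoon_supplied"]
        assert total_area(out) == pytest.approx(200)

    def test_overlapping_override_union_matches_rasterization_oracle(self):
        extent = [ExtentPolygon(box(0, 0, 60, 40), "below_ex50")]
        override = box(30, 10, 90, 50)
        out = merge_overrides(extent, [override], "regional_override")
        union = shapely.union_all([e.polygon for e in out])
        oracle = rasterized_area(
            shapely.union_all([box(0, 0, 60, 40), override]), (0, 0, 90, 50))
        assert union.area == pytest.approx(oracle, rel=1e-9)
        # override provenance wins in the overlap
        overlap_pt = shapely.Point(45, 25)
        winner = [e for e in out if e.polygon.covers(overlap_pt)]
        assert {e.provenance for e in winner} == {"regional_override"}

    def test_never_removes_area(self):
        extent = [ExtentPolygon(box(0, 0, 10, 10), "below_ex50")]
        out = merge_overrides(extent, [box(5, 5, 15, 15)], "regional_override")
        assert total_area(out) >= 100 - 1e-9


def test_monotone_under_uniform_ex50_increase(rng):
    """Raising the exceedance surface everywhere can only grow the extent."""
    for _ in range(5):
        dem = make_grid(rng.uniform(0, 3, (16, 16)))
        ex50 = make_grid(rng.uniform(0.5, 2.5, (16, 16)))
        base = threshold_mask(dem, ex50)
        raised = threshold_mask(dem, ex50.copy_with(ex50.values + 0.3))
        assert (base <= raised).all()
        assert raised.sum() >= base.sum()
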