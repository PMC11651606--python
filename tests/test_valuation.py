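"""Flame-length screening and protected-value (AFB/AWB) computation."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

from fbnopt import (
    BreakSegment,
    FireEvent,
    RasterGrid,
    awb_value,
    constituent_breaks,
    max_flame_on_boundary,
    screen,
    split_footprint,
)
from fbnopt.scenarios import analyze_fires, apply_screen
from fbnopt.valuation import build_record

from conftest import make_record


def _split_square(x_break: float = 0.5, square=(0, 0, 1, 1), ignition=(0.25, 0.5)):
    f = FireEvent(id="f", footprint=box(*square), ignition=Point(*ignition),
                  size=box(*square).area)
    net = [BreakSegment(id="b1", geom=LineString([(x_break, square[1] - 1),
                                                  (x_break, square[3] + 1)]))]
    split = split_footprint(f, net)
    return f, split, constituent_breaks(split)


def _segment_cell_oracle(grid: RasterGrid, p0, p1) -> float:
    """Independent oracle: enumerate every cell whose rectangle intersects
    the segment (via shapely box/segment predicates cell by cell) and return
    the maximum value."""
    seg = LineString([p0, p1])
    best = -math.inf
    for r in range(grid.nrows):
        for c in range(grid.ncols):
            if box(*grid.cell_bounds(r, c)).intersects(seg):
                best = max(best, grid.values[r, c])
    return best


class TestMaxFlame:
    def test_single_cell(self):
        _, split, s = _split_square()
        flame = RasterGrid(x0=-1, y0=-1, cell_size=3.0, values=np.array([[3.0]]))
        assert max_flame_on_boundary(split, s, flame) == 3.0

    def test_vertical_arc_restricted_to_left_column(self):
        # 2x2 grid [[1,5],[2,3]] over [0,1]^2; the arc at x=0.25 lies strictly
        # in the left column, so the max is 2, not 5
        _, split, s = _split_square(x_break=0.25, ignition=(0.1, 0.5))
        flame = RasterGrid(x0=0, y0=0, cell_size=0.5,
                           values=np.array([[1.0, 5.0], [2.0, 3.0]]))
        assert max_flame_on_boundary(split, s, flame) == 2.0

    def test_arc_on_shared_cell_edge_counts_both_cells(self):
        # arc exactly on the edge between cells valued 4 and 7
        _, split, s = _split_square(x_break=0.5)
        flame = RasterGrid(x0=0, y0=0, cell_size=0.5,
                           values=np.array([[4.0, 7.0], [4.0, 7.0]]))
        got = max_flame_on_boundary(split, s, flame)
        assert got == 7.0
        assert got == _segment_cell_oracle(flame, (0.5, 0), (0.5, 1))

    def test_matches_rectangle_segment_oracle_on_offset_arcs(self):
        rng = np.random.default_rng(3)
        flame = RasterGrid(x0=0, y0=0, cell_size=0.25,
                           values=rng.uniform(1, 9, size=(4, 4)).round(2))
        for xb in (0.3, 0.45, 0.62, 0.75):
            _, split, s = _split_square(x_break=xb, ignition=(0.05, 0.5))
            got = max_flame_on_boundary(split, s, flame)
            assert got == _segment_cell_oracle(flame, (xb, 0), (xb, 1))

    def test_nodata_only_boundary_flags_fire(self):
        _, split, s = _split_square()
        flame = RasterGrid(x0=-1, y0=-1, cell_size=3.0,
                           values=np.array([[-9999.0]]), nodata=-9999.0)
        assert max_flame_on_boundary(split, s, flame) is None

    def test_off_grid_boundary_flags_fire(self):
        _, split, s = _split_square()
        flame = RasterGrid(x0=100, y0=100, cell_size=1.0, values=np.ones((2, 2)))
        assert max_flame_on_boundary(split, s, flame) is None

    def test_boundary_mode_sees_perimeter_cells(self):
        # ignition face is the right strip [0.25,1] x [0,1]; the high value
        # sits under its right perimeter edge, far from the x=0.25 break arc,
        # so only mode='boundary' picks it up
        _, split, s = _split_square(x_break=0.25, ignition=(0.6, 0.5))
        vals = np.full((4, 4), 1.0)
        vals[:, 3] = 9.0  # right edge of the square, away from the x=0.25 arc
        flame = RasterGrid(x0=0, y0=0, cell_size=0.25, values=vals)
        assert max_flame_on_boundary(split, s, flame, mode="arcs") == 1.0
        assert max_flame_on_boundary(split, s, flame, mode="boundary") == 9.0


class TestScreen:
    @pytest.mark.parametrize(
        "max_flame,fl,expected",
        [
            (3.5, 4.0, True),          # below the threshold
            (4.0, 4.0, True),          # non-strict pass at equality
            (8.2, 8.0, False),         # strictly exceeding is unstoppable
            (1e9, math.inf, True),     # optimistic INF scenario
        ],
    )
    def test_threshold_rule(self, max_flame, fl, expected):
        rec = make_record("f", {"b1"}, 1.0, max_flame=max_flame)
        assert screen(rec, fl) is expected

    def test_empty_set_never_containable(self):
        rec = make_record("f", set(), 0.0)
        assert screen(rec, math.inf) is False

    def test_negative_threshold_rejected(self):
        rec = make_record("f", {"b1"}, 1.0)
        with pytest.raises(ValueError, match="threshold"):
            screen(rec, -1.0)

    def test_fl_monotonicity_on_synthetic_batch(self, small_landscape):
        base = analyze_fires(small_landscape.fires, small_landscape.network,
                             small_landscape.flame, small_landscape.wui)
        sets = {}
        for fl in (4.0, 8.0, math.inf):
            recs = apply_screen(base, fl)
            sets[fl] = {r.fire_id for r in recs if r.containable}
        assert sets[4.0] <= sets[8.0] <= sets[math.inf]
        assert sets[math.inf]  # non-trivial batch

    def test_inf_threshold_ignores_flame_values(self, small_landscape):
        land = small_landscape
        base = analyze_fires(land.fires, land.network, land.flame, land.wui)
        perturbed_flame = RasterGrid(
            x0=land.flame.x0, y0=land.flame.y0, cell_size=land.flame.cell_size,
            values=land.flame.values * 100 + 5,
        )
        base2 = analyze_fires(land.fires, land.network, perturbed_flame, land.wui)
        ids1 = {r.fire_id for r in apply_screen(base, math.inf) if r.containable}
        ids2 = {r.fire_id for r in apply_screen(base2, math.inf) if r.containable}
        assert ids1 == ids2


class TestAwb:
    WUI = RasterGrid(x0=0, y0=0, cell_size=0.5,
                     values=np.array([[0.0, 4.0], [1.0, 2.0]]))
    # centers: (0.25,0.75)=1? careful: row 0 top -> values[0]=[0,4] at y=0.75

    def test_right_column_centers(self):
        # AFB = right half of the unit square: centers (0.75, 0.25) and
        # (0.75, 0.75) with values 2 and 4
        f, split, _ = _split_square(ignition=(0.25, 0.5))
        assert awb_value(f, split, self.WUI) == pytest.approx(6.0)

    def test_not_fully_split_gives_zero(self):
        f = FireEvent(id="f", footprint=box(0, 0, 1, 1), ignition=Point(0.5, 0.5),
                      size=1.0)
        split = split_footprint(f, [])
        assert awb_value(f, split, self.WUI) == 0.0

    def test_total_when_afb_covers_all_centers(self):
        # sliver ignition face: AFB covers all four cell centers
        f, split, _ = _split_square(x_break=0.05, ignition=(0.02, 0.5))
        assert awb_value(f, split, self.WUI) == pytest.approx(7.0)

    def test_additive_over_parts_and_bounded(self, small_landscape):
        land = small_landscape
        base = analyze_fires(land.fires, land.network, land.flame, land.wui)
        total = land.wui.total()
        for rec in base:
            assert 0.0 <= rec.awb <= total + 1e-9
            assert rec.afb >= 0.0


def test_build_record_without_flame_always_passes():
    f, split, s = _split_square()
    rec = build_record(f, split, s, flame=None, wui=None, fl_threshold=4.0)
    assert rec.containable
    assert rec.max_flame == 0.0
    assert rec.afb == pytest.approx(0.5)
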