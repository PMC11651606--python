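"""Containment feasibility screening and per-fire valuation.

Whether suppression along a treated break can actually hold a fire is
screened with the fire's flame-length raster: the *maximum* flame length in
any cell touched by the break arcs bounding the ignition polygon is compared
to an escape flame length threshold (FL).  A fire whose maximum flame length
strictly exceeds FL is assumed to escape regardless of treatment, and its
constituent set is emptied (``S_j = empty``).

Two values are computed per fire for use as the protected value ``V_j``:

* AFB — avoided fire area burned (from :mod:`fbnopt.geometry`);
* AWB — avoided WUI burned: the sum of WUI raster values whose cell centers
  fall in the protected (AFB) region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import shapely
from shapely.geometry import box

from .geometry import EMPTY_SET, ConstituentSet, FireEvent, SplitResult
from .raster import RasterGrid

__all__ = [
    "ContainmentRecord",
    "max_flame_on_boundary",
    "screen",
    "awb_value",
]


@dataclass(frozen=True)
class ContainmentRecord:
    """Per-fire model inputs after preprocessing.

    ``s`` is the post-screening constituent set: empty means the fire can
    never be contained (disjoint from the network, not fully split, flame
    screened out, or flame unknown).  ``s_raw`` preserves the geometric set
    before flame screening so a different FL threshold can be re-applied
    without redoing geometry.  ``afb``/``awb`` are the two ``V_j``
    candidates; ``size`` is the simulated final fire size used by the
    large-fire exclusion rule.
    """

    fire_id: str
    s: ConstituentSet
    s_raw: ConstituentSet
    max_flame: float | None
    afb: float
    awb: float
    size: float

    @property
    def containable(self) -> bool:
        return bool(self.s)

    def value(self, objective: str) -> float:
        if objective == "afb":
            return self.afb
        if objective == "awb":
            return self.awb
        raise ValueError(f"unknown objective {objective!r} (expected 'afb' or 'awb')")

    def rescreen(self, fl_threshold: float) -> "ContainmentRecord":
        """Re-apply flame screening at a different FL threshold."""
        ok = _passes(self.s_raw, self.max_flame, fl_threshold)
        return replace(self, s=self.s_raw if ok else EMPTY_SET)


def max_flame_on_boundary(
    split: SplitResult,
    s: ConstituentSet,
    flame: RasterGrid,
    mode: str = "arcs",
) -> float | None:
    """Maximum flame length along the ignition polygon's control lines.

    Every raster cell whose square geometrically intersects the relevant
    linework counts — the conservative rule, capturing the worst flame
    adjacent to the control line.  ``mode='arcs'`` (default) restricts to
    the fuel-break arcs bounding the ignition face; ``mode='boundary'`` uses
    the whole ignition-polygon boundary including footprint-perimeter arcs.

    Returns ``None`` when the linework touches no valid cell (only nodata or
    off-grid); callers must treat that fire as not containable.
    """
    if not split.fully_split or split.ignition_face is None or not s:
        raise ValueError("max_flame_on_boundary requires a fully split fire with S_j != empty")
    if mode == "arcs":
        geoms = [split.arc_geoms[bid] for bid in s.break_ids if bid in split.arc_geoms]
        if not geoms:
            return None
        lines = shapely.union_all(geoms)
    elif mode == "boundary":
        lines = split.ignition_face.boundary
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'arcs' or 'boundary')")

    r0, r1, c0, c1 = flame.window(*lines.bounds)
    if r0 >= r1 or c0 >= c1:
        return None
    shapely.prepare(lines)
    best: float | None = None
    valid = flame.mask_valid()
    for row in range(r0, r1):
        for col in range(c0, c1):
            if not valid[row, col]:
                continue
            if lines.intersects(box(*flame.cell_bounds(row, col))):
                v = float(flame.values[row, col])
                if best is None or v > best:
                    best = v
    return best


def _passes(s: ConstituentSet, max_flame: float | None, fl_threshold: float) -> bool:
    if fl_threshold < 0:
        raise ValueError("FL threshold must be nonnegative")
    if not s:
        return False
    if max_flame is None:
        return False  # flame unknown along the arcs: not containable
    return max_flame <= fl_threshold


def screen(record: ContainmentRecord, fl_threshold: float) -> bool:
    """Containment feasibility under an escape flame length threshold.

    True iff ``S_j`` is non-empty and the maximum flame length along the
    bounding arcs does not exceed FL (non-strict pass, strict fail).
    ``fl_threshold = math.inf`` is the optimistic scenario where suppression
    succeeds at any intensity.
    """
    return _passes(record.s_raw if record.s_raw else record.s, record.max_flame,
                   fl_threshold)


def awb_value(fire: FireEvent, split: SplitResult, wui: RasterGrid) -> float:
    """Avoided WUI burned: WUI value protected when containment succeeds.

    Sums WUI cells whose centers fall inside the AFB region (footprint minus
    ignition polygon).  Zero when the fire is not fully split.
    """
    if not split.fully_split or split.ignition_face is None:
        return 0.0
    region = shapely.difference(
        shapely.union_all([shapely.make_valid(f) for f in split.faces]),
        split.ignition_face,
    )
    if region.is_empty:
        return 0.0
    r0, r1, c0, c1 = wui.window(*region.bounds)
    if r0 >= r1 or c0 >= c1:
        return 0.0
    cx, cy = wui.cell_centers()
    cx = cx[r0:r1, c0:c1]
    cy = cy[r0:r1, c0:c1]
    inside = shapely.contains_xy(region, cx.ravel(), cy.ravel()).reshape(cx.shape)
    vals = wui.values[r0:r1, c0:c1]
    valid = wui.mask_valid()[r0:r1, c0:c1]
    return float(vals[inside & valid].sum())


def build_record(
    fire: FireEvent,
    split: SplitResult,
    s_raw: ConstituentSet,
    flame: RasterGrid | None,
    wui: RasterGrid | None,
    fl_threshold: float = math.inf,
    flame_mode: str = "arcs",
) -> ContainmentRecord:
    """Assemble the full per-fire record (geometry + screening + values)."""
    from .geometry import avoided_area  # local import avoids cycle at module load

    afb = avoided_area(fire, split)
    awb = awb_value(fire, split, wui) if wui is not None else 0.0
    max_flame: float | None = None
    if s_raw and flame is not None:
        max_flame = max_flame_on_boundary(split, s_raw, flame, mode=flame_mode)
    elif s_raw and flame is None:
        max_flame = 0.0  # no flame screening requested: always passes
    ok = _passes(s_raw, max_flame, fl_threshold)
    return ContainmentRecord(
        fire_id=fire.id,
        s=s_raw if ok else EMPTY_SET,
        s_raw=s_raw,
        max_flame=max_flame,
        afb=afb,
        awb=awb,
        size=fire.size,
    )
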