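"""Ignition-polygon geometry.

A wildfire footprint crossed by fuel breaks can be carved into faces by
noding the footprint boundary with the break polylines and polygonizing the
result.  The face containing the fire's ignition point is the *ignition
polygon*: if every fuel break bounding that face is treated (and suppression
along them succeeds), the fire is assumed to be held inside it, and the rest
of the footprint is protected.

This module derives, per fire:

* the planar subdivision of the footprint induced by the break network,
* the ignition face and whether the footprint is *fully split* at all,
* the set of breaks whose arcs bound the ignition face (``S_j``) and its
  cardinality (``M_j``),
* the avoided fire area burned (AFB): footprint area minus ignition-face
  area when containment is geometrically possible, else zero.

All geometries must live in one planar projected CRS (meters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import shapely
from shapely.geometry import (
    GeometryCollection,
    LineString,
    MultiLineString,
    MultiPolygon,
    Point,
    Polygon,
)
from shapely.geometry.base import BaseGeometry
from shapely.ops import polygonize, unary_union

__all__ = [
    "BreakSegment",
    "FireEvent",
    "SplitResult",
    "ConstituentSet",
    "split_footprint",
    "constituent_breaks",
    "avoided_area",
]

#: Relative snap tolerance: multiplied by the footprint bounding-box diagonal.
SNAP_REL_TOL = 1e-9

#: Relative minimum arc length for a break to count as bounding the ignition
#: face (filters point-touches).
MIN_ARC_REL_LENGTH = 1e-6


@dataclass(frozen=True)
class BreakSegment:
    """One treatable fuel break: a polyline with a length and a cost.

    ``cost`` defaults to the geometric length — the simplifying assumption
    that treating a break costs its length, which makes a length-based
    budget and a cost-based budget coincide.
    """

    id: str
    geom: BaseGeometry
    cost: float | None = None

    def __post_init__(self) -> None:
        if self.geom.is_empty or self.geom.length <= 0:
            raise ValueError(f"break {self.id!r}: geometry must have positive length")
        if self.cost is not None and self.cost < 0:
            raise ValueError(f"break {self.id!r}: cost must be nonnegative")

    @property
    def length_m(self) -> float:
        return float(self.geom.length)

    @property
    def effective_cost(self) -> float:
        return float(self.cost) if self.cost is not None else self.length_m


@dataclass(frozen=True)
class FireEvent:
    """One simulated fire: footprint polygon, ignition point, final size."""

    id: str
    footprint: BaseGeometry
    ignition: Point
    size: float

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"fire {self.id!r}: size must be positive")
        if self.footprint.is_empty or self.footprint.area <= 0:
            raise ValueError(f"fire {self.id!r}: footprint must have positive area")


@dataclass
class SplitResult:
    """Planar subdivision of one footprint by the break network.

    ``break_arcs`` maps break id -> total boundary length that break shares
    with the ignition face; ``arc_geoms`` keeps the shared linework itself
    for downstream flame-length screening.
    """

    faces: list[Polygon]
    ignition_face: Polygon | None
    fully_split: bool
    break_arcs: dict[str, float]
    arc_geoms: dict[str, BaseGeometry] = field(default_factory=dict, repr=False)
    footprint_area: float = 0.0


@dataclass(frozen=True)
class ConstituentSet:
    """The set ``S_j`` of breaks bounding fire *j*'s ignition polygon."""

    break_ids: frozenset[str]

    @property
    def m(self) -> int:
        """``M_j``: number of breaks defining the ignition polygon."""
        return len(self.break_ids)

    def __bool__(self) -> bool:
        return bool(self.break_ids)


EMPTY_SET = ConstituentSet(frozenset())


def _repair(poly: BaseGeometry) -> BaseGeometry:
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    if isinstance(poly, GeometryCollection):
        parts = [g for g in poly.geoms if isinstance(g, (Polygon, MultiPolygon))]
        poly = unary_union(parts) if parts else Polygon()
    return poly

def _parts(poly: BaseGeometry) -> list[Polygon]:
    if isinstance(poly, Polygon):
        return [poly]
    if isinstance(poly, MultiPolygon):
        return list(poly.geoms)
    raise ValueError(f"footprint must be polygonal, got {poly.geom_type}")

def _line_parts(geom: BaseGeometry) -> list[LineString]:
    if geom.is_empty:
        return []
    if isinstance(geom, LineString):
        return [geom]
    if isinstance(geom, (MultiLineString, GeometryCollection)):
        out: list[LineString] = []
        for g in geom.geoms:
            out.extend(_line_parts(g))
        return out
    return []  # points from tangential touches carry no length

def _face_sort_key(face: Polygon) -> tuple:
    b = face.bounds
    return (face.area, b[0], b[1], b[2], b[3])


def split_footprint(
    fire: FireEvent,
    network: list[BreakSegment],
    snap_tol: float | None = None,
) -> SplitResult:
    """Split a fire footprint by the fuel-break network.

    The footprint boundary (exterior and hole rings) is noded together with
    every break polyline clipped to the footprint; polygonizing the noded
    linework yields the faces of the subdivision.  The unique face covering
    the ignition point is the ignition face.  When the ignition point falls
    exactly on a noded arc (within the snap tolerance), the smaller adjacent
    face is chosen — the conservative reading of "smallest polygon enclosing
    the ignition point".

    For multi-part footprints the part containing the ignition point is
    subdivided; the other parts are carried as whole faces so that face
    areas always sum to the footprint area.

    Parameters
    ----------
    fire : FireEvent
    network : list of BreakSegment
    snap_tol : float, optional
        Absolute snap tolerance; default ``1e-9`` x the footprint
        bounding-box diagonal.

    Returns
    -------
    SplitResult

    Raises
    ------
    ValueError
        If the footprint is empty/degenerate or the ignition point lies
        outside the footprint beyond the snap tolerance.
    """
    footprint = _repair(fire.footprint)
    if footprint.is_empty or footprint.area <= 0:
        raise ValueError(f"fire {fire.id!r}: footprint empty or degenerate after repair")

    xmin, ymin, xmax, ymax = footprint.bounds
    diag = math.hypot(xmax - xmin, ymax - ymin)
    if snap_tol is None:
        snap_tol = SNAP_REL_TOL * diag

    if footprint.distance(fire.ignition) > snap_tol:
        raise ValueError(
            f"fire {fire.id!r}: ignition point lies outside the footprint "
            f"(distance {footprint.distance(fire.ignition):.3g} > tol {snap_tol:.3g})"
        )

    parts = _parts(footprint)
    # the part holding the ignition point is the one that gets subdivided
    ign_part = None
    for p in sorted(parts, key=_face_sort_key):
        if p.distance(fire.ignition) <= snap_tol:
            ign_part = p
            break
    if ign_part is None:  # pragma: no cover - guarded by the distance check above
        raise ValueError(f"fire {fire.id!r}: no footprint part contains the ignition")
    other_parts = [p for p in parts if p is not ign_part]

    # clip breaks to the ignition part; keep per-break linework for identity.
    # every piece is snapped to one precision grid so that face boundaries
    # and break arcs share exact coordinates after noding.
    def _snap(geom: BaseGeometry) -> BaseGeometry:
        return shapely.set_precision(geom, snap_tol) if snap_tol > 0 else geom

    ign_part_snapped = _snap(ign_part)
    clipped: dict[str, BaseGeometry] = {}
    for seg in network:
        if not seg.geom.intersects(ign_part):
            continue
        inter = _snap(seg.geom.intersection(ign_part))
        lines = _line_parts(inter)
        if lines:
            clipped[seg.id] = unary_union(lines)

    boundary_lines = [_snap(ign_part.exterior)] + [_snap(r) for r in ign_part.interiors]
    linework = unary_union(list(clipped.values()) + list(boundary_lines))

    faces = [f for f in polygonize(_line_parts(linework))
             if f.representative_point().within(ign_part_snapped)]
    faces.sort(key=_face_sort_key)
    if not faces:  # degenerate precision collapse: fall back to the raw part
        faces = [ign_part]

    # ignition face: any face within the snap tolerance of the point counts
    # as adjacent (covers the on-arc case, where snapping may have nudged the
    # arc off the point); ties resolve to the smallest face.
    tol = max(snap_tol, 1e-12)
    candidates = [f for f in faces if f.distance(fire.ignition) <= tol]
    if not candidates:
        candidates = [min(faces, key=lambda f: f.distance(fire.ignition))]
    ignition_face = min(candidates, key=_face_sort_key)

    fully_split = len(faces) > 1 and ignition_face.area < ign_part.area * (1 - 1e-12)

    break_arcs: dict[str, float] = {}
    arc_geoms: dict[str, BaseGeometry] = {}
    if fully_split:
        ring = ignition_face.boundary
        for bid, line in clipped.items():
            shared = _line_parts(line.intersection(ring))
            length = sum(s.length for s in shared)
            if length > 0:
                break_arcs[bid] = float(length)
                arc_geoms[bid] = unary_union(shared)

    all_faces = faces + other_parts
    return SplitResult(
        faces=all_faces,
        ignition_face=ignition_face,
        fully_split=fully_split,
        break_arcs=break_arcs,
        arc_geoms=arc_geoms,
        footprint_area=float(footprint.area),
    )


def constituent_breaks(
    split: SplitResult, min_arc_length: float | None = None
) -> ConstituentSet:
    """Identify ``S_j``: breaks whose arcs bound the ignition face.

    Breaks sharing no more than ``min_arc_length`` of boundary with the
    ignition face (point touches, slivers) are excluded.  A fire that is not
    fully split returns the empty set: it can never be contained.
    """
    if not split.fully_split:
        return EMPTY_SET
    if min_arc_length is None:
        bounds = [f.bounds for f in split.faces]
        xmin = min(b[0] for b in bounds)
        ymin = min(b[1] for b in bounds)
        xmax = max(b[2] for b in bounds)
        ymax = max(b[3] for b in bounds)
        min_arc_length = MIN_ARC_REL_LENGTH * math.hypot(xmax - xmin, ymax - ymin)
    ids = frozenset(
        bid for bid, length in split.break_arcs.items() if length > min_arc_length
    )
    return ConstituentSet(ids)


def avoided_area(fire: FireEvent, split: SplitResult) -> float:
    """Avoided fire area burned (AFB).

    The footprint area outside the ignition polygon — protected when
    containment succeeds — or zero when the fire is not fully split.
    """
    if not split.fully_split or split.ignition_face is None:
        return 0.0
    return max(0.0, split.footprint_area - float(split.ignition_face.area))
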