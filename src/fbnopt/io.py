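"""Serialization: GeoJSON vectors, JSON-lines records, JSON/CSV solutions.

All vector coordinates must be planar (projected, meters).  GeoJSON files
declaring a geographic CRS (EPSG:4326 / CRS84) are rejected — splitting and
zonal math here is strictly Euclidean.  Writers are deterministic (sorted
keys, ``\\n`` newlines) so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from shapely.geometry import Point, mapping, shape

from .geometry import BreakSegment, ConstituentSet, FireEvent
from .optimize import ProblemInstance, Solution
from .valuation import ContainmentRecord

__all__ = [
    "read_breaks_geojson", "write_breaks_geojson",
    "read_fires_geojson", "write_fires_geojson",
    "write_records_jsonl", "read_records_jsonl",
    "write_solution_json", "write_solution_csv",
    "write_selection_geojson",
]

_GEOGRAPHIC_NAMES = ("4326", "CRS84", "WGS 84", "WGS84")


def _check_planar(fc: dict, path) -> None:
    crs = fc.get("crs")
    if crs is None:
        return  # assumed planar; GeoJSON carries no projected-CRS standard
    name = str(crs.get("properties", {}).get("name", crs))
    if any(tag in name for tag in _GEOGRAPHIC_NAMES):
        raise ValueError(
            f"{path}: geographic (lon/lat) coordinates are not supported; "
            "reproject the data to a planar CRS in meters first"
        )


def _load_fc(path) -> dict:
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    _check_planar(fc, path)
    return fc


def read_breaks_geojson(path: str | Path) -> list[BreakSegment]:
    fc = _load_fc(path)
    breaks = []
    for i, feat in enumerate(fc["features"]):
        props = feat.get("properties") or {}
        bid = str(props.get("id", f"b{i + 1:04d}"))
        cost = props.get("cost")
        breaks.append(
            BreakSegment(id=bid, geom=shape(feat["geometry"]),
                         cost=float(cost) if cost is not None else None)
        )
    ids = [b.id for b in breaks]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: break ids are not unique")
    return breaks


def write_breaks_geojson(breaks: list[BreakSegment], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(b.geom),
            "properties": {"id": b.id, "cost": b.effective_cost,
                           "length_m": b.length_m},
        }
        for b in breaks
    ]
    _dump_json({"type": "FeatureCollection", "features": feats}, path)


def read_fires_geojson(path: str | Path,
                       ignitions_path: str | Path | None = None) -> list[FireEvent]:
    """Fire footprints with ignitions either inline (`ignition_x`/`ignition_y`
    properties) or as a companion Point FeatureCollection keyed by fire id."""
    fc = _load_fc(path)
    ign_by_id: dict[str, Point] = {}
    if ignitions_path is not None:
        ifc = _load_fc(ignitions_path)
        for feat in ifc["features"]:
            props = feat.get("properties") or {}
            geom = shape(feat["geometry"])
            if not isinstance(geom, Point):
                raise ValueError(f"{ignitions_path}: ignition features must be Points")
            ign_by_id[str(props.get("id"))] = geom

    fires = []
    for i, feat in enumerate(fc["features"]):
        props = feat.get("properties") or {}
        fid = str(props.get("id", f"f{i + 1:05d}"))
        geom = shape(feat["geometry"])
        if "ignition_x" in props and "ignition_y" in props:
            ign = Point(float(props["ignition_x"]), float(props["ignition_y"]))
        elif fid in ign_by_id:
            ign = ign_by_id[fid]
        else:
            raise ValueError(
                f"{path}: fire {fid!r} has no ignition (ignition_x/ignition_y "
                "properties or a companion ignition point layer required)"
            )
        size = float(props.get("size", geom.area))
        fires.append(FireEvent(id=fid, footprint=geom, ignition=ign, size=size))
    return fires


def write_fires_geojson(fires: list[FireEvent], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(f.footprint),
            "properties": {
                "id": f.id, "size": f.size,
                "ignition_x": f.ignition.x, "ignition_y": f.ignition.y,
            },
        }
        for f in fires
    ]
    _dump_json({"type": "FeatureCollection", "features": feats}, path)


def _rec_to_dict(rec: ContainmentRecord) -> dict:
    return {
        "fire_id": rec.fire_id,
        "s": sorted(rec.s.break_ids),
        "s_raw": sorted(rec.s_raw.break_ids),
        "max_flame": rec.max_flame,
        "afb": rec.afb,
        "awb": rec.awb,
        "size": rec.size,
    }


def _rec_from_dict(d: dict) -> ContainmentRecord:
    return ContainmentRecord(
        fire_id=d["fire_id"],
        s=ConstituentSet(frozenset(d["s"])),
        s_raw=ConstituentSet(frozenset(d.get("s_raw", d["s"]))),
        max_flame=d.get("max_flame"),
        afb=float(d["afb"]),
        awb=float(d["awb"]),
        size=float(d.get("size", 1.0)),
    )


def write_records_jsonl(records: list[ContainmentRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(json.dumps(_rec_to_dict(rec), sort_keys=True))
            fh.write("\n")


def read_records_jsonl(path: str | Path) -> list[ContainmentRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(_rec_from_dict(json.loads(line)))
    return records


def write_solution_json(solution: Solution, path: str | Path) -> None:
    _dump_json(
        {
            "selected": sorted(solution.selected),
            "contained": sorted(solution.contained),
            "objective_value": solution.objective_value,
            "status": solution.status,
            "gap": None if math.isnan(solution.gap) else solution.gap,
            "spend": solution.spend,
            "budget_feasible": solution.budget_feasible,
        },
        path,
    )


def write_solution_csv(instance: ProblemInstance, solution: Solution,
                       path: str | Path) -> None:
    """One row per break (x_i) then one per fire (y_j, V_j)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("kind,id,x,y,value\n")
        for b in instance.breaks:
            x = int(b.id in solution.selected)
            fh.write(f"break,{b.id},{x},,\n")
        for rec in instance.records:
            y = int(rec.fire_id in solution.contained)
            fh.write(f"fire,{rec.fire_id},,{y},{instance.value(rec)!r}\n")


def write_selection_geojson(breaks: list[BreakSegment], selected: set[str],
                            path: str | Path) -> None:
    """Treatment layout: the network with a selected flag per break."""
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(b.geom),
            "properties": {"id": b.id, "selected": int(b.id in selected)},
        }
        for b in breaks
    ]
    _dump_json({"type": "FeatureCollection", "features": feats}, path)


def _dump_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, sort_keys=True, separators=(",", ": "), indent=1)
        fh.write("\n")
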