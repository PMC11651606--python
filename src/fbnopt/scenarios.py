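"""Preprocessing pipeline and full-factorial scenario execution.

The pipeline mirrors the three data-processing stages of the method:

1. drop fires whose footprints never touch the network (they cannot affect
   any selection decision);
2. split each remaining footprint, extract the ignition polygon and its
   constituent break set, and find the maximum flame length along the
   bounding arcs;
3. compute the two protected-value candidates per fire (avoided area, and
   avoided WUI value).

A scenario grid then crosses objectives x fire filters x escape flame
length thresholds x budget fractions, solving one exact model and one
rule-based model per cell.  Geometry and flame maxima are computed once and
re-screened per FL threshold, since screening is the only FL-dependent
step.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass

import pandas as pd
from shapely.strtree import STRtree

from .geometry import (
    BreakSegment,
    FireEvent,
    constituent_breaks,
    split_footprint,
)
from .optimize import ProblemInstance, build_mip, solve
from .raster import RasterGrid
from .rbs import rbs_solve
from .valuation import ContainmentRecord, build_record

__all__ = [
    "ScenarioSpec",
    "PreprocessStats",
    "analyze_fires",
    "apply_screen",
    "preprocess",
    "filter_fires",
    "run_grid",
]

log = logging.getLogger(__name__)

LARGE_FIRE_FRACTION = 0.20


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factorial design."""

    objective: str = "afb"                 # "afb" | "awb"
    fire_filter: str = "all"               # "all" | "no_large"
    fl_threshold: float = math.inf
    budget_fraction: float = 1.0           # of total network length (or cost)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.budget_fraction <= 1):
            raise ValueError("budget_fraction must lie in (0, 1]")
        if self.fl_threshold <= 0:
            raise ValueError("fl_threshold must be positive (math.inf allowed)")
        if self.fire_filter not in ("all", "no_large"):
            raise ValueError(f"unknown fire_filter {self.fire_filter!r}")


@dataclass
class PreprocessStats:
    """Stage-by-stage fire accounting, mirrored in the log output."""

    n_read: int = 0
    n_disjoint: int = 0
    n_retained: int = 0
    n_fully_split: int = 0
    n_screened_out: int = 0
    n_containable: int = 0


def analyze_fires(
    fires: list[FireEvent],
    network: list[BreakSegment],
    flame: RasterGrid | dict[str, RasterGrid] | None,
    wui: RasterGrid | None,
    min_arc_length: float | None = None,
    flame_mode: str = "arcs",
    stats: PreprocessStats | None = None,
) -> list[ContainmentRecord]:
    """FL-independent preprocessing: geometry, flame maxima, values.

    Fires disjoint from every break are dropped (with a logged count).
    Records come back *unscreened*: ``s == s_raw``.  ``flame`` may be one
    shared raster or a mapping fire id -> raster; ``None`` disables flame
    screening entirely.
    """
    if stats is None:
        stats = PreprocessStats()
    stats.n_read = len(fires)

    tree = STRtree([b.geom for b in network]) if network else None
    records: list[ContainmentRecord] = []
    for fire in fires:
        if tree is None:
            hit = False
        else:
            cand = tree.query(fire.footprint, predicate="intersects")
            hit = len(cand) > 0
        if not hit:
            stats.n_disjoint += 1
            continue
        stats.n_retained += 1
        try:
            split = split_footprint(fire, network)
        except ValueError as exc:
            raise ValueError(f"preprocessing fire {fire.id!r} failed: {exc}") from exc
        s_raw = constituent_breaks(split, min_arc_length)
        if split.fully_split:
            stats.n_fully_split += 1
        fire_flame = flame.get(fire.id) if isinstance(flame, dict) else flame
        rec = build_record(
            fire, split, s_raw, fire_flame, wui,
            fl_threshold=math.inf, flame_mode=flame_mode,
        )
        records.append(rec)

    log.info(
        "preprocess: %d fires read, %d disjoint from the network (excluded), "
        "%d retained, %d fully split",
        stats.n_read, stats.n_disjoint, stats.n_retained, stats.n_fully_split,
    )
    return records


def apply_screen(records: list[ContainmentRecord], fl_threshold: float,
                 stats: PreprocessStats | None = None) -> list[ContainmentRecord]:
    """Re-apply the escape-flame-length screen to unscreened (or screened) records."""
    out = [rec.rescreen(fl_threshold) for rec in records]
    n_out = sum(1 for r in out if r.s_raw and not r.containable)
    n_in = sum(1 for r in out if r.containable)
    if stats is not None:
        stats.n_screened_out = n_out
        stats.n_containable = n_in
    log.info("screen FL=%s: %d containable, %d screened out", fl_threshold, n_in, n_out)
    return out


def preprocess(
    fires: list[FireEvent],
    network: list[BreakSegment],
    flame: RasterGrid | dict[str, RasterGrid] | None,
    wui: RasterGrid | None,
    fl_threshold: float = math.inf,
    min_arc_length: float | None = None,
    flame_mode: str = "arcs",
) -> list[ContainmentRecord]:
    """Full preprocessing at one FL threshold (stages 1-3 plus screening)."""
    stats = PreprocessStats()
    base = analyze_fires(fires, network, flame, wui, min_arc_length,
                         flame_mode, stats)
    return apply_screen(base, fl_threshold, stats)


def filter_fires(records: list[ContainmentRecord], mode: str) -> list[ContainmentRecord]:
    """Fire-sample selection: all fires, or the largest 20% excluded.

    ``no_large`` drops exactly ``floor(0.20 n)`` of the retained fires, from
    the largest size down; ties at the cutoff are dropped larger-id-first,
    so the result is fully deterministic.
    """
    if mode == "all":
        return list(records)
    if mode != "no_large":
        raise ValueError(f"unknown fire filter {mode!r}")
    n_drop = int(LARGE_FIRE_FRACTION * len(records))
    if n_drop == 0:
        return list(records)
    order = sorted(records, key=lambda r: (r.size, r.fire_id))
    return order[: len(records) - n_drop]


def _budget_base(breaks: list[BreakSegment], budget_mode: str) -> float:
    if budget_mode == "length":
        return sum(b.length_m for b in breaks)
    return sum(b.effective_cost for b in breaks)


def run_grid(
    network: list[BreakSegment],
    fires: list[FireEvent],
    flame: RasterGrid | dict[str, RasterGrid] | None,
    wui: RasterGrid | None,
    objectives: tuple[str, ...] = ("afb", "awb"),
    fire_filters: tuple[str, ...] = ("all", "no_large"),
    fl_thresholds: tuple[float, ...] = (4.0, 8.0, math.inf),
    budget_fractions: tuple[float, ...] = tuple((b + 1) / 10 for b in range(10)),
    budget_mode: str = "length",
    flame_mode: str = "arcs",
    rel_gap: float = 0.0,
) -> pd.DataFrame:
    """Run the full factorial of scenarios, one OPT and one RBS row per cell.

    The default grid (2 objectives x 2 filters x 3 FL thresholds x 10
    budgets) is 120 cells; budgets are fractions of the total network
    length.  Cell failures are recorded as ``status='error'`` rows and the
    grid continues.

    Returns a DataFrame with one row per (cell, method).
    """
    base = analyze_fires(fires, network, flame, wui, flame_mode=flame_mode)
    total = _budget_base(network, budget_mode)
    rows: list[dict] = []
    for filt in fire_filters:
        for fl in fl_thresholds:
            screened = apply_screen(base, fl)
            kept = filter_fires(screened, filt)
            for objective in objectives:
                for frac in budget_fractions:
                    budget = frac * total
                    cell = dict(
                        objective=objective,
                        fire_filter=filt,
                        fl_threshold=fl,
                        budget_fraction=frac,
                        budget=budget,
                        n_fires=len(kept),
                    )
                    instance = ProblemInstance(
                        breaks=list(network), records=kept, budget=budget,
                        objective=objective, budget_mode=budget_mode,
                    )
                    results = {}
                    for method in ("OPT", "RBS"):
                        t0 = time.perf_counter()
                        try:
                            if method == "OPT":
                                sol = solve(build_mip(instance), rel_gap=rel_gap)
                            else:
                                sol = rbs_solve(instance)
                            results[method] = sol
                            rows.append(
                                cell
                                | dict(
                                    method=method,
                                    status=sol.status,
                                    objective_value=sol.objective_value,
                                    spend=sol.spend,
                                    gap=sol.gap,
                                    n_contained=len(sol.contained),
                                    prop_contained=(
                                        len(sol.contained) / len(kept) if kept else 0.0
                                    ),
                                    selected=",".join(sorted(sol.selected)),
                                    wall_time=time.perf_counter() - t0,
                                )
                            )
                        except Exception as exc:  # record, keep the grid going
                            log.error("cell %s %s failed: %s", cell, method, exc)
                            rows.append(
                                cell
                                | dict(
                                    method=method, status="error",
                                    objective_value=float("nan"), spend=float("nan"),
                                    gap=float("nan"), n_contained=0,
                                    prop_contained=float("nan"), selected="",
                                    wall_time=time.perf_counter() - t0,
                                )
                            )
                    if "OPT" in results and "RBS" in results:
                        rbs_obj = results["RBS"].objective_value
                        ratio = (
                            results["OPT"].objective_value / rbs_obj
                            if rbs_obj > 0 else float("nan")
                        )
                        for row in rows[-2:]:
                            row["opt_rbs_ratio"] = ratio
    report = pd.DataFrame(rows)
    return report
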