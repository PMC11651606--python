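"""Seeded synthetic landscapes.

The real inputs to this kind of analysis — stochastic fire footprints with
ignition points and flame-length rasters from a large-fire simulator, a
housing-density (WUI) raster, and a vector fuel-break network — are bulky
and proprietary.  These generators produce small landscapes with the same
statistical structure so every stage of the pipeline is exercisable from a
single integer seed:

* a connected (jittered-)lattice polyline network, one break per lattice
  edge, with optional random dropout;
* fire footprints built as buffered correlated random walks, scaled to an
  exact lognormally distributed area, each with a strictly interior
  ignition point — irregular shapes that cross several breaks at once;
* a spatially smooth lognormal flame-length field and a clustered
  nonnegative WUI field, on independent grids.

All randomness flows through one ``numpy`` Generator per call, so identical
seeds give byte-identical serialized outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely import affinity
from shapely.geometry import LineString, MultiPolygon, Point, Polygon, box

from .geometry import BreakSegment, FireEvent
from .raster import RasterGrid

__all__ = [
    "SynthConfig",
    "Landscape",
    "generate_network",
    "generate_fires",
    "generate_rasters",
    "generate_landscape",
    "toy_fixture",
]


@dataclass
class SynthConfig:
    """Knobs for one synthetic landscape.

    Defaults describe a 12 x 12 km landscape with a 1.5 km jittered lattice
    network (15% of edges dropped), 150 fires with lognormal areas of median
    ~44 ha and a heavy tail (sigma = 1 on the log scale, so the largest
    fires reach tens of km^2 and span many breaks), a 270 m flame grid whose
    log-field has standard deviation 0.5 around a median of ~3.5 feet (a
    realistic mix relative to 4 ft / 8 ft escape thresholds), and five WUI
    patches on a 30 m grid capped at the per-cell area of 0.09 ha.
    """

    seed: int = 0
    extent: tuple[float, float] = (12_000.0, 12_000.0)
    # network
    pattern: str = "jittered-lattice"     # "lattice" | "jittered-lattice"
    spacing: float = 1_500.0              # m between lattice lines
    jitter: float = 0.15                  # node displacement, fraction of spacing
    dropout: float = 0.15                 # fraction of lattice edges removed
    # fires
    n_fires: int = 150
    area_log_mean: float = math.log(4.4e5)   # median fire area ~44 ha
    area_log_sigma: float = 1.0
    walk_steps: int = 12
    # rasters
    flame_cell: float = 270.0
    flame_log_mean: float = math.log(3.5)    # median flame ~3.5 ft
    flame_roughness: float = 0.5             # sigma of the log flame field
    flame_corr_length: float = 800.0         # smoothing length, m
    wui_cell: float = 30.0
    wui_patches: int = 5
    wui_patch_scale: float = 600.0           # Gaussian decay length, m
    wui_cell_cap: float = 0.09               # max WUI ha per 30 m cell

    def __post_init__(self) -> None:
        w, h = self.extent
        if w <= 0 or h <= 0:
            raise ValueError("extent must be positive in both directions")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if not (0 <= self.jitter < 0.5):
            raise ValueError("jitter must lie in [0, 0.5)")
        if self.spacing <= 0 or self.spacing > min(w, h):
            raise ValueError("spacing must be positive and fit inside the extent")
        if self.pattern not in ("lattice", "jittered-lattice"):
            raise ValueError(f"unknown network pattern {self.pattern!r}")
        for name in ("n_fires", "walk_steps", "wui_patches"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("flame_cell", "wui_cell", "flame_corr_length",
                     "wui_patch_scale", "area_log_sigma", "flame_roughness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class Landscape:
    """One complete synthetic input bundle."""

    network: list[BreakSegment]
    fires: list[FireEvent]
    flame: RasterGrid
    wui: RasterGrid
    budget: float | None = None
    budget_mode: str = "length"
    fl_threshold: float = math.inf
    notes: str = ""


def _rng(cfg: SynthConfig, salt: int) -> np.random.Generator:
    # independent stream per generator so e.g. changing n_fires leaves the
    # network untouched
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), salt]))


def generate_network(cfg: SynthConfig) -> list[BreakSegment]:
    """Lattice (optionally jittered, with edge dropout) of break segments.

    Nodes sit at every multiple of ``spacing`` across the extent (including
    the edges); every horizontal and vertical lattice edge becomes one
    break.  A 3 x 3-cell lattice therefore yields 24 unit segments.
    """
    rng = _rng(cfg, 1)
    w, h = cfg.extent
    nx = int(round(w / cfg.spacing)) + 1   # nodes per row
    ny = int(round(h / cfg.spacing)) + 1
    if nx < 2 or ny < 2:
        raise ValueError("extent/spacing combination yields a degenerate lattice")

    xs = np.linspace(0.0, w, nx)
    ys = np.linspace(0.0, h, ny)
    nodes = np.empty((ny, nx, 2))
    nodes[..., 0] = xs[None, :]
    nodes[..., 1] = ys[:, None]
    if cfg.pattern == "jittered-lattice" and cfg.jitter > 0:
        # interior nodes only, so the network keeps covering the extent
        dx = rng.uniform(-1, 1, size=(ny, nx)) * cfg.jitter * cfg.spacing
        dy = rng.uniform(-1, 1, size=(ny, nx)) * cfg.jitter * cfg.spacing
        dx[[0, -1], :] = 0.0
        dx[:, [0, -1]] = 0.0
        dy[[0, -1], :] = 0.0
        dy[:, [0, -1]] = 0.0
        nodes[..., 0] += dx
        nodes[..., 1] += dy

    segments: list[BreakSegment] = []
    k = 0
    # horizontal edges row by row, then vertical edges — stable id order
    for r in range(ny):
        for c in range(nx - 1):
            k += 1
            geom = LineString([nodes[r, c], nodes[r, c + 1]])
            segments.append(BreakSegment(id=f"b{k:04d}", geom=geom))
    for r in range(ny - 1):
        for c in range(nx):
            k += 1
            geom = LineString([nodes[r, c], nodes[r + 1, c]])
            segments.append(BreakSegment(id=f"b{k:04d}", geom=geom))

    if cfg.dropout > 0:
        keep = rng.random(len(segments)) >= cfg.dropout
        segments = [s for s, k_ in zip(segments, keep) if k_]
    return segments


def _walk_polygon(rng: np.random.Generator, start: np.ndarray, area: float,
                  steps: int) -> Polygon:
    """Buffered correlated random walk, affinely scaled to an exact area."""
    scale = math.sqrt(area)
    heading = rng.uniform(0, 2 * math.pi)
    pts = [start.copy()]
    for _ in range(max(steps, 1)):
        heading += rng.normal(0, 0.9)
        step = rng.uniform(0.15, 0.45) * scale
        pts.append(pts[-1] + step * np.array([math.cos(heading), math.sin(heading)]))
    spine = LineString(pts)
    poly = spine.buffer(0.35 * math.sqrt(area / math.pi), quad_segs=8)
    if isinstance(poly, MultiPolygon):  # extremely contorted walk; take largest
        poly = max(poly.geoms, key=lambda g: g.area)
    factor = math.sqrt(area / poly.area)
    poly = affinity.scale(poly, xfact=factor, yfact=factor, origin="centroid")
    return poly


def generate_fires(cfg: SynthConfig) -> list[FireEvent]:
    """Fires as buffered random walks with exact lognormal areas.

    Each footprint is a simple polygon whose area equals its lognormal draw
    exactly (the walk shape is scaled about its centroid); the ignition
    point is rejection-sampled strictly inside the footprint.
    """
    rng = _rng(cfg, 2)
    w, h = cfg.extent
    fires: list[FireEvent] = []
    for k in range(cfg.n_fires):
        area = float(np.exp(rng.normal(cfg.area_log_mean, cfg.area_log_sigma)))
        start = rng.uniform([0.05 * w, 0.05 * h], [0.95 * w, 0.95 * h])
        poly = _walk_polygon(rng, start, area, cfg.walk_steps)
        xmin, ymin, xmax, ymax = poly.bounds
        while True:  # interior ignition; buffered walks make this terminate fast
            p = Point(rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
            if poly.contains(p) and poly.exterior.distance(p) > 1e-9:
                break
        fires.append(
            FireEvent(id=f"f{k + 1:05d}", footprint=poly, ignition=p,
                      size=float(poly.area))
        )
    return fires


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int],
                       sigma_cells: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    if sigma_cells > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma_cells, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = z / sd
    return z


def generate_rasters(cfg: SynthConfig) -> tuple[RasterGrid, RasterGrid]:
    """(flame, wui) rasters on the configured extent.

    Flame: ``exp(mu + roughness * Z)`` with ``Z`` a smoothed unit-variance
    Gaussian field (roughness 0 gives a spatially constant field).  WUI:
    sum of Gaussian patches, clipped to the per-cell area cap; zero patches
    give an all-zero raster.
    """
    rng = _rng(cfg, 3)
    w, h = cfg.extent

    fc, fr = int(math.ceil(w / cfg.flame_cell)), int(math.ceil(h / cfg.flame_cell))
    z = _smooth_unit_field(rng, (fr, fc), cfg.flame_corr_length / cfg.flame_cell)
    flame_vals = np.exp(cfg.flame_log_mean + cfg.flame_roughness * z)
    flame = RasterGrid(x0=0.0, y0=0.0, cell_size=cfg.flame_cell, values=flame_vals)

    wc, wr = int(math.ceil(w / cfg.wui_cell)), int(math.ceil(h / cfg.wui_cell))
    wui_vals = np.zeros((wr, wc))
    if cfg.wui_patches > 0:
        cx = (np.arange(wc) + 0.5) * cfg.wui_cell
        cy = (wr - np.arange(wr) - 0.5) * cfg.wui_cell
        gx, gy = np.meshgrid(cx, cy)
        for _ in range(cfg.wui_patches):
            px, py = rng.uniform([0, 0], [w, h])
            amp = rng.uniform(0.5, 1.0) * cfg.wui_cell_cap
            d2 = (gx - px) ** 2 + (gy - py) ** 2
            wui_vals += amp * np.exp(-d2 / (2 * cfg.wui_patch_scale**2))
        wui_vals = np.clip(wui_vals, 0.0, cfg.wui_cell_cap)
    wui = RasterGrid(x0=0.0, y0=0.0, cell_size=cfg.wui_cell, values=wui_vals)
    return flame, wui


def generate_landscape(cfg: SynthConfig) -> Landscape:
    """Network + fires + rasters for one seed."""
    flame, wui = generate_rasters(cfg)
    return Landscape(
        network=generate_network(cfg),
        fires=generate_fires(cfg),
        flame=flame,
        wui=wui,
    )


def toy_fixture() -> Landscape:
    """Hand-built 4-break / 4-fire landscape with a known optimality gap.

    Four vertical breaks (explicit costs 2, 2, 3, 1) and four rectangular
    fires whose ignition polygons require the break sets {b1,b2}, {b2,b3},
    {b1,b3}, {b4} with avoided-area values 4, 3, 5, 0.5.  At the documented
    budget B = 5 (cost mode) the exact optimum treats {b1, b3} and protects
    5 area units, while the effectiveness ranking walks b1, b2, b4 into the
    budget and protects only 4.5 — the coordination failure of scoring
    breaks under full-network treatment.  The constant 3.0 flame field
    passes the documented FL = 4 screen everywhere; at full budget (8) both
    approaches saturate at 12.5.
    """
    breaks = [
        BreakSegment("b1", LineString([(2, -1), (2, 11)]), cost=2.0),
        BreakSegment("b2", LineString([(4, -1), (4, 6)]), cost=2.0),
        BreakSegment("b3", LineString([(6, -1), (6, 11)]), cost=3.0),
        BreakSegment("b4", LineString([(8, -1), (8, 11)]), cost=1.0),
    ]
    fires = [
        # S={b1,b2}: split into strips of widths 1, 2, 1 (height 2) -> AFB 4
        FireEvent("f1", box(1, 0, 5, 2), Point(3, 0.5), size=8.0),
        # S={b2,b3}: widths 1, 2, 1 (height 1.5) -> AFB 3
        FireEvent("f2", box(3, 3, 7, 4.5), Point(5, 3.75), size=6.0),
        # S={b1,b3} (b2 stops at y=6): widths 1, 4, 1 (height 2.5) -> AFB 5
        FireEvent("f3", box(1, 7, 7, 9.5), Point(4, 8), size=15.0),
        # S={b4}: halves of 0.5 each -> AFB 0.5
        FireEvent("f4", box(7, 0, 9, 0.5), Point(7.5, 0.25), size=1.0),
    ]
    flame = RasterGrid(x0=-2.0, y0=-2.0, cell_size=1.0,
                       values=np.full((16, 14), 3.0))
    wui_col = np.linspace(0.0, 0.08, 20)
    wui = RasterGrid(x0=0.0, y0=0.0, cell_size=0.5,
                     values=np.tile(wui_col, (20, 1)))
    return Landscape(
        network=breaks,
        fires=fires,
        flame=flame,
        wui=wui,
        budget=5.0,
        budget_mode="cost",
        fl_threshold=4.0,
        notes="documented intermediate budget B=5 (cost mode): OPT 5.0 > RBS 4.5",
    )
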