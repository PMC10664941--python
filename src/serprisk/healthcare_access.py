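"""Friction-surface travel time to the nearest treating facility.

A per-cell speed is assembled from landcover class, road presence and
slope; its reciprocal (minutes per metre) is the friction surface. Travel
time is exact multi-source Dijkstra on the 8-connected cell lattice with
edge cost = step length x mean of the two endpoint frictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import GridLayer, require_same_grid
from .synthetic_landscape import EATable, LANDCOVER_CLASSES


@dataclass
class SpeedTable:
    """Travel speeds in km/h per landcover class plus road and slope rules."""

    landcover_speeds: dict[int, float] = field(default_factory=lambda: {
        LANDCOVER_CLASSES["built_up"]: 25.0,
        LANDCOVER_CLASSES["cropland"]: 8.0,
        LANDCOVER_CLASSES["trees"]: 4.0,
        LANDCOVER_CLASSES["grassland"]: 6.0,
    })
    road_speed: float = 60.0
    slope_factor: float = 0.97       # speed multiplier per degree of slope
    walking_floor: float = 5.0       # km/h on barrier classes
    barrier_classes: tuple[int, ...] = (
        LANDCOVER_CLASSES["water_protected"],)
    barriers_impassable: bool = False

    def __post_init__(self) -> None:
        if self.road_speed <= 0 or self.walking_floor <= 0:
            raise ValueError("speeds must be positive")
        if any(v <= 0 for v in self.landcover_speeds.values()):
            raise ValueError("speeds must be positive")
        if not 0.0 < self.slope_factor <= 1.0:
            raise ValueError("slope_factor must be in (0, 1]")


def slope_degrees(elevation: GridLayer) -> np.ndarray:
    """Slope of steepest descent, in degrees, by central differences."""
    gy, gx = np.gradient(elevation.data, elevation.cell_size)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def speed_to_friction(speed_kmh) -> np.ndarray:
    """km/h -> minutes per metre."""
    return 60.0 / (np.asarray(speed_kmh, dtype=float) * 1000.0)


def build_friction_surface(landcover: GridLayer, roads: GridLayer,
                           elevation: GridLayer,
                           speeds: SpeedTable | None = None) -> GridLayer:
    """Per-cell friction in minutes per metre; impassable cells get +inf."""
    speeds = speeds or SpeedTable()
    require_same_grid(landcover, roads, elevation)
    lc = landcover.data.astype(int)
    known = set(speeds.landcover_speeds) | set(speeds.barrier_classes)
    present = set(np.unique(lc).tolist())
    unknown = present - known
    if unknown:
        raise ValueError(f"unknown landcover class(es): {sorted(unknown)}")

    speed = np.empty(lc.shape, dtype=float)
    for cls, v in speeds.landcover_speeds.items():
        speed[lc == cls] = v
    barrier = np.isin(lc, speeds.barrier_classes)
    speed[barrier] = speeds.walking_floor
    speed[roads.data.astype(bool)] = speeds.road_speed
    speed = speed * speeds.slope_factor ** slope_degrees(elevation)

    friction = speed_to_friction(speed)
    if speeds.barriers_impassable:
        friction[barrier] = np.inf
    return landcover.copy_with(friction)


def _lattice_graph(friction: GridLayer) -> coo_matrix:
    """Sparse 8-connected graph; edge weight = distance x mean friction."""
    f = friction.data
    nr, nc = f.shape
    cell = friction.cell_size
    idx = np.arange(nr * nc).reshape(nr, nc)
    rows, cols, weights = [], [], []
    steps = [(0, 1, cell), (1, 0, cell),
             (1, 1, cell * np.sqrt(2.0)), (1, -1, cell * np.sqrt(2.0))]
    for dr, dc, dist in steps:
        src = idx[max(0, -dr):nr - max(0, dr), max(0, -dc):nc - max(0, dc)]
        dst = idx[max(0, dr):nr + min(0, dr), max(0, dc):nc + min(0, dc)]
        w = dist * 0.5 * (f.ravel()[src.ravel()] + f.ravel()[dst.ravel()])
        ok = np.isfinite(w)
        rows.append(src.ravel()[ok])
        cols.append(dst.ravel()[ok])
        weights.append(w[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    return coo_matrix((weights, (rows, cols)), shape=(nr * nc, nr * nc))


@dataclass
class TravelTimeSurface:
    layer: GridLayer  # minutes; +inf where unreachable


def travel_time_surface(friction: GridLayer,
                        facility_cells: list[tuple[int, int]]
                        ) -> TravelTimeSurface:
    """Exact multi-source Dijkstra over the 8-connected lattice."""
    if not facility_cells:
        raise ValueError("at least one facility cell is required")
    nr, nc = friction.shape
    for r, c in facility_cells:
        if not (0 <= r < nr and 0 <= c < nc):
            raise ValueError(f"facility cell {(r, c)} outside grid")
    graph = _lattice_graph(friction)
    sources = [r * nc + c for r, c in facility_cells]
    dist = dijkstra(graph, directed=False, indices=sources)
    minutes = np.min(np.atleast_2d(dist), axis=0).reshape(nr, nc)
    return TravelTimeSurface(layer=friction.copy_with(minutes))


def facility_cells_from_table(facilities: pd.DataFrame,
                              treats_only: bool = True
                              ) -> list[tuple[int, int]]:
    df = facilities
    if treats_only and "treats_snakebite" in df.columns:
        df = df[df["treats_snakebite"].astype(bool)]
    return [(int(r), int(c)) for r, c in zip(df["row"], df["col"])]


def zonal_travel_time(surface: TravelTimeSurface, eas: EATable,
                      population: GridLayer | None = None) -> pd.Series:
    """Per-EA mean travel time in minutes, optionally population-weighted."""
    t = surface.layer.data
    if t.shape != eas.labels.shape:
        raise ValueError("surface and EA labels must share the grid frame")
    labels = eas.labels
    n = eas.n_eas
    valid = np.isfinite(t)
    if population is not None:
        if population.shape != t.shape:
            raise ValueError("population raster must share the grid frame")
        w = np.where(valid, population.data, 0.0)
    else:
        w = valid.astype(float)
    num = np.bincount(labels.ravel(),
                      weights=np.where(valid, t, 0.0).ravel() * w.ravel(),
                      minlength=n)
    den = np.bincount(labels.ravel(), weights=w.ravel(), minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return pd.Series(means, index=eas.table["ea_id"], name="travel_minutes")
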