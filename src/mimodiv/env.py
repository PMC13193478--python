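"""Occurrence cleaning and species-level environmental predictor assembly.

Steps mirror a standard niche-characterization workflow: native-range
filtering (point-in-polygon), convex-hull range delineation, random-point
generation on the environmental grid for poorly sampled species (< 5
records), spatial thinning at a minimum great-circle distance, extraction
and per-species aggregation of gridded environmental variables, VIF
collinearity screening, and mean-centering/2-SD scaling of predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.prepared import prep

__all__ = [
    "OccurrenceSet",
    "GridEnv",
    "filter_native",
    "convex_hull",
    "random_points_in_polygon",
    "thin_points",
    "haversine_km",
    "species_env_summary",
    "vif",
    "scale_2sd",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class OccurrenceSet:
    """Occurrence points (lon, lat in degrees) for one species."""

    species: str
    points: np.ndarray  # (n, 2) lon, lat
    provenance: list[str] = field(default_factory=list)  # 'observed' | 'random'

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.points.size:
            lon, lat = self.points[:, 0], self.points[:, 1]
            if lon.min() < -180 or lon.max() > 180 or abs(lat).max() > 90:
                raise ValueError(f"{self.species}: coordinates out of range")
        uniq = {tuple(p) for p in self.points}
        if len(uniq) != len(self.points):
            raise ValueError(f"{self.species}: exact duplicate points")
        if not self.provenance:
            self.provenance = ["observed"] * len(self.points)
        if len(self.provenance) != len(self.points):
            raise ValueError("provenance length mismatch")

    def __len__(self) -> int:
        return len(self.points)


def filter_native(
    occ: OccurrenceSet,
    native_polygons: list[Polygon] | Polygon | None,
    on_missing: str = "warn",
) -> OccurrenceSet:
    """Keep only points falling inside any native-range polygon.

    ``on_missing`` controls species without polygons: 'warn' retains all
    points with a warning, 'drop' removes the species (empty set).
    """
    if native_polygons is None:
        if on_missing == "drop":
            return OccurrenceSet(occ.species, np.empty((0, 2)), [])
        warnings.warn(
            f"{occ.species}: no native polygon; retaining all points", stacklevel=2
        )
        return occ
    polys = native_polygons if isinstance(native_polygons, list) else [native_polygons]
    for p in polys:
        if not p.is_valid:
            raise ValueError(f"{occ.species}: invalid native polygon")
    prepped = [prep(p) for p in polys]
    keep = [
        any(pp.covers(Point(lon, lat)) for pp in prepped)
        for lon, lat in occ.points
    ]
    removed = len(keep) - sum(keep)
    if removed:
        warnings.warn(
            f"{occ.species}: removed {removed} non-native points", stacklevel=2
        )
    return OccurrenceSet(
        occ.species,
        occ.points[np.asarray(keep, dtype=bool)],
        [pv for pv, k in zip(occ.provenance, keep) if k],
    )


def convex_hull(points: np.ndarray, degenerate_buffer: float = 0.0) -> Polygon:
    """Minimal convex polygon containing the points.

    With < 3 points or collinear points the hull is degenerate; it is
    buffered by ``degenerate_buffer`` (e.g. one grid cell) to give it area.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 1:
        raise ValueError("need at least one point")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        if degenerate_buffer <= 0:
            raise ValueError(
                "degenerate hull (collinear or < 3 points); provide degenerate_buffer"
            )
        hull = hull.buffer(degenerate_buffer)
    return hull


@dataclass
class GridEnv:
    """Regular lon/lat grid of environmental layers with nearest-cell lookup.

    ``layers`` maps variable name -> 2D array indexed [row=lat, col=lon];
    cell (0, 0) has center (x0, y0) and spacing (dx, dy).
    """

    layers: dict[str, np.ndarray]
    x0: float
    y0: float
    dx: float
    dy: float

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def cell_center(self, row, col):
        return self.x0 + np.asarray(col) * self.dx, self.y0 + np.asarray(row) * self.dy

    def lookup(self, var: str, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        arr = self.layers[var]
        col = np.clip(np.round((pts[:, 0] - self.x0) / self.dx), 0, arr.shape[1] - 1)
        row = np.clip(np.round((pts[:, 1] - self.y0) / self.dy), 0, arr.shape[0] - 1)
        return arr[row.astype(int), col.astype(int)]


def random_points_in_polygon(
    polygon: Polygon,
    n: int = 20,
    grid: GridEnv | None = None,
    grid_res: float = 1.0 / 120.0,  # 30 arc-seconds in degrees
    seed: int = 0,
) -> np.ndarray:
    """Sample ``n`` distinct grid-cell centers inside the polygon, uniformly
    without replacement, reproducibly by seed.

    The sampling frame is the environmental grid (given by ``grid``, or a
    regular grid of resolution ``grid_res`` aligned to the polygon bounds).
    Returns all available cells with a warning when fewer than ``n`` exist.
    """
    minx, miny, maxx, maxy = polygon.bounds
    if grid is not None:
        dx, dy = grid.dx, grid.dy
        c0 = int(np.ceil((minx - grid.x0) / dx))
        c1 = int(np.floor((maxx - grid.x0) / dx))
        r0 = int(np.ceil((miny - grid.y0) / dy))
        r1 = int(np.floor((maxy - grid.y0) / dy))
        cols = np.arange(c0, c1 + 1)
        rows = np.arange(r0, r1 + 1)
        xs = grid.x0 + cols * dx
        ys = grid.y0 + rows * dy
    else:
        xs = np.arange(minx + grid_res / 2, maxx, grid_res)
        ys = np.arange(miny + grid_res / 2, maxy, grid_res)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("polygon smaller than one grid cell")
    XX, YY = np.meshgrid(xs, ys)
    cand = np.column_stack([XX.ravel(), YY.ravel()])
    prepped = prep(polygon)
    inside = np.fromiter(
        (prepped.covers(Point(x, y)) for x, y in cand), dtype=bool, count=len(cand)
    )
    cells = cand[inside]
    rng = np.random.default_rng(seed)
    if len(cells) < n:
        warnings.warn(
            f"only {len(cells)} grid cells inside polygon (requested {n})",
            stacklevel=2,
        )
        return cells[rng.permutation(len(cells))]
    pick = rng.choice(len(cells), size=n, replace=False)
    return cells[pick]


def haversine_km(p: np.ndarray, q: np.ndarray | None = None) -> np.ndarray:
    """Great-circle distances (km); all-pairs matrix if ``q`` is None."""
    a = np.radians(np.asarray(p, dtype=float).reshape(-1, 2))
    b = a if q is None else np.radians(np.asarray(q, dtype=float).reshape(-1, 2))
    dlon = a[:, None, 0] - b[None, :, 0]
    dlat = a[:, None, 1] - b[None, :, 1]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(a[:, None, 1]) * np.cos(b[None, :, 1]) * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def thin_points(points: np.ndarray, min_km: float = 1.5, seed: int = 0) -> np.ndarray:
    """Spatial thinning: drop points until no retained pair is closer than
    ``min_km`` (haversine).

    Greedy max-conflict removal: repeatedly delete the point with the most
    neighbors inside the exclusion radius, breaking ties at random
    (seed-controlled). Idempotent on its own output.
    """
    if min_km <= 0:
        raise ValueError("min_km must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        return pts.copy()
    D = haversine_km(pts)
    np.fill_diagonal(D, np.inf)
    conflict = D < min_km
    alive = np.ones(len(pts), dtype=bool)
    rng = np.random.default_rng(seed)
    while True:
        counts = conflict[np.ix_(alive, alive)].sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        alive_idx = np.flatnonzero(alive)
        worst = alive_idx[counts == counts.max()]
        alive[rng.choice(worst)] = False
    return pts[alive]


def species_env_summary(
    occ_sets: list[OccurrenceSet],
    grid: GridEnv,
    native_polygons: dict[str, Polygon] | None = None,
    min_records: int = 5,
    n_random: int = 20,
    thin_km: float = 1.5,
    seed: int = 0,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Per-species environmental values over cleaned, thinned points.

    Species with >= ``min_records`` occurrences use their (thinned) observed
    points; species below the threshold use ``n_random`` thinned random
    grid points inside their native polygon (or the convex hull of what
    points they have). Observed and random points are never mixed for one
    species. Species with neither enough records nor a usable polygon are
    excluded and listed in the ``excluded`` attribute of the result.
    """
    agg = {"mean": np.mean, "median": np.median}[aggregate]
    rows, excluded = [], []
    cell = max(abs(grid.dx), abs(grid.dy))
    for k, occ in enumerate(occ_sets):
        sub_seed = (seed + 104729 * (k + 1)) % (2**31)
        if len(occ) >= min_records:
            pts = thin_points(occ.points, min_km=thin_km, seed=sub_seed)
            provenance = "observed"
        else:
            poly = (native_polygons or {}).get(occ.species)
            if poly is None and len(occ) >= 1:
                poly = convex_hull(occ.points, degenerate_buffer=cell)
            if poly is None:
                excluded.append(occ.species)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rand = random_points_in_polygon(
                    poly, n=n_random, grid=grid, seed=sub_seed
                )
            if len(rand) == 0:
                excluded.append(occ.species)
                continue
            pts = thin_points(rand, min_km=thin_km, seed=sub_seed)
            provenance = "random"
        row = {"species": occ.species, "n_points": len(pts), "provenance": provenance}
        for var in grid.layers:
            row[var] = float(agg(grid.lookup(var, pts)))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


def vif(table: pd.DataFrame | np.ndarray, threshold: float = 5.0) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j) from regressing
    column j on the remaining columns (with intercept).

    Perfect collinearity is reported as inf; flagged columns (> threshold)
    are listed in the result's ``flagged`` attribute.
    """
    X = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=float)
    names = (
        list(table.columns) if isinstance(table, pd.DataFrame)
        else [f"x{j}" for j in range(X.shape[1])]
    )
    n, p = X.shape
    if p < 2:
        raise ValueError("need >= 2 columns")
    if n <= p:
        raise ValueError("need more rows than columns")
    out = []
    for j in range(p):
        y = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out.append(np.inf)
            continue
        r2 = 1 - resid @ resid / ss_tot
        out.append(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
    s = pd.Series(out, index=names, name="VIF")
    s.attrs["flagged"] = [nm for nm, v in s.items() if v > threshold]
    return s


def scale_2sd(table: pd.DataFrame, columns=None):
    """Gelman scaling: x' = (x - mean) / (2 SD), so scaled SD is 0.5.

    Binary dummies are scaled the same way, making coefficients comparable
    with those of continuous predictors. Returns (scaled table, constants)
    where constants maps column -> (mean, sd) for back-transformation.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if np.issubdtype(table[c].dtype, np.number)
    ]
    out = table.copy()
    constants = {}
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd == 0:
            raise ValueError(f"zero-variance column {c!r}")
        out[c] = (x - mu) / (2 * sd)
        constants[c] = (mu, sd)
    return out, constants


def unscale_2sd(table: pd.DataFrame, constants: dict) -> pd.DataFrame:
    out = table.copy()
    for c, (mu, sd) in constants.items():
        out[c] = table[c].to_numpy(dtype=float) * 2 * sd + mu
    return out
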