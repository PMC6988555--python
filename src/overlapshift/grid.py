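"""Lattice data model: cell geometry, depth masking, adjacency, gridded-table I/O.

Cells of a regular ``n_rows x n_cols`` grid are identified 0..N-1 in row-major
order.  Cell centers are placed on a local equirectangular layout anchored at an
origin longitude/latitude, spaced so that adjacent centers are approximately
``cell_size_km`` apart.  Only relative geometry matters downstream: the grid is
a stand-in for a projected marine survey grid (nominally 7 x 7 km), not a map
projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import xarray as xr

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "LatticeGrid",
    "Adjacency",
    "SpeciesSurface",
    "build_grid",
    "apply_depth_mask",
    "build_adjacency",
    "read_surface",
    "write_surface",
    "EARTH_RADIUS_KM",
]


@dataclass(frozen=True)
class LatticeGrid:
    """Masked regular lattice with cell-center coordinates and depths."""

    n_rows: int
    n_cols: int
    cell_size_km: float
    lon: np.ndarray          # (N,) degrees, cell centers
    lat: np.ndarray          # (N,) degrees
    depth_m: np.ndarray      # (N,) nonnegative
    active_mask: np.ndarray  # (N,) bool

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    @property
    def active_ids(self) -> np.ndarray:
        """Cell ids of active cells, ascending."""
        return np.flatnonzero(self.active_mask)

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    def rowcol(self, cell_id: np.ndarray | int):
        return np.divmod(cell_id, self.n_cols)

    def __post_init__(self):
        for name in ("lon", "lat", "depth_m", "active_mask"):
            arr = getattr(self, name)
            if arr.shape != (self.n_cells,):
                raise ValueError(f"{name} must have shape ({self.n_cells},), got {arr.shape}")
        if np.any((self.lon < -180) | (self.lon > 180)):
            raise ValueError("longitudes must lie in [-180, 180]")
        if np.any((self.lat < -90) | (self.lat > 90)):
            raise ValueError("latitudes must lie in [-90, 90]")


@dataclass(frozen=True)
class Adjacency:
    """Symmetric neighbor structure over the active cells of a grid.

    ``matrix`` is a symmetric 0/1 sparse matrix indexed by *active-cell order*
    (the order of ``grid.active_ids``); ``degrees`` is its row sums.  Cells with
    degree zero are listed in ``isolated`` (as original cell ids) — they are
    retained, not dropped, and their CAR conditional reduces to the
    heterogeneous effect.
    """

    contiguity: str
    matrix: sp.csr_matrix          # (n_active, n_active), binary, zero diagonal
    active_ids: np.ndarray         # maps active index -> cell id
    isolated: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_active(self) -> int:
        return self.matrix.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel().astype(int)

    def neighbors(self, active_index: int) -> np.ndarray:
        """Neighbor *active indices* of one active cell."""
        row = self.matrix.getrow(active_index)
        return row.indices.copy()


@dataclass(frozen=True)
class SpeciesSurface:
    """Per-active-cell density/abundance values with likelihood-family metadata."""

    grid: LatticeGrid
    values: np.ndarray            # (n_active,), nonnegative
    family: str                   # "gamma" | "hurdle-gamma"
    scenario: str = "present"     # "present" | "future"
    season: str = "summer"
    name: str = "species"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_active,):
            raise ValueError(
                f"values length {v.shape} does not match {self.grid.n_active} active cells"
            )
        if np.any(~np.isfinite(v)):
            raise ValueError("surface values must be finite")
        if np.any(v < 0):
            bad = self.grid.active_ids[np.flatnonzero(v < 0)[0]]
            raise ValueError(f"negative density at cell {bad}")
        if self.family not in ("gamma", "hurdle-gamma"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "gamma" and np.any(v == 0):
            raise ValueError("family 'gamma' requires strictly positive values; "
                             "use 'hurdle-gamma' for data with exact zeros")
        object.__setattr__(self, "values", v)

    @property
    def zero_fraction(self) -> float:
        return float(np.mean(self.values == 0.0))


def build_grid(n_rows: int, n_cols: int, origin_lonlat=(0.0, 56.0),
               cell_size_km: float = 7.0, depth_field=None) -> LatticeGrid:
    """Build a fully active regular lattice.

    Centers are laid out equirectangularly around ``origin_lonlat`` so that
    rook-adjacent centers are approximately ``cell_size_km`` apart (exact in
    latitude; in longitude exact at the origin latitude).
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid needs n_rows >= 2 and n_cols >= 2")
    if cell_size_km <= 0:
        raise ValueError("cell_size_km must be positive")
    n = n_rows * n_cols
    if depth_field is None:
        depth_field = np.full(n, 100.0)
    depth_field = np.asarray(depth_field, dtype=float)
    if depth_field.shape != (n,):
        raise ValueError(f"depth_field must have length {n}")
    if np.any(np.isnan(depth_field)):
        bad = int(np.flatnonzero(np.isnan(depth_field))[0])
        raise ValueError(f"NaN depth at cell {bad}")
    if np.any(depth_field < 0):
        bad = int(np.flatnonzero(depth_field < 0)[0])
        raise ValueError(f"negative depth at cell {bad}")

    lon0, lat0 = origin_lonlat
    dlat = cell_size_km / EARTH_RADIUS_KM * 180.0 / np.pi
    dlon = dlat / np.cos(np.deg2rad(lat0))
    rows, cols = np.divmod(np.arange(n), n_cols)
    lat = lat0 + rows * dlat
    lon = lon0 + cols * dlon
    return LatticeGrid(
        n_rows=n_rows, n_cols=n_cols, cell_size_km=float(cell_size_km),
        lon=lon, lat=lat, depth_m=depth_field,
        active_mask=np.ones(n, dtype=bool),
    )


def apply_depth_mask(grid: LatticeGrid, max_depth_m: float = 500.0) -> LatticeGrid:
    """Deactivate cells deeper than ``max_depth_m`` (strictly greater).

    Idempotent.  Raises if no active cell would remain.
    """
    remove = grid.active_mask & (grid.depth_m > max_depth_m)
    new_mask = grid.active_mask & ~remove
    if not new_mask.any():
        raise ValueError(f"depth mask at {max_depth_m} m removed every cell")
    n_removed = int(remove.sum())
    if n_removed:
        logger.info("depth mask >%g m removed %d of %d cells",
                    max_depth_m, n_removed, int(grid.active_mask.sum()))
    return replace(grid, active_mask=new_mask)


def _lattice_offsets(contiguity: str):
    rook = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    diag = [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    if contiguity == "rook":
        return rook
    if contiguity == "queen":
        return rook + diag
    raise ValueError(f"unknown contiguity {contiguity!r}; use 'rook' or 'queen'")


def build_adjacency(grid: LatticeGrid, contiguity: str = "queen") -> Adjacency:
    """Symmetric binary adjacency among active cells only."""
    offsets = _lattice_offsets(contiguity)
    active_ids = grid.active_ids
    if active_ids.size == 0:
        raise ValueError("grid has no active cells")
    pos = -np.ones(grid.n_cells, dtype=int)
    pos[active_ids] = np.arange(active_ids.size)
    rows_i, cols_i = grid.rowcol(active_ids)
    src, dst = [], []
    for dr, dc in offsets:
        rr, cc = rows_i + dr, cols_i + dc
        ok = (rr >= 0) & (rr < grid.n_rows) & (cc >= 0) & (cc < grid.n_cols)
        nbr_id = rr[ok] * grid.n_cols + cc[ok]
        nbr_pos = pos[nbr_id]
        sel = nbr_pos >= 0
        src.append(np.flatnonzero(ok)[sel])
        dst.append(nbr_pos[sel])
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    mat = sp.csr_matrix(
        (np.ones(src.size), (src, dst)), shape=(active_ids.size, active_ids.size)
    )
    mat.data[:] = 1.0  # guard against duplicates
    degrees = np.asarray(mat.sum(axis=1)).ravel()
    isolated = active_ids[degrees == 0]
    if isolated.size:
        logger.warning("%d isolated active cells (degree 0): %s",
                       isolated.size, isolated.tolist())
    return Adjacency(contiguity=contiguity, matrix=mat,
                     active_ids=active_ids, isolated=isolated)


# ---------------------------------------------------------------------------
# I/O: CSV grid tables and NetCDF gridded arrays
# ---------------------------------------------------------------------------

def surface_to_frame(surface: SpeciesSurface) -> pd.DataFrame:
    g = surface.grid
    ids = g.active_ids
    return pd.DataFrame({
        "cell_id": ids,
        "lon": g.lon[ids],
        "lat": g.lat[ids],
        "depth_m": g.depth_m[ids],
        "value": surface.values,
    })


def write_surface(surface: SpeciesSurface, path) -> None:
    """Write a surface as a CSV grid table or a NetCDF gridded array.

    CSV carries full float precision (round-trips bit-exactly); the format is
    chosen from the file suffix (``.nc`` for NetCDF, anything else CSV).
    """
    path = str(path)
    if path.endswith(".nc"):
        _write_surface_netcdf(surface, path)
        return
    df = surface_to_frame(surface)
    df.to_csv(path, index=False, float_format="%.17g")


def read_surface(path, grid: LatticeGrid, family: str = "gamma",
                 scenario: str = "present", season: str = "summer",
                 name: str = "species") -> SpeciesSurface:
    """Read a per-cell value table back onto ``grid``'s active cells."""
    path = str(path)
    if path.endswith(".nc"):
        values = _read_surface_netcdf(path, grid)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"cell_id", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"surface table needs columns {sorted(required)}")
        ids = df["cell_id"].to_numpy()
        known = set(grid.active_ids.tolist())
        unknown = [int(i) for i in ids if int(i) not in known]
        if unknown:
            raise ValueError(f"unknown or inactive cell ids in file: {unknown[:5]}")
        if len(ids) != grid.n_active:
            raise ValueError(
                f"file has {len(ids)} cells but grid has {grid.n_active} active cells"
            )
        order = np.argsort(ids)
        values = df["value"].to_numpy(dtype=float)[order]
    neg = np.flatnonzero(values < 0)
    if neg.size:
        raise ValueError(f"negative density at cell {int(grid.active_ids[neg[0]])}")
    if family == "gamma" and np.any(values == 0):
        family = "hurdle-gamma"
    return SpeciesSurface(grid=grid, values=values, family=family,
                          scenario=scenario, season=season, name=name)


def _write_surface_netcdf(surface: SpeciesSurface, path: str) -> None:
    g = surface.grid
    full = np.full(g.n_cells, np.nan)
    full[g.active_ids] = surface.values
    shape = (g.n_rows, g.n_cols)
    ds = xr.Dataset(
        {
            "value": (("row", "col"), full.reshape(shape)),
            "depth": (("row", "col"), g.depth_m.reshape(shape)),
        },
        coords={
            "lon": (("row", "col"), g.lon.reshape(shape)),
            "lat": (("row", "col"), g.lat.reshape(shape)),
        },
        attrs={"scenario": surface.scenario, "season": surface.season,
               "family": surface.family, "name": surface.name},
    )
    ds.to_netcdf(path, engine="scipy")


def _read_surface_netcdf(path: str, grid: LatticeGrid) -> np.ndarray:
    with xr.open_dataset(path, engine="scipy") as ds:
        full = ds["value"].values.reshape(-1)
    if full.size != grid.n_cells:
        raise ValueError(
            f"NetCDF grid has {full.size} cells but grid has {grid.n_cells}"
        )
    values = full[grid.active_ids]
    if np.any(np.isnan(values)):
        raise ValueError("NaN values at active cells in NetCDF surface")
    return values
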