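"""Regular lat/lon grids and point-to-cell lookup.

All grids are cell-center registered: ``lat0``/``lon0`` are the coordinates
of the *center* of the first (south-west) cell, latitudes are stored
ascending and longitudes normalized to [-180, 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


class OutOfDomainError(ValueError):
    """A point falls outside the grid's bounding box (cell edges)."""


def normalize_lon(lon):
    """Map longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class GridSpec:
    """A regular latitude/longitude grid, cell-center registered.

    Parameters
    ----------
    lat0, lon0 : float
        Center coordinates of the first cell, in degrees.  Latitudes run
        ascending from ``lat0``; longitudes eastward from ``lon0``.
    dlat, dlon : float
        Cell sizes in degrees, strictly positive.
    nlat, nlon : int
        Number of cells along each axis.
    """

    lat0: float
    lon0: float
    dlat: float
    dlon: float
    nlat: int
    nlon: int

    def __post_init__(self):
        if self.dlat <= 0 or self.dlon <= 0:
            raise ValueError("cell sizes must be positive")
        if self.nlat < 1 or self.nlon < 1:
            raise ValueError("grid must have at least one cell")
        lat_top = self.lat0 + (self.nlat - 1) * self.dlat
        if not (-90.0 < self.lat0 and lat_top < 90.0):
            raise ValueError("cell-center latitudes must lie strictly within (-90, 90)")
        object.__setattr__(self, "lon0", float(normalize_lon(self.lon0)))

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.dlat * np.arange(self.nlat)

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.dlon * np.arange(self.nlon)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def ncells(self) -> int:
        return self.nlat * self.nlon

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) arrays of shape (nlat, nlon) with every cell center."""
        la, lo = np.meshgrid(self.lats, self.lons, indexing="ij")
        return la, lo

    def is_multiple_of(self, fine: "GridSpec") -> bool:
        """True if this (coarser) grid's cells tile an integer block of ``fine`` cells."""
        ry = self.dlat / fine.dlat
        rx = self.dlon / fine.dlon
        return abs(ry - round(ry)) < 1e-9 and abs(rx - round(rx)) < 1e-9


def _axis_index(x: float, x0: float, dx: float, n: int) -> int:
    """Nearest cell index along one axis; exact edge ties go to the lower index."""
    f = (x - x0) / dx
    if f < -0.5 or f > n - 0.5:
        raise OutOfDomainError(f"coordinate {x} outside grid axis")
    i = int(np.floor(f + 0.5))
    # a point exactly on the shared edge between i-1 and i has f + 0.5 == i
    if f + 0.5 == i and i > 0:
        i -= 1
    return min(max(i, 0), n - 1)


def locate_cell(grid: GridSpec, lon: float, lat: float) -> tuple[int, int]:
    """Index pair (ilat, ilon) of the grid cell containing / nearest to a point.

    Points exactly on the boundary between two cells assign to the lower
    index; points outside the grid's outer cell edges raise
    :class:`OutOfDomainError`.
    """
    lon = float(normalize_lon(lon))
    ilat = _axis_index(float(lat), grid.lat0, grid.dlat, grid.nlat)
    ilon = _axis_index(lon, grid.lon0, grid.dlon, grid.nlon)
    return ilat, ilon


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def block_reduce_mean(values: np.ndarray, by: int, bx: int) -> np.ndarray:
    """Mean over non-overlapping (by, bx) blocks of the trailing two axes."""
    *lead, ny, nx = values.shape
    if ny % by or nx % bx:
        raise ValueError("array axes are not integer multiples of the block size")
    v = values.reshape(*lead, ny // by, by, nx // bx, bx)
    return v.mean(axis=(-3, -1))


def coarsen_grid(fine: GridSpec, by: int, bx: int) -> GridSpec:
    """GridSpec of the coarse grid whose cells are (by, bx) blocks of fine cells."""
    if fine.nlat % by or fine.nlon % bx:
        raise ValueError("block size does not tile the fine grid")
    return GridSpec(
        lat0=fine.lat0 + fine.dlat * (by - 1) / 2.0,
        lon0=fine.lon0 + fine.dlon * (bx - 1) / 2.0,
        dlat=fine.dlat * by,
        dlon=fine.dlon * bx,
        nlat=fine.nlat // by,
        nlon=fine.nlon // bx,
    )
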