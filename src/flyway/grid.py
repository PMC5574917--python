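"""Lattice geometry shared by every gridded field.

The model world is a regular latitude-longitude lattice covering the globe.
Row 0 is the northernmost row and column 0 the westernmost column; cell
centres sit at ``lat = lat0 - i*cell_deg`` and ``lon = lon0 + j*cell_deg``.
Columns are periodic (the lattice wraps across the antimeridian); rows are
not -- there is nothing beyond the first and last row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: Offsets of the 8 lattice neighbours, clockwise from due north.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0),   # N
    (-1, 1),   # NE
    (0, 1),    # E
    (1, 1),    # SE
    (1, 0),    # S
    (1, -1),   # SW
    (0, -1),   # W
    (-1, -1),  # NW
)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance between points given in degrees, in km.

    Vectorised: accepts scalars or broadcastable arrays.
    """
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    # clip guards against roundoff pushing h just above 1 for antipodes
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a global lat/lon lattice.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions (latitude x longitude).
    cell_deg
        Cell size in degrees (cells are square in degrees).
    lat0, lon0
        Centre of cell (0, 0).  Defaults follow the common satellite-product
        layout: northernmost/westernmost cell centred half a cell in from
        the +90 / -180 edge.
    """

    n_rows: int
    n_cols: int
    cell_deg: float
    lat0: float = field(default=None)  # type: ignore[assignment]
    lon0: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.lat0 is None:
            object.__setattr__(self, "lat0", 90.0 - self.cell_deg / 2.0)
        if self.lon0 is None:
            object.__setattr__(self, "lon0", -180.0 + self.cell_deg / 2.0)
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not np.isclose(self.n_cols * self.cell_deg, 360.0):
            raise ValueError("n_cols * cell_deg must equal 360 (global, periodic)")
        if self.n_rows * self.cell_deg > 180.0 + 1e-9:
            raise ValueError("n_rows * cell_deg must not exceed 180")
        lats = self.lat_centers()
        if lats.max() > 90.0 + 1e-9 or lats.min() < -90.0 - 1e-9:
            raise ValueError("cell-centre latitudes must lie in [-90, 90]")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat(self, row) -> np.ndarray | float:
        return self.lat0 - np.asarray(row, dtype=float) * self.cell_deg

    def lon(self, col) -> np.ndarray | float:
        lon = self.lon0 + np.asarray(col, dtype=float) * self.cell_deg
        return (lon + 180.0) % 360.0 - 180.0

    def lat_centers(self) -> np.ndarray:
        return self.lat(np.arange(self.n_rows))

    def lon_centers(self) -> np.ndarray:
        return self.lon(np.arange(self.n_cols))

    def cell_center(self, cell: tuple[int, int]) -> tuple[float, float]:
        """(lat, lon) of a cell centre."""
        row, col = cell
        if not self.in_bounds(cell):
            raise ValueError(f"cell {cell} outside grid {self.shape}")
        return float(self.lat(row)), float(self.lon(col))

    def in_bounds(self, cell: tuple[int, int]) -> bool:
        row, col = cell
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def wrap_col(self, col: int) -> int:
        return col % self.n_cols

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Cell whose centre is nearest to (lat, lon)."""
        row = int(np.clip(round((self.lat0 - lat) / self.cell_deg), 0, self.n_rows - 1))
        col = self.wrap_col(int(round(((lon - self.lon0) % 360.0) / self.cell_deg)))
        return row, col

    def neighbors(self, cell: tuple[int, int]) -> list[tuple[int, int]]:
        """The 8 surrounding cells in NEIGHBOR_OFFSETS order.

        Columns wrap across the antimeridian.  Rows beyond the first or last
        row are returned unwrapped (out of bounds) so the caller can flag
        them as not permitted; latitude never wraps.
        """
        row, col = cell
        out = []
        for dr, dc in NEIGHBOR_OFFSETS:
            r = row + dr
            c = self.wrap_col(col + dc)
            out.append((r, c))
        return out

    def are_adjacent(self, a: tuple[int, int], b: tuple[int, int]) -> bool:
        """True when b is one of a's 8 neighbours under longitude wrap."""
        dr = b[0] - a[0]
        dc = (b[1] - a[1]) % self.n_cols
        if dc > self.n_cols // 2:
            dc -= self.n_cols
        return (dr, dc) != (0, 0) and abs(dr) <= 1 and abs(dc) <= 1


def great_circle_distance(cell_a: tuple[int, int], cell_b: tuple[int, int],
                          grid: GridSpec) -> float:
    """Haversine distance in km between two cell centres (sphere R=6371 km)."""
    lat_a, lon_a = grid.cell_center(cell_a)
    lat_b, lon_b = grid.cell_center(cell_b)
    return float(haversine_km(lat_a, lon_a, lat_b, lon_b))
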