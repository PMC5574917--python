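"""The environmental potential landscape.

Each unit of resource concentration acts like a unit of charge or mass
producing an attractive potential that decays as 1/r, so the resource
potential at lattice point (i, j) is

    phi_ij = - sum_{(k,l) != (i,j)} C_kl / r_ij,kl

with r the great-circle distance between cell centres in km (sphere radius
6371 km).  Wind is rotational, so it has no global scalar potential; instead
it tilts the landscape locally around the current cell (x, y): for a move to
neighbour (i, j),

    chi_ij = -|w_xy| (w_xy . dx_hat)

where dx_hat is the unit displacement in the spherical surface geometry
(zonal component scaled by cos latitude).  Drag grows with |w|^2, hence the
extra |w| factor: downwind moves are energetically downhill, upwind moves
uphill, crosswind moves flat.  The combined landscape seen from (x, y) is

    Psi_ij = phi_ij + a * chi_ij

with a the wind-weighting parameter.  Units: phi in mg m^-3 km^-1, chi in
m^2 s^-2; a absorbs the conversion, so its numerical value is tied to this
convention (km distances, m s^-1 winds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import MonthlyEnvironment, OceanMask, ScalarField, WindField
from .grid import NEIGHBOR_OFFSETS, GridSpec, great_circle_distance, haversine_km

__all__ = [
    "ModelParams", "LocalPotential", "PotentialCache",
    "resource_potential", "spherical_displacement", "wind_potential",
    "local_potential", "great_circle_distance",
]


@dataclass(frozen=True)
class ModelParams:
    """The model's free parameters.

    a
        Weight of the wind tilt relative to resource attraction
        (dimensionless in this package's unit convention); a >= 0.
    kT
        Movement-randomness temperature; move probabilities are Boltzmann
        with beta = 1/kT.  Low kT approaches greedy descent, high kT a
        uniform random walk.
    airspeed
        Typical airspeed in km/h used for the step clock (default 60).
    """

    a: float
    kT: float
    airspeed: float = 60.0

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("a must be >= 0")
        if self.kT <= 0:
            raise ValueError("kT must be > 0")
        if self.airspeed <= 0:
            raise ValueError("airspeed must be > 0")


@dataclass
class LocalPotential:
    """The landscape seen from one cell: Psi at each of the 8 neighbours.

    Not-permitted neighbours (land, or beyond the first/last row) carry
    phi = psi = +inf and chi = 0 so that psi == phi + a*chi holds element-wise
    while no probability can ever leak onto them.
    """

    centre: tuple[int, int]
    neighbour_cells: list[tuple[int, int]]
    phi: np.ndarray
    chi: np.ndarray
    psi: np.ndarray
    permitted: np.ndarray


def _masked_values(field: ScalarField, mask: OceanMask) -> np.ndarray:
    """Validate that land carries no resource; return values with gaps as 0."""
    values = field.values
    land = values[~mask.is_ocean]
    land = land[np.isfinite(land)]
    if land.size and (land != 0).any():
        raise ValueError("field has resource on land cells; apply_ocean_mask first")
    return np.nan_to_num(values, nan=0.0)


def resource_potential(field: ScalarField, mask: OceanMask,
                       target: tuple[int, int]) -> float:
    """Resource-attraction potential phi at one cell: -sum C_kl / r (km).

    The sum runs over every cell with positive concentration except the
    target itself; zero and missing cells contribute nothing.  phi <= 0, and
    more resource nearby makes it more negative.
    """
    if field.grid != mask.grid:
        raise ValueError("field and mask grids differ")
    if not field.grid.in_bounds(target):
        raise ValueError(f"target {target} outside grid")
    values = _masked_values(field, mask)
    return _phi_from_values(values, field.grid, target)


def _phi_from_values(values: np.ndarray, grid: GridSpec,
                     target: tuple[int, int]) -> float:
    rows, cols = np.nonzero(values > 0)
    if rows.size == 0:
        return 0.0
    self_hit = (rows == target[0]) & (cols == target[1])
    if self_hit.any():
        keep = ~self_hit
        rows, cols = rows[keep], cols[keep]
        if rows.size == 0:
            return 0.0
    lat_t, lon_t = grid.cell_center(target)
    r = haversine_km(lat_t, lon_t, grid.lat(rows), grid.lon(cols))
    return float(-np.sum(values[rows, cols] / r))


class PotentialCache:
    """Per-(month, cell) memoisation of the resource potential phi.

    The global sum is O(N) per cell, so a full-grid precompute would be
    O(N^2); instead phi is computed on demand around the positions birds
    actually visit and memoised.  phi depends only on the month's resource
    field, never on (a, kT), so one cache serves a whole parameter sweep.
    Memoisation is transparent: cached and fresh values are identical.
    """

    def __init__(self):
        self._phi: dict[tuple[int, int, int], float] = {}
        self._values: dict[int, np.ndarray] = {}

    def phi(self, env: MonthlyEnvironment, cell: tuple[int, int]) -> float:
        key = (env.month, cell[0], cell[1])
        try:
            return self._phi[key]
        except KeyError:
            pass
        values = self._values.get(env.month)
        if values is None:
            values = _masked_values(env.resource, env.mask)
            self._values[env.month] = values
        val = _phi_from_values(values, env.grid, cell)
        self._phi[key] = val
        return val


def spherical_displacement(centre: tuple[int, int], neighbour: tuple[int, int],
                           grid: GridSpec) -> np.ndarray:
    """Unit displacement (zonal, meridional) of a move, on the sphere.

    The wind vector lives on the spherical surface, so the displacement it is
    dotted with must too: the zonal component is the longitude difference
    scaled by cos of the mean latitude of the two cells, the meridional
    component the latitude difference.  Their relative lengths therefore vary
    across the globe -- a diagonal move near the pole is almost meridional.
    """
    if not grid.are_adjacent(centre, neighbour):
        raise ValueError(f"{neighbour} is not adjacent to {centre}")
    dlat = (centre[0] - neighbour[0]) * grid.cell_deg  # row 0 is northernmost
    dlon = (neighbour[1] - centre[1]) % grid.n_cols
    if dlon > grid.n_cols // 2:
        dlon -= grid.n_cols
    dlon *= grid.cell_deg
    mean_lat = 0.5 * (grid.lat(centre[0]) + grid.lat(neighbour[0]))
    zonal = dlon * np.cos(np.radians(mean_lat))
    meridional = dlat
    vec = np.array([zonal, meridional], dtype=float)
    norm = np.hypot(*vec)
    if norm == 0.0:
        raise ValueError("degenerate displacement (coincident cell centres)")
    return vec / norm


def wind_potential(wind: WindField, centre: tuple[int, int],
                   neighbour: tuple[int, int], grid: GridSpec) -> float:
    """Local wind tilt chi = -|w_xy| (w_xy . dx_hat) for one move.

    Wind is sampled at the *current* cell (x, y).  Negative (downhill) when
    moving downwind, positive upwind, exactly zero perpendicular to the wind.
    Scaling the wind by s scales chi by s^2 (drag grows with |w|^2).
    """
    w = np.array([wind.u[centre], wind.v[centre]], dtype=float)
    dx_hat = spherical_displacement(centre, neighbour, grid)
    speed = np.hypot(*w)
    return float(-speed * np.dot(w, dx_hat))


def local_potential(env: MonthlyEnvironment, centre: tuple[int, int],
                    params: ModelParams,
                    cache: PotentialCache | None = None) -> LocalPotential:
    """Psi = phi + a*chi at the 8 neighbours of an ocean cell.

    Land neighbours and rows beyond the lattice edge are flagged not
    permitted; their psi is +inf so they can never receive probability.
    """
    grid = env.grid
    if not grid.in_bounds(centre) or not env.mask.is_ocean[centre]:
        raise ValueError(f"centre {centre} is not an ocean cell")
    if cache is None:
        cache = PotentialCache()
    cells = grid.neighbors(centre)
    n = len(NEIGHBOR_OFFSETS)
    phi = np.full(n, np.inf)
    chi = np.zeros(n)
    psi = np.full(n, np.inf)
    permitted = np.zeros(n, dtype=bool)
    for k, cell in enumerate(cells):
        if not grid.in_bounds(cell) or not env.mask.is_ocean[cell]:
            continue
        permitted[k] = True
        phi[k] = cache.phi(env, cell)
        chi[k] = wind_potential(env.wind, centre, cell, grid)
        psi[k] = phi[k] + params.a * chi[k]
    return LocalPotential(centre, cells, phi, chi, psi, permitted)
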