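"""Full simulations: single birds, colony ensembles, parameter sweeps.

A run starts at the ocean cell nearest a breeding colony and iterates the
movement rule through the non-breeding window (April-July by default),
switching the monthly environment as simulated time passes.  Ensembles
aggregate per-cell occupancy (every visit) and endpoint (final position)
densities; parameter sweeps cover an (a, kT) grid with deterministic
per-bird seeding so any subset of the sweep is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .environment import MonthlyEnvironment, OceanMask, write_csv_grid
from .grid import GridSpec, haversine_km
from .movement import BirdState, MonthCalendar, advance
from .potential import ModelParams, PotentialCache

__all__ = [
    "Colony", "Trajectory", "TrajectoryStep", "EnsembleResult", "COLONIES",
    "snap_to_ocean", "simulate_bird", "simulate_ensemble", "sweep_parameters",
    "directional_split", "default_a_grid", "default_kt_grid",
    "trajectories_to_dataframe", "write_trajectories_csv",
    "write_trajectories_geojson", "write_density_csv", "write_run_metadata",
]

#: Default sweep grid: a in 0.001..0.008 step 0.001, kT in 0.05..0.2 step 0.05.
def default_a_grid() -> list[float]:
    return [round(0.001 * k, 3) for k in range(1, 9)]


def default_kt_grid() -> list[float]:
    return [round(0.05 * k, 2) for k in range(1, 5)]


DEFAULT_N_BIRDS = 16
SWEEP_PAIR_STRIDE = 10 ** 6  # seed(pair p, bird b) = base + p*stride + b


@dataclass(frozen=True)
class Colony:
    """A breeding colony: a name and its (lat, lon) in degrees."""

    name: str
    lat: float
    lon: float

    def __post_init__(self):
        if abs(self.lat) > 90 or abs(self.lon) > 180:
            raise ValueError("colony coordinates out of range")


#: Black-browed albatross colonies with documented non-breeding movements.
#: Campbell Island, the Crozet Islands and Islas Diego de Almagro are also of
#: interest but their coordinates must be supplied by the user.
COLONIES: dict[str, Colony] = {
    c.name: c for c in (
        Colony("diego-ramirez", -56.5, -68.7),
        Colony("falklands", -51.0, -61.1),
        Colony("kerguelen", -49.4, 70.0),
        Colony("macquarie", -54.5, 158.9),
        Colony("south-georgia", -54.2, -36.5),
    )
}


class TrajectoryStep(NamedTuple):
    row: int
    col: int
    clock_h: float
    month: int


@dataclass
class Trajectory:
    """One simulated bird's time-stamped cell sequence."""

    bird_id: int
    colony: Colony
    params: ModelParams
    seed: int
    steps: list[TrajectoryStep]

    @property
    def start(self) -> tuple[int, int]:
        return (self.steps[0].row, self.steps[0].col)

    @property
    def end(self) -> tuple[int, int]:
        return (self.steps[-1].row, self.steps[-1].col)


@dataclass
class EnsembleResult:
    """Trajectories plus occupancy/endpoint densities for one (colony, params) run."""

    colony: Colony
    params: ModelParams
    grid: GridSpec
    trajectories: list[Trajectory]
    occupancy: np.ndarray = field(init=False)
    endpoints: np.ndarray = field(init=False)

    def __post_init__(self):
        occ = np.zeros(self.grid.shape, dtype=np.int64)
        end = np.zeros(self.grid.shape, dtype=np.int64)
        for traj in self.trajectories:
            for s in traj.steps:
                occ[s.row, s.col] += 1
            end[traj.end] += 1
        self.occupancy = occ
        self.endpoints = end


def snap_to_ocean(colony: Colony, mask: OceanMask) -> tuple[int, int]:
    """Ocean cell whose centre is nearest the colony (colonies sit on land).

    Ties are broken toward the smallest (row, col) so the choice is
    deterministic.
    """
    grid = mask.grid
    rows, cols = np.nonzero(mask.is_ocean)
    d = haversine_km(colony.lat, colony.lon, grid.lat(rows), grid.lon(cols))
    best = np.flatnonzero(d == d.min())
    # lexicographic (row, col) among exact ties
    order = np.lexsort((cols[best], rows[best]))
    k = best[order[0]]
    return int(rows[k]), int(cols[k])


def _env_mapping(envs, start_month: int, duration_months: int,
                 ) -> Mapping[int, MonthlyEnvironment]:
    if isinstance(envs, Mapping):
        mapping = dict(envs)
    else:
        mapping = {e.month: e for e in envs}
    needed = [(start_month - 1 + k) % 12 + 1 for k in range(duration_months)]
    missing = [m for m in needed if m not in mapping]
    if missing:
        raise ValueError(f"environment missing for month(s) {missing}")
    return mapping


def simulate_bird(colony: Colony, params: ModelParams, envs,
                  start_month: int = 4, duration_months: int = 4,
                  seed: int = 0, bird_id: int = 0,
                  cache: PotentialCache | None = None) -> Trajectory:
    """Simulate one bird from its colony through the run window.

    The bird starts at the ocean cell nearest the colony and iterates until
    the clock reaches the end of the window; the final step is executed in
    full even if it overshoots the end time.  Deterministic for a fixed seed.
    """
    mapping = _env_mapping(envs, start_month, duration_months)
    calendar = MonthCalendar(start_month, duration_months)
    first_env = mapping[start_month] if duration_months else next(iter(mapping.values()))
    start_cell = snap_to_ocean(colony, first_env.mask)
    state = BirdState(cell=start_cell, clock=0.0, month=start_month)
    steps = [TrajectoryStep(*state.cell, state.clock, state.month)]
    if cache is None:
        cache = PotentialCache()
    rng = np.random.default_rng(seed)
    while state.clock < calendar.total_hours:
        state = advance(state, mapping, params, rng, calendar, cache)
        steps.append(TrajectoryStep(*state.cell, state.clock, state.month))
    return Trajectory(bird_id, colony, params, seed, steps)


def simulate_ensemble(colony: Colony, params: ModelParams, envs,
                      n_birds: int = DEFAULT_N_BIRDS, base_seed: int = 0,
                      start_month: int = 4, duration_months: int = 4,
                      cache: PotentialCache | None = None) -> EnsembleResult:
    """n_birds independent trajectories (seeds base_seed + bird index)."""
    if n_birds < 1:
        raise ValueError("n_birds must be >= 1")
    mapping = _env_mapping(envs, start_month, duration_months)
    if cache is None:
        cache = PotentialCache()
    grid = next(iter(mapping.values())).grid
    trajectories = [
        simulate_bird(colony, params, mapping, start_month, duration_months,
                      seed=base_seed + b, bird_id=b, cache=cache)
        for b in range(n_birds)
    ]
    return EnsembleResult(colony, params, grid, trajectories)


def sweep_parameters(colony: Colony, a_values: Sequence[float] | None = None,
                     kT_values: Sequence[float] | None = None, envs=None,
                     n_birds: int = DEFAULT_N_BIRDS, base_seed: int = 0,
                     start_month: int = 4, duration_months: int = 4,
                     airspeed: float = 60.0) -> list[EnsembleResult]:
    """One ensemble per (a, kT) pair over the full parameter grid.

    Pairs are enumerated a-major; seed(pair p, bird b) = base_seed +
    p * 10^6 + b, so adding pairs or birds never perturbs existing runs.
    The phi cache is shared across pairs (phi does not depend on a or kT).
    """
    if a_values is None:
        a_values = default_a_grid()
    if kT_values is None:
        kT_values = default_kt_grid()
    if not a_values or not kT_values:
        raise ValueError("parameter value lists must be non-empty")
    cache = PotentialCache()
    results = []
    for p, (a, kT) in enumerate((a, kT) for a in a_values for kT in kT_values):
        params = ModelParams(a=a, kT=kT, airspeed=airspeed)
        results.append(simulate_ensemble(
            colony, params, envs, n_birds=n_birds,
            base_seed=base_seed + p * SWEEP_PAIR_STRIDE,
            start_month=start_month, duration_months=duration_months,
            cache=cache))
    return results


def directional_split(result: EnsembleResult,
                      meridian: float | None = None) -> tuple[float, float]:
    """Fractions of final positions east/west of a meridian.

    Defaults to the meridian through the ensemble's start cell.  East/west is
    judged along the shorter arc; a bird exactly on the meridian counts as
    east (as does the antipodal degenerate case).
    """
    if not result.trajectories:
        raise ValueError("empty ensemble")
    grid = result.grid
    if meridian is None:
        meridian = grid.lon(result.trajectories[0].start[1])
    n_east = 0
    for traj in result.trajectories:
        lon_end = grid.lon(traj.end[1])
        delta = (lon_end - meridian + 180.0) % 360.0 - 180.0  # (-180, 180]
        if delta == -180.0:
            delta = 180.0
        if delta >= 0.0:
            n_east += 1
    n = len(result.trajectories)
    return n_east / n, (n - n_east) / n


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def trajectories_to_dataframe(trajectories: Sequence[Trajectory],
                              grid: GridSpec) -> pd.DataFrame:
    records = []
    for traj in trajectories:
        for k, s in enumerate(traj.steps):
            records.append((traj.bird_id, k, s.clock_h, s.month, s.row, s.col,
                            float(grid.lat(s.row)), float(grid.lon(s.col))))
    return pd.DataFrame.from_records(
        records,
        columns=["bird_id", "step", "clock_h", "month", "row", "col",
                 "lat", "lon"])


def write_trajectories_csv(path, trajectories: Sequence[Trajectory],
                           grid: GridSpec) -> None:
    trajectories_to_dataframe(trajectories, grid).to_csv(path, index=False)


def write_trajectories_geojson(path, trajectories: Sequence[Trajectory],
                               grid: GridSpec) -> None:
    """One (Multi)LineString feature per bird, segments split at the dateline."""
    features = []
    for traj in trajectories:
        coords = [[float(grid.lon(s.col)), float(grid.lat(s.row))]
                  for s in traj.steps]
        segments, current = [], [coords[0]]
        for prev, here in zip(coords, coords[1:]):
            if abs(here[0] - prev[0]) > 180.0:  # crossed the antimeridian
                segments.append(current)
                current = [here]
            else:
                current.append(here)
        segments.append(current)
        segments = [s for s in segments if len(s) >= 2]
        if not segments:
            continue
        if len(segments) == 1:
            geometry = {"type": "LineString", "coordinates": segments[0]}
        else:
            geometry = {"type": "MultiLineString", "coordinates": segments}
        features.append({"type": "Feature",
                         "properties": {"bird_id": traj.bird_id,
                                        "colony": traj.colony.name,
                                        "seed": traj.seed},
                         "geometry": geometry})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_density_csv(path, result: EnsembleResult, which: str = "occupancy",
                      month: int = 0) -> None:
    density = getattr(result, which)
    write_csv_grid(path, result.grid, month, density.astype(float))


def write_run_metadata(path, result: EnsembleResult, base_seed: int,
                       extra: dict | None = None) -> None:
    meta = {
        "colony": {"name": result.colony.name, "lat": result.colony.lat,
                   "lon": result.colony.lon},
        "params": {"a": result.params.a, "kT": result.params.kT,
                   "airspeed_kmh": result.params.airspeed},
        "n_birds": len(result.trajectories),
        "base_seed": base_seed,
        "seeds": [t.seed for t in result.trajectories],
        "grid": {"n_rows": result.grid.n_rows, "n_cols": result.grid.n_cols,
                 "cell_deg": result.grid.cell_deg, "lat0": result.grid.lat0,
                 "lon0": result.grid.lon0,
                 "convention": "row 0 northernmost, col 0 westernmost, "
                               "cell centres"},
        "software": "flyway 0.1.0",
    }
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
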