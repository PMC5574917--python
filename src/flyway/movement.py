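"""Stochastic movement rules: Boltzmann move probabilities and the step clock.

From its current cell a bird can move to any of the 8 surrounding lattice
points -- never stay put, never onto land.  Treating the neighbours as energy
states with energies Psi, the move probabilities follow Maxwell-Boltzmann
statistics:

    P(i, j) = exp(-Psi_ij / kT) / sum_kl exp(-Psi_kl / kT)

over permitted neighbours only.  The weights are computed after subtracting
the minimum Psi among permitted neighbours, which leaves the distribution
unchanged but keeps the exponentials finite for arbitrarily large |Psi|.

After each move the clock advances by the travel time: great-circle step
length divided by ground speed, where ground speed combines the typical
airspeed with the tailwind component of the wind at the departure cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .environment import MonthlyEnvironment, WindField
from .grid import GridSpec, great_circle_distance
from .potential import (LocalPotential, ModelParams, PotentialCache,
                        local_potential, spherical_displacement)

__all__ = [
    "BirdState", "MoveDistribution", "MonthCalendar", "DeadEndError",
    "move_probabilities", "sample_move", "step_duration", "advance",
]

MS_TO_KMH = 3.6
#: Ground speed is floored at this fraction of airspeed so every step,
#: however strong the headwind, takes finite time.
SPEED_FLOOR_FRACTION = 0.1

_DAYS_PER_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


class DeadEndError(RuntimeError):
    """No permitted neighbour to move to (unreachable from legal states)."""


@dataclass(frozen=True)
class BirdState:
    """A bird's position on the lattice, elapsed time, and current month."""

    cell: tuple[int, int]
    clock: float = 0.0  # hours since simulation start
    month: int = 4


@dataclass
class MoveDistribution:
    """Probabilities over the 8 neighbour cells; land/out-of-bounds are 0."""

    neighbour_cells: list[tuple[int, int]]
    probabilities: np.ndarray


class MonthCalendar:
    """Maps the simulation clock to a calendar month.

    Months have their calendar lengths at 24 h/day (April = 720 h, May = 744
    h, ...), anchored at the simulation start; a non-leap year is assumed.
    Month indices wrap December -> January.
    """

    def __init__(self, start_month: int = 4, n_months: int = 4):
        if not 1 <= start_month <= 12:
            raise ValueError("start_month must be in 1..12")
        if n_months < 0:
            raise ValueError("n_months must be >= 0")
        self.start_month = start_month
        self.months = [(start_month - 1 + k) % 12 + 1 for k in range(n_months)]
        hours = [24.0 * _DAYS_PER_MONTH[m - 1] for m in self.months]
        self.boundaries = np.cumsum([0.0] + hours)  # len n_months + 1

    @property
    def total_hours(self) -> float:
        return float(self.boundaries[-1])

    def month_at(self, clock: float) -> int:
        """Calendar month containing ``clock``; clamped to the run window."""
        if not self.months:
            return self.start_month
        idx = int(np.searchsorted(self.boundaries, clock, side="right")) - 1
        idx = min(max(idx, 0), len(self.months) - 1)
        return self.months[idx]


def move_probabilities(local: LocalPotential, kT: float) -> MoveDistribution:
    """Boltzmann distribution over the permitted neighbours.

    P proportional to exp(-Psi/kT); not-permitted neighbours get exactly 0.
    Stable for |Psi| up to at least 1e6 at kT = 0.05 thanks to the
    min-subtraction.
    """
    if kT <= 0:
        raise ValueError("kT must be > 0")
    permitted = local.permitted
    if not permitted.any():
        raise DeadEndError(f"no permitted neighbour at {local.centre}")
    p = np.zeros(len(local.neighbour_cells))
    psi = local.psi[permitted]
    w = np.exp(-(psi - psi.min()) / kT)
    p[permitted] = w / w.sum()
    return MoveDistribution(list(local.neighbour_cells), p)


def sample_move(dist: MoveDistribution, rng: np.random.Generator) -> tuple[int, int]:
    """Draw the next cell according to the move distribution."""
    k = rng.choice(len(dist.probabilities), p=dist.probabilities)
    return dist.neighbour_cells[k]


def step_duration(centre: tuple[int, int], chosen: tuple[int, int],
                  wind: WindField, airspeed: float, grid: GridSpec) -> float:
    """Hours taken for one step at airspeed plus the tailwind component.

    Ground speed (km/h) = airspeed + 3.6 * (w_xy . dx_hat), floored at 10% of
    airspeed; a tailwind shortens the step, a headwind lengthens it.  The
    wind, like the potential tilt, is sampled at the departure cell.
    """
    dist_km = great_circle_distance(centre, chosen, grid)
    dx_hat = spherical_displacement(centre, chosen, grid)
    tail_ms = wind.u[centre] * dx_hat[0] + wind.v[centre] * dx_hat[1]
    ground = max(airspeed + MS_TO_KMH * tail_ms,
                 SPEED_FLOOR_FRACTION * airspeed)
    return dist_km / ground


def advance(state: BirdState, envs, params: ModelParams,
            rng: np.random.Generator, calendar: MonthCalendar,
            cache: PotentialCache | None = None) -> BirdState:
    """One iteration: choose a neighbour, move, advance the clock and month.

    ``envs`` maps month index -> MonthlyEnvironment; the environment for the
    bird's current month defines both the landscape and the wind clock term.
    The month is refreshed from the calendar after the clock increment, so
    the landscape switches as simulated time crosses month boundaries.
    """
    env = envs[state.month]
    local = local_potential(env, state.cell, params, cache)
    dist = move_probabilities(local, params.kT)
    chosen = sample_move(dist, rng)
    dt = step_duration(state.cell, chosen, env.wind, params.airspeed, env.grid)
    clock = state.clock + dt
    return replace(state, cell=chosen, clock=clock, month=calendar.month_at(clock))
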