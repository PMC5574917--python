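"""Brute-force oracles and the randomized property suite.

The production code vectorises the global resource sum and stabilises the
Boltzmann weights numerically; the oracles here recompute both quantities by
the most literal route available -- a naive double loop over the lattice, and
arbitrary-precision exponentials -- so tests can detect algorithmic deviation
independent of either implementation path.
"""

from __future__ import annotations

import decimal
import json
from dataclasses import asdict, dataclass

import numpy as np

from .environment import OceanMask, ScalarField, synth_environment
from .grid import GridSpec, great_circle_distance
from .movement import move_probabilities
from .potential import (LocalPotential, ModelParams, resource_potential,
                        wind_potential)

__all__ = ["OracleReport", "oracle_resource_potential", "oracle_boltzmann",
           "run_property_suite", "reports_to_json"]

PHI_RTOL = 1e-9      # reassociation noise only
PROB_ATOL = 1e-12


@dataclass
class OracleReport:
    operation: str
    max_abs_error: float
    max_rel_error: float
    n_cases: int
    passed: bool


def oracle_resource_potential(field: ScalarField, mask: OceanMask,
                              target: tuple[int, int]) -> float:
    """Reference phi: explicit loop over every lattice cell, no caching.

    Skips only the self term and cells with no positive concentration.
    Intended for grids up to ~64x128 (O(N) per call, Python-loop speed).
    """
    if field.grid != mask.grid:
        raise ValueError("field and mask grids differ")
    grid = field.grid
    values = np.nan_to_num(field.values, nan=0.0)
    total = 0.0
    for k in range(grid.n_rows):
        for l in range(grid.n_cols):
            if (k, l) == target:
                continue
            c = values[k, l]
            if c > 0 and mask.is_ocean[k, l]:
                total -= c / great_circle_distance(target, (k, l), grid)
    return total


def oracle_boltzmann(psi, permitted, kT: float) -> np.ndarray:
    """Reference move probabilities in arbitrary precision.

    Evaluates exp(-psi/kT) literally with `decimal` (60 digits, huge exponent
    range) -- no max-subtraction -- then normalises, so overflow/underflow of
    double precision cannot occur.
    """
    if kT <= 0:
        raise ValueError("kT must be > 0")
    psi = np.asarray(psi, dtype=float)
    permitted = np.asarray(permitted, dtype=bool)
    ctx = decimal.Context(prec=60, Emin=-10 ** 9, Emax=10 ** 9)
    weights = []
    for p, ok in zip(psi, permitted):
        if not ok:
            weights.append(ctx.create_decimal(0))
        else:
            weights.append(ctx.exp(ctx.create_decimal(repr(float(-p / kT)))))
    total = ctx.create_decimal(0)
    for w in weights:
        total = ctx.add(total, w)
    if total == 0:
        raise ValueError("no permitted state")
    return np.array([float(ctx.divide(w, total)) for w in weights])


# ---------------------------------------------------------------------------
# Property suite
# ---------------------------------------------------------------------------

def _random_field(rng, grid, density=0.2):
    values = np.where(rng.random(grid.shape) < density,
                      rng.gamma(1.0, 2.0, grid.shape), 0.0)
    is_ocean = rng.random(grid.shape) < 0.8
    values[~is_ocean] = 0.0
    if not is_ocean.any():
        is_ocean[0, 0] = True
    return (ScalarField(grid, 4, values), OceanMask(grid, is_ocean))


def _report(name, errors, tol, n, absolute=True) -> OracleReport:
    errors = np.asarray(errors, dtype=float)
    max_abs = float(errors.max()) if errors.size else 0.0
    return OracleReport(name, max_abs, max_abs, n, bool(max_abs <= tol))


def _check_phi_oracle(rng) -> OracleReport:
    grid = GridSpec(12, 24, 15.0)
    field, mask = _random_field(rng, grid)
    errs = []
    n = 40
    for _ in range(n):
        target = (int(rng.integers(grid.n_rows)), int(rng.integers(grid.n_cols)))
        got = resource_potential(field, mask, target)
        want = oracle_resource_potential(field, mask, target)
        scale = max(abs(want), 1e-30)
        errs.append(abs(got - want) / scale)
    return _report("resource_potential_vs_oracle", errs, PHI_RTOL, n)


def _check_boltzmann_oracle(rng) -> OracleReport:
    errs = []
    n = 200
    for _ in range(n):
        psi = rng.normal(scale=10.0 ** rng.integers(-2, 6), size=8)
        permitted = rng.random(8) < 0.7
        if not permitted.any():
            permitted[int(rng.integers(8))] = True
        kT = float(rng.choice([0.05, 0.1, 0.2, 1.0]))
        local = LocalPotential((1, 1), [(0, 0)] * 8, psi.copy(), np.zeros(8),
                               psi.copy(), permitted)
        got = move_probabilities(local, kT).probabilities
        want = oracle_boltzmann(psi, permitted, kT)
        errs.append(np.abs(got - want).max())
    return _report("move_probabilities_vs_oracle", errs, PROB_ATOL, n)


def _check_wind_contract(rng) -> OracleReport:
    from .environment import WindField

    grid = GridSpec(16, 32, 11.25)
    n = 100
    errs = []
    for _ in range(n):
        u = rng.normal(scale=10.0, size=grid.shape)
        v = rng.normal(scale=10.0, size=grid.shape)
        wind = WindField(grid, 4, u, v)
        r = int(rng.integers(1, grid.n_rows - 1))
        c = int(rng.integers(grid.n_cols))
        centre = (r, c)
        east = (r, grid.wrap_col(c + 1))
        west = (r, grid.wrap_col(c - 1))
        north, south = (r - 1, c), (r + 1, c)
        errs.append(abs(wind_potential(wind, centre, east, grid)
                        + wind_potential(wind, centre, west, grid)))
        errs.append(abs(wind_potential(wind, centre, north, grid)
                        + wind_potential(wind, centre, south, grid)))
        s = float(rng.uniform(0.5, 3.0))
        scaled = WindField(grid, 4, s * u, s * v)
        chi = wind_potential(wind, centre, east, grid)
        chi_s = wind_potential(scaled, centre, east, grid)
        errs.append(abs(chi_s - s ** 2 * chi) / max(abs(chi), 1e-30))
    return _report("wind_potential_contract", errs, 1e-9, n)


def _check_masking_idempotent(rng) -> OracleReport:
    from .environment import apply_ocean_mask

    grid = GridSpec(10, 20, 18.0)
    n = 20
    errs = []
    for _ in range(n):
        field, mask = _random_field(rng, grid)
        raw = ScalarField(grid, 4, rng.gamma(1.0, 2.0, grid.shape))
        once = apply_ocean_mask(raw, mask)
        twice = apply_ocean_mask(once, mask)
        errs.append(np.abs(once.values - twice.values).max())
    return _report("masking_idempotence", errs, 0.0, n)


def _check_trajectory_legality(rng) -> OracleReport:
    from .simulate import Colony, simulate_ensemble

    grid = GridSpec(16, 32, 11.25)
    envs = synth_environment("ring_world", grid,
                             {"lat_min": -70.0, "lat_max": -20.0, "u": 5.0},
                             seed=int(rng.integers(2 ** 31)), months=(4,))
    params = ModelParams(a=0.002, kT=0.1)
    colony = Colony("test", -50.0, 0.0)
    result = simulate_ensemble(colony, params, envs, n_birds=4,
                               base_seed=int(rng.integers(2 ** 20)),
                               duration_months=1)
    bad = 0
    mask = envs[0].mask.is_ocean
    for traj in result.trajectories:
        clocks = [s.clock_h for s in traj.steps]
        if not all(b > a for a, b in zip(clocks, clocks[1:])):
            bad += 1
        for s in traj.steps:
            if not mask[s.row, s.col]:
                bad += 1
        for a, b in zip(traj.steps, traj.steps[1:]):
            if not grid.are_adjacent((a.row, a.col), (b.row, b.col)):
                bad += 1
    return _report("trajectory_legality", [float(bad)], 0.0,
                   len(result.trajectories))


def _check_greedy_and_hot_limits(rng) -> OracleReport:
    errs = []
    n = 100
    for _ in range(n):
        psi = rng.normal(size=8)
        permitted = np.ones(8, dtype=bool)
        local = LocalPotential((1, 1), [(0, 0)] * 8, psi.copy(), np.zeros(8),
                               psi.copy(), permitted)
        cold = move_probabilities(local, 1e-9).probabilities
        errs.append(abs(cold[np.argmin(psi)] - 1.0))
        hot = move_probabilities(local, 1e9).probabilities
        errs.append(np.abs(hot - 0.125).max())
    return _report("greedy_and_hot_limits", errs, 1e-6, n)


def run_property_suite(seed: int) -> list[OracleReport]:
    """Run every cross-module invariant on randomized small instances.

    Deterministic for a fixed seed; failures are reported, never raised.
    """
    rng = np.random.default_rng(seed)
    checks = [
        _check_phi_oracle,
        _check_boltzmann_oracle,
        _check_wind_contract,
        _check_masking_idempotent,
        _check_greedy_and_hot_limits,
        _check_trajectory_legality,
    ]
    return [check(rng) for check in checks]


def reports_to_json(reports: list[OracleReport]) -> str:
    return json.dumps({"reports": [asdict(r) for r in reports],
                       "all_passed": all(r.passed for r in reports)}, indent=2)
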