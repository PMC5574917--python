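"""Gridded environmental data: resource fields, winds, ocean masks.

The model consumes monthly ocean-colour (chlorophyll-a, mg m^-3) rasters as a
resource proxy and monthly surface-wind rasters (zonal u / meridional v,
m s^-1), both on a common global lattice, plus a binary ocean mask that
excludes land and inland lakes from all calculations.  This module loads and
validates those fields, builds multi-year monthly climatologies (which both
retain only the predictable geography and fill cloud/measurement gaps), and
generates synthetic environments with the same structure for testing and
experimentation.

Two on-disk dialects are supported:

* NetCDF (classic, via xarray's scipy backend): one variable per file
  (``chlor_a``, or ``u_wind`` + ``v_wind``, or byte ``is_ocean``) with CF-style
  ``lat``/``lon`` coordinate variables validated against the GridSpec.
* A plain-text CSV-grid dialect for bit-exact fixtures: a header line
  ``#grid n_rows n_cols cell_deg lat0 lon0 month`` followed by n_rows
  comma-separated rows, ``NA`` marking missing cells.  A wind "file" in this
  dialect is a basename resolving to ``<base>.u.csv`` and ``<base>.v.csv``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .grid import GridSpec, haversine_km

__all__ = [
    "ScalarField", "WindField", "OceanMask", "MonthlyEnvironment",
    "read_csv_grid", "write_csv_grid",
    "load_scalar_field", "load_wind_field", "load_ocean_mask",
    "apply_ocean_mask", "build_climatology", "synth_environment",
]


@dataclass
class ScalarField:
    """A monthly scalar raster (chlorophyll-a concentration, mg m^-3).

    Missing cells (cloud gaps, land in the raw product) carry NaN; after
    :func:`apply_ocean_mask` land cells are exactly 0 so they contribute
    nothing to potential sums.
    """

    grid: GridSpec
    month: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid {self.grid.shape}")
        if not 1 <= self.month <= 12:
            raise ValueError("month must be in 1..12")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("negative concentrations: corrupt input")


@dataclass
class WindField:
    """A monthly wind raster: zonal u (+east) and meridional v (+north), m s^-1."""

    grid: GridSpec
    month: int
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        for name, comp in (("u", self.u), ("v", self.v)):
            if comp.shape != self.grid.shape:
                raise ValueError(
                    f"{name} shape {comp.shape} != grid {self.grid.shape}")
        if not 1 <= self.month <= 12:
            raise ValueError("month must be in 1..12")

    def require_finite(self):
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("wind field has unfilled gaps; build a climatology")


@dataclass
class OceanMask:
    """Binary lattice: True on ocean cells, False on land and inland lakes."""

    grid: GridSpec
    is_ocean: np.ndarray

    def __post_init__(self):
        self.is_ocean = np.asarray(self.is_ocean, dtype=bool)
        if self.is_ocean.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.is_ocean.shape} != grid {self.grid.shape}")
        if not self.is_ocean.any():
            raise ValueError("ocean mask has no ocean cells")


@dataclass
class MonthlyEnvironment:
    """One month's resource field, wind field, and ocean mask on one grid."""

    month: int
    resource: ScalarField
    wind: WindField
    mask: OceanMask

    def __post_init__(self):
        g = self.resource.grid
        if self.wind.grid != g or self.mask.grid != g:
            raise ValueError("resource, wind and mask must share one GridSpec")
        if not (self.resource.month == self.wind.month == self.month):
            raise ValueError("month mismatch between fields")

    @property
    def grid(self) -> GridSpec:
        return self.resource.grid


# ---------------------------------------------------------------------------
# CSV-grid dialect (bit-exact round trip; used for text fixtures)
# ---------------------------------------------------------------------------

def write_csv_grid(path, grid: GridSpec, month: int, values: np.ndarray) -> None:
    """Write one raster in the CSV-grid dialect; NaN becomes ``NA``.

    Floats are written with ``repr`` so a read-back is bit-exact.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    with open(path, "w") as fh:
        fh.write(f"#grid {grid.n_rows} {grid.n_cols} {grid.cell_deg!r} "
                 f"{grid.lat0!r} {grid.lon0!r} {month}\n")
        for row in values:
            fh.write(",".join("NA" if not np.isfinite(x) else repr(float(x))
                              for x in row) + "\n")


def read_csv_grid(path) -> tuple[GridSpec, int, np.ndarray]:
    """Read a CSV-grid file; returns (grid, month, values with NaN for NA)."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 7 or header[0] != "#grid":
            raise ValueError(f"{path}: not a CSV-grid file")
        n_rows, n_cols = int(header[1]), int(header[2])
        cell_deg, lat0, lon0 = (float(header[i]) for i in (3, 4, 5))
        month = int(header[6])
        grid = GridSpec(n_rows, n_cols, cell_deg, lat0, lon0)
        rows = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rows.append([np.nan if tok == "NA" else float(tok)
                         for tok in line.split(",")])
    values = np.array(rows, dtype=float)
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: body shape {values.shape} != header "
                         f"({n_rows}, {n_cols})")
    return grid, month, values


# ---------------------------------------------------------------------------
# NetCDF (classic) via xarray's scipy backend
# ---------------------------------------------------------------------------

def _open_netcdf(path):
    import xarray as xr
    return xr.open_dataset(path, engine="scipy")


def _check_coords(ds, grid: GridSpec, path) -> None:
    lat = np.asarray(ds["lat"])
    lon = np.asarray(ds["lon"])
    if lat.size != grid.n_rows or lon.size != grid.n_cols:
        raise ValueError(f"{path}: dimensions ({lat.size}, {lon.size}) do not "
                         f"match grid {grid.shape}")
    if not (np.allclose(lat, grid.lat_centers(), atol=1e-4)
            and np.allclose(lon, grid.lon_centers(), atol=1e-4)):
        raise ValueError(f"{path}: coordinate variables do not match GridSpec")


def write_netcdf_scalar(path, field: ScalarField, var: str = "chlor_a") -> None:
    import xarray as xr
    ds = xr.Dataset(
        {var: (("lat", "lon"), field.values.astype(np.float32))},
        coords={"lat": field.grid.lat_centers(), "lon": field.grid.lon_centers()},
        attrs={"month": field.month},
    )
    ds.to_netcdf(path, engine="scipy")


def write_netcdf_wind(path, wind: WindField) -> None:
    import xarray as xr
    ds = xr.Dataset(
        {"u_wind": (("lat", "lon"), wind.u.astype(np.float32)),
         "v_wind": (("lat", "lon"), wind.v.astype(np.float32))},
        coords={"lat": wind.grid.lat_centers(), "lon": wind.grid.lon_centers()},
        attrs={"month": wind.month},
    )
    ds.to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def _is_netcdf(path) -> bool:
    return str(path).endswith(".nc")


def load_scalar_field(path, month: int, grid: GridSpec,
                      var: str = "chlor_a") -> ScalarField:
    """Load a monthly scalar raster (NetCDF or CSV-grid).

    Dimension mismatches are errors, never silently reshaped; negative
    concentrations are rejected as corrupt input.
    """
    if _is_netcdf(path):
        with _open_netcdf(path) as ds:
            if var not in ds:
                raise ValueError(f"{path}: variable {var!r} not found")
            _check_coords(ds, grid, path)
            values = np.asarray(ds[var], dtype=float)
    else:
        fgrid, fmonth, values = read_csv_grid(path)
        if fgrid.shape != grid.shape or not np.isclose(fgrid.cell_deg, grid.cell_deg):
            raise ValueError(f"{path}: grid {fgrid.shape} does not match "
                             f"expected {grid.shape}")
        if fmonth != month:
            raise ValueError(f"{path}: file month {fmonth} != requested {month}")
    return ScalarField(grid, month, values)


def load_wind_field(path, month: int, grid: GridSpec) -> WindField:
    """Load a monthly wind raster.

    NetCDF files must provide both ``u_wind`` and ``v_wind``; in the CSV-grid
    dialect ``path`` is a basename resolving to ``<base>.u.csv`` and
    ``<base>.v.csv``.  A missing component is an error.
    """
    if _is_netcdf(path):
        with _open_netcdf(path) as ds:
            missing = [v for v in ("u_wind", "v_wind") if v not in ds]
            if missing:
                raise ValueError(f"{path}: missing wind component(s) {missing}")
            _check_coords(ds, grid, path)
            u = np.asarray(ds["u_wind"], dtype=float)
            v = np.asarray(ds["v_wind"], dtype=float)
    else:
        base = str(path)
        for suffix in (".u.csv", ".v.csv"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
        upath, vpath = Path(base + ".u.csv"), Path(base + ".v.csv")
        for p in (upath, vpath):
            if not p.exists():
                raise ValueError(f"missing wind component file {p}")
        ugrid, umonth, u = read_csv_grid(upath)
        vgrid, vmonth, v = read_csv_grid(vpath)
        if ugrid.shape != grid.shape or vgrid.shape != grid.shape:
            raise ValueError("wind component grid does not match expected grid")
        if umonth != month or vmonth != month:
            raise ValueError("wind component month does not match request")
    return WindField(grid, month, u, v)


def load_ocean_mask(path, grid: GridSpec) -> OceanMask:
    """Load a binary ocean mask (NetCDF byte ``is_ocean`` or CSV-grid 0/1)."""
    if _is_netcdf(path):
        with _open_netcdf(path) as ds:
            if "is_ocean" not in ds:
                raise ValueError(f"{path}: variable 'is_ocean' not found")
            _check_coords(ds, grid, path)
            raw = np.asarray(ds["is_ocean"])
    else:
        fgrid, _month, raw = read_csv_grid(path)
        if fgrid.shape != grid.shape:
            raise ValueError("mask grid does not match expected grid")
    if not np.isin(np.nan_to_num(raw), (0, 1)).all():
        raise ValueError("ocean mask values must be 0 or 1")
    return OceanMask(grid, np.nan_to_num(raw).astype(bool))


# ---------------------------------------------------------------------------
# Masking and climatology
# ---------------------------------------------------------------------------

def apply_ocean_mask(field: ScalarField, mask: OceanMask) -> ScalarField:
    """Zero out every land cell so it is excluded from all potential sums.

    Ocean cells are unchanged (including NaN data gaps, which the potential
    sum also skips).  Idempotent.
    """
    if field.grid != mask.grid:
        raise ValueError("field and mask grids differ")
    values = field.values.copy()
    values[~mask.is_ocean] = 0.0
    return ScalarField(field.grid, field.month, values)


def _nearest_fill(values: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Fill NaN cells with the value of the nearest non-NaN cell.

    Nearness is great-circle distance between cell centres, computed on 3-D
    unit vectors so longitude wrap is handled naturally.
    """
    from scipy.spatial import cKDTree

    out = values.copy()
    missing = ~np.isfinite(out)
    if not missing.any():
        return out
    if missing.all():
        raise ValueError("cannot fill: no cell has data in any year")
    lat = np.radians(grid.lat_centers())[:, None] + np.zeros(grid.shape)
    lon = np.radians(grid.lon_centers())[None, :] + np.zeros(grid.shape)
    xyz = np.stack([np.cos(lat) * np.cos(lon),
                    np.cos(lat) * np.sin(lon),
                    np.sin(lat)], axis=-1)
    good = ~missing
    tree = cKDTree(xyz[good])
    _, idx = tree.query(xyz[missing])
    out[missing] = out[good][idx]
    return out


def build_climatology(paths: Sequence, month: int, grid: GridSpec,
                      kind: str = "scalar"):
    """Per-cell mean over yearly files for one month.

    Averaging over years both keeps only the inter-annually predictable
    geography and fills per-year gaps: a cell missing in some years takes the
    mean of the years where it has data.  A scalar cell missing in every year
    stays missing (NaN); a wind cell missing in every year is filled from the
    nearest cell with data, with a warning.

    Parameters
    ----------
    paths
        One file per year, all in the same dialect on the same grid.
    kind
        ``"scalar"`` or ``"wind"``.
    """
    if not paths:
        raise ValueError("empty file list")

    def exact_nanmean(stack):
        # cell-wise mean over years; where every year agrees the mean is
        # taken bit-exactly (no 1-ulp division noise)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            mean = np.nanmean(stack, axis=0)
            lo, hi = np.nanmin(stack, axis=0), np.nanmax(stack, axis=0)
        agree = np.isfinite(lo) & (lo == hi)
        mean[agree] = lo[agree]
        return mean

    if kind == "scalar":
        stack = np.stack([load_scalar_field(p, month, grid).values
                          for p in paths])
        return ScalarField(grid, month, exact_nanmean(stack))
    elif kind == "wind":
        winds = [load_wind_field(p, month, grid) for p in paths]
        u = exact_nanmean(np.stack([w.u for w in winds]))
        v = exact_nanmean(np.stack([w.v for w in winds]))
        n_gaps = int((~np.isfinite(u)).sum() + (~np.isfinite(v)).sum())
        if n_gaps:
            warnings.warn(f"wind climatology: {n_gaps} cell-components missing "
                          "in all years; filled from nearest cell with data")
            u = _nearest_fill(u, grid)
            v = _nearest_fill(v, grid)
        return WindField(grid, month, u, v)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Synthetic environments
# ---------------------------------------------------------------------------

DEFAULT_MONTHS = (4, 5, 6, 7)  # April-July, the simulated non-breeding window


def synth_environment(kind: str, grid: GridSpec, params: dict | None = None,
                      seed: int = 0,
                      months: Sequence[int] = DEFAULT_MONTHS,
                      ) -> list[MonthlyEnvironment]:
    """Generate a deterministic synthetic environment series.

    Kinds
    -----
    point_source
        All-ocean world, zero wind, a single resource cell of amplitude
        ``amplitude`` (default 1000 mg m^-3, standing in for an integrated
        productive patch) at ``source`` (default the grid centre).
    two_patch
        All-ocean world, zero wind, two equal point patches at ``center``'s
        row, ``offset_cols`` columns east and west of it -- exactly
        mirror-symmetric about ``center``'s meridian.
    uniform_wind
        All-ocean world, uniform resource ``resource`` (default 1 mg m^-3),
        constant wind ``(u, v)`` (default (10, 0) m s^-1, a typical monthly
        mean westerly).
    ring_world
        Ocean only in the latitude band ``lat_min..lat_max`` (default
        -65..-35, the subantarctic zone), uniform resource, optional uniform
        wind ``(u, v)`` (default calm) -- a zonally symmetric channel like the
        Southern Ocean.
    zonal_jet
        Ocean except polar caps and one meridional continent; smooth patchy
        lognormal resource (seeded), a Gaussian westerly jet centred at
        ``jet_lat`` (default -50) with peak ``u_max`` (default 10 m s^-1) and
        width ``jet_width`` (default 15 deg), mild seasonal modulation.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    builders = {
        "point_source": _synth_point_source,
        "two_patch": _synth_two_patch,
        "uniform_wind": _synth_uniform_wind,
        "ring_world": _synth_ring_world,
        "zonal_jet": _synth_zonal_jet,
    }
    if kind not in builders:
        raise ValueError(f"unknown synthetic environment kind {kind!r}")
    return [builders[kind](grid, p, rng, m) for m in months]


def _all_ocean(grid: GridSpec) -> OceanMask:
    return OceanMask(grid, np.ones(grid.shape, dtype=bool))


def _calm(grid: GridSpec, month: int) -> WindField:
    z = np.zeros(grid.shape)
    return WindField(grid, month, z, z.copy())


def _synth_point_source(grid, p, rng, month):
    amplitude = float(p.get("amplitude", 1000.0))
    source = tuple(p.get("source", (grid.n_rows // 2, grid.n_cols // 2)))
    values = np.zeros(grid.shape)
    values[source] = amplitude
    mask = _all_ocean(grid)
    return MonthlyEnvironment(month, ScalarField(grid, month, values),
                              _calm(grid, month), mask)


def _synth_two_patch(grid, p, rng, month):
    amplitude = float(p.get("amplitude", 1000.0))
    center = tuple(p.get("center", (grid.n_rows // 2, grid.n_cols // 2)))
    offset = int(p.get("offset_cols", grid.n_cols // 4))
    values = np.zeros(grid.shape)
    row, col = center
    values[row, grid.wrap_col(col + offset)] = amplitude
    values[row, grid.wrap_col(col - offset)] = amplitude
    return MonthlyEnvironment(month, ScalarField(grid, month, values),
                              _calm(grid, month), _all_ocean(grid))


def _synth_uniform_wind(grid, p, rng, month):
    resource = float(p.get("resource", 1.0))
    u = float(p.get("u", 10.0))
    v = float(p.get("v", 0.0))
    values = np.full(grid.shape, resource)
    wind = WindField(grid, month, np.full(grid.shape, u), np.full(grid.shape, v))
    return MonthlyEnvironment(month, ScalarField(grid, month, values),
                              wind, _all_ocean(grid))


def _synth_ring_world(grid, p, rng, month):
    lat_min = float(p.get("lat_min", -65.0))
    lat_max = float(p.get("lat_max", -35.0))
    resource = float(p.get("resource", 1.0))
    u = float(p.get("u", 0.0))
    v = float(p.get("v", 0.0))
    lats = grid.lat_centers()
    ocean_rows = (lats >= lat_min) & (lats <= lat_max)
    is_ocean = np.zeros(grid.shape, dtype=bool)
    is_ocean[ocean_rows, :] = True
    mask = OceanMask(grid, is_ocean)
    values = np.where(is_ocean, resource, 0.0)
    wind = WindField(grid, month, np.full(grid.shape, u), np.full(grid.shape, v))
    return MonthlyEnvironment(month, ScalarField(grid, month, values), wind, mask)


def _synth_zonal_jet(grid, p, rng, month):
    from scipy.ndimage import gaussian_filter

    u_max = float(p.get("u_max", 10.0))
    jet_lat = float(p.get("jet_lat", -50.0))
    jet_width = float(p.get("jet_width", 15.0))
    mean_resource = float(p.get("resource", 1.0))
    cap_lat = float(p.get("cap_lat", 78.0))
    lats = grid.lat_centers()
    lons = grid.lon_centers()

    # land: polar caps plus one meridional continent in the eastern hemisphere
    is_ocean = np.ones(grid.shape, dtype=bool)
    is_ocean[np.abs(lats) > cap_lat, :] = False
    continent_cols = (lons >= 10.0) & (lons <= 40.0)
    continent_rows = lats > -30.0
    is_ocean[np.ix_(continent_rows, continent_cols)] = False
    mask = OceanMask(grid, is_ocean)

    # patchy lognormal resource, smoothed, mildly seasonal (SH spring peak)
    noise = rng.normal(size=grid.shape)
    smooth = gaussian_filter(noise, sigma=max(1.0, grid.n_rows / 24.0),
                             mode=("nearest", "wrap"))
    field = np.exp(smooth - smooth.mean())
    season = 1.0 + 0.2 * np.cos(2.0 * np.pi * (month - 10) / 12.0)
    values = mean_resource * season * field / field.mean()
    values[~is_ocean] = np.nan  # raw product: no data over land
    resource = apply_ocean_mask(ScalarField(grid, month, values), mask)

    u = u_max * np.exp(-((lats - jet_lat) / jet_width) ** 2)[:, None] \
        * np.ones(grid.shape)
    v = np.zeros(grid.shape)
    wind = WindField(grid, month, u, v)
    return MonthlyEnvironment(month, resource, wind, mask)
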