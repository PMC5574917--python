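# Methods

## Model

A bird is a particle on a global lat/lon lattice. The potential landscape
has two components. The resource potential treats every cell's chlorophyll-a
concentration as a point mass producing a −1/r field:
φ_ij = −Σ C_kl / r_ij,kl, summed over all cells with positive concentration
except the target cell itself (distinct cell centres never coincide, so no
softening term is needed). The wind component is local: wind is a
rotational field with no global potential, so around the current cell the
landscape is tilted by χ_ij = −|w_xy|(w_xy · d̂x), derived from drag ∝ |w|²;
the wind is sampled at the departure cell only, with no midpoint
interpolation. The combined potential is Ψ = φ + a·χ, and moves to the 8
neighbouring cells are drawn with Boltzmann probabilities
P ∝ exp(−Ψ/kT) over *permitted* neighbours — ocean cells inside the
latitude bounds. Staying put is not an option, and land never receives
probability mass. The step clock advances by great-circle step length over
ground speed.

Assumptions worth keeping in mind: birds are assumed to know the global
resource distribution (attraction acts at any distance); movement is purely
environment-driven inside the simulated window (no colony-return urge, no
competition, no thermal-niche term); crosswind dynamic soaring is ignored —
the wind term is tailwind support only.

## Units and conventions

* Grid: row 0 is the northernmost row, column 0 the westernmost; cell
  centres at `lat = lat0 − i·cell_deg`, `lon = lon0 + j·cell_deg`.
  Columns wrap across ±180°; latitude does not wrap, and a neighbour beyond
  the first/last row is not permitted. The reference resolution of the real
  data products is 720 × 1440 at 0.25°; any global grid works.
* Distances: haversine between cell centres on a 6371 km sphere, in km.
  Because φ is concentration over distance in mg m⁻³ km⁻¹ and χ is in m² s⁻²,
  the numerical scale of `a` is tied to this convention; values of `a`
  quoted for other unit conventions are indicative only.
* Spherical displacement: d̂x = normalize(Δlon·cos(lat̄), Δlat), with lat̄ the
  mean latitude of the two cells; sub-cell accuracy beyond the mean-latitude
  cosine is ignored.
* Masked cells contribute exactly 0 to potential sums (not NaN); ocean data
  gaps (NaN) also contribute 0 after climatological averaging.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `a` | wind weight in Ψ = φ + a·χ | sweep 0.001–0.008 | transition range between resource- and wind-dominance under this unit convention |
| `kT` | movement temperature (β = 1/kT) | sweep 0.05–0.2 | larger values wash patterns out into a random walk |
| `airspeed` | typical airspeed | 60 km/h | sets the step clock together with the tailwind |
| speed floor | minimum ground speed | 10 % of airspeed | keeps headwind steps finite; configurable constant |
| window | simulated months | April–July | the core non-breeding season |
| ensemble | birds per (colony, a, kT) | 16 | the sample size used throughout |

Ground speed = airspeed + 3.6·(w·d̂x) km/h, floored as above. The published
description of the clock ("typical speed plus a wind component") fixes no
formula; using the same tailwind dot product as χ is this package's design
choice, as is the 10 % floor. Months last their calendar number of days at
24 h/day (April = 720 h), anchored at the simulation start, non-leap;
the final step of a run is executed in full even when it overshoots the
window end.

## Numerical choices

* Boltzmann weights are exponentiated after subtracting the minimum Ψ among
  permitted neighbours — an invariant shift — so probabilities stay finite
  for |Ψ| up to at least 1e6 at kT = 0.05. kT = 0 exactly is rejected
  rather than special-cased.
* φ is memoised per (month, cell) and shared across birds and across the
  (a, kT) pairs of a sweep, since it depends on neither parameter. The
  cache is transparent (tested against fresh evaluation).
* The independent oracles: a naive double-loop φ (no vectorisation, no
  caching) and an arbitrary-precision Boltzmann evaluation using `decimal`
  at 60 digits with a huge exponent range (no max-subtraction). Tolerances:
  1e−9 relative for φ (float reassociation noise only), 1e−12 absolute for
  probabilities.
* Ties in `snap_to_ocean` break toward the smallest (row, col);
  `directional_split` judges east/west along the shorter arc and counts a
  bird exactly on the meridian as east.
* RNG: one `numpy` Generator per bird, seeded `base_seed + bird`;
  sweep pair p uses `base_seed + p·10⁶ + b` so extending a sweep never
  perturbs existing runs.

## Synthetic environments

The generator mimics the *structure* of the real monthly climatologies —
non-negative patchy scalar fields masked to ocean, smooth winds with
dominant westerlies, monthly slices — not their geography:

* `point_source` (amplitude 1000 mg m⁻³ at one cell): a single integrated
  productive patch; chosen so per-step potential differences are of order
  kT at a few thousand km on a 64×128 grid (A·Δr/r² ≈ 0.03 at 3000 km).
* `two_patch`: two equal point patches exactly mirror-symmetric about a
  reference meridian.
* `uniform_wind` / `ring_world`: uniform resource with constant wind
  (default 10 m s⁻¹, a typical Southern Ocean monthly mean); `ring_world`
  restricts ocean to a zonal band (default 65–35° S, the subantarctic
  zone), giving a zonally symmetric channel.
* `zonal_jet`: smoothed lognormal resource patchiness with mild seasonal
  modulation, a Gaussian westerly jet centred at 50° S (peak 10 m s⁻¹,
  width 15°), polar-cap land plus one meridional continent.

What passing tests on these worlds show: the potential and probability
machinery is exact against oracles, and drift responds to resource
gradients and wind in the designed direction. What they do not show: any
statement about real migration routes, which depends on the real
chlorophyll/wind climatology (loadable via the NetCDF readers) and on
qualitative comparison with tracking data — both outside the test suite.

## Problem sizes

Verification runs use 32×64 and 64×128 lattices, one or two simulated
months, 16-bird ensembles (400 for the symmetry check), and the full
8 × 4 = 32-pair sweep at 16 birds — sizes chosen so the whole suite and the
acceptance script each complete in a few minutes on one CPU while leaving
the statistical checks well-powered (binomial 5σ bounds).

## Known limitations

* No competition, niche tracking (e.g. sea-surface-temperature terms),
  stopovers, day/night structure, energetics, or return migration.
* The global −1/r sum is exact but O(N) per cell; very long runs on the
  full 0.25° lattice rely on the per-cell cache rather than on FFT/treecode
  acceleration.
* Ocean-mask rasterization is consumed pre-made; no shapefile processing.
* The inland-lake exclusion and land exclusion share one binary mask; brief
  over-land shortcuts some seabirds take are not representable.
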