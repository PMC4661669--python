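# Methods

This note documents the models implemented in `soilrisk`, the defaults
shipped with the package, what the synthetic scene generator does and
does not emulate, and the numerical choices a maintainer should know.

## Health-risk model

The engine implements the standard three-pathway soil exposure model
used by US EPA RAGS and the Chinese contaminated-site guideline
HJ 25.3: incidental soil ingestion, dermal contact and inhalation of
resuspended particulates. For a concentration C (mg/kg) and an
exposure scenario s:

- ingestion dose: `C·IngR·EF·ED·CF / (BW·AT)`
- dermal dose: `C·SA·AF·ABS·EF·ED·CF / (BW·AT)`
- inhalation dose: `C·InhR·EF·ED / (PEF·BW·AT)`

with `AT = AT_ca` (25 550 d, a 70-year lifetime) for carcinogenic
endpoints and `AT = AT_nc = ED·365` otherwise. Carcinogenic risk is
`CR = dose·SF` on pathways with a slope factor, the hazard quotient is
`HQ = dose/RfD` on pathways with a reference dose, and TCR/THI are the
sums over all (pollutant, pathway) pairs. A pathway without a
toxicity value for a pollutant simply contributes nothing — there is
no imputation.

Parameters live entirely in configuration. The shipped registry covers
18 analytes (As, Cd, Cr⁶⁺, Co, Cu, Pb, Ni, V, Zn, Hg and eight
organics including benzene, ethylbenzene, xylenes and two PAHs) with
literature default SF/RfD values (IRIS/RSL-style) and per-pollutant
dermal absorption overrides (0.03 for As, 0.13 for PAHs). These are
screening-grade defaults, not site-specific values; any study should
review and override them. Chromium is risk-assessed as Cr⁶⁺ (registry
key `Cr6`), the carcinogenic species.

Exposure scenarios are defined per land-use class (adult receptor;
residential, industrial, agriculture, conservation differ in EF, ED,
IngR, SA, AF, InhR). A sample is assessed under the scenario of the
land-use cell it falls in, with residential as the conservative
fallback off-grid or on nodata cells.

Nondetects (absent concentration entries) contribute zero dose by
default; an LOD/2 substitution is available and must be requested
explicitly together with an LOD table, so censoring handling is always
a visible choice.

### Classification

TCR is classed at breaks (10⁻⁶, 10⁻⁵, 10⁻⁴). The 10⁻⁶ line is the
conventional de-minimis lifetime cancer risk; 10⁻⁴ is the usual upper
bound of the tolerable range. All class intervals in the package —
TCR, CRI, raster classification — are lower-open/upper-closed except
the lowest (a value exactly on a break falls in the lower class),
matching the printed form of the CRI table: low 0 ≤ CRI ≤ 1, moderate
1 < CRI ≤ 2, high 2 < CRI ≤ 2.5, extreme 2.5 < CRI ≤ 3. Four-class TCR
boundaries are not standardized in the literature; both the breaks and
the interval convention are config-visible rather than hard-coded.

## Factory inherent-risk index (CRI)

The index system has three criteria with fixed weights — sudden-risk
potential 0.30, cumulative risk 0.30, supervision level 0.40 — and 22
indicators carrying their published weights (hazardous-substance
inventory 0.35, emergency plan 0.15, annual soot/SO₂/NOₓ emissions
0.15 each, treatment rates 0.15 each, and so on). Raw attributes are
standardized to [0, 3] by per-indicator rules of three kinds: interval
bins over a numeric value, categorical label lookups, and booleans.
The shipped rules are stand-ins built from typical emission and
management gradations — the original standardization tables referenced
national industry standards that are not reproducible here — and every
rule is overridable in the config.

Within a criterion the subscore is the weight-normalized mean
`Σwᵢsᵢ/Σwᵢ`. This matters because the cumulative criterion's printed
indicator weights sum to 0.65, not 1.0: normalization keeps every
criterion on the same [0, 3] scale (a constant score field is a fixed
point regardless of the weight total) while preserving the printed
relative importances verbatim. The raw weighted sum is available as
`weight_mode: raw` for anyone wanting the un-normalized reading.
Missing indicators are an error by default, with `worst_case` (score
3) and `renormalize` (drop) as explicit alternatives.

## Spatial interpolation

IDW with weights `d⁻ᵖ` over the k nearest sample points; defaults
p = 2, k = 12, both exposed in config and CLI. Distance ties at the
k-th neighbor are all included, making the neighborhood
order-independent. A query within `snap_eps` (10⁻⁹ m) of a sample
returns that sample's value exactly. Distances are normalized by the
nearest neighbor's distance before exponentiation so large powers
(used to test the nearest-neighbor limit) cannot overflow. Predictions
are convex combinations of the used values, hence bounded by the data
range and exact at data points — the extremum-preserving behavior that
motivates IDW over kriging/splines for hotspot mapping, where
smoothing would erase exactly the local maxima of interest.

Interpolation quality is measured by leave-one-out cross-validation
RMSE. The pipeline interpolates the per-sample TCR (sum first,
interpolate second); interpolating per-pollutant CR rasters and
summing them afterwards gives a different surface, and the library
supports computing either, but sum-first is the default because the
classified quantity is the per-point TCR itself.

Rasters use cell-center evaluation on a lower-left-origin grid; the
in-memory row 0 is the northernmost row, matching the ESRI ASCII file
order, and that contract is tested. Raster I/O is the plain ESRI
ASCII grid dialect with the canonical six-token header and shortest
round-trip float formatting, which is what makes byte-identical
re-runs achievable.

## Integrated risk overlay

The integrated class of a cell is a pure 4×4 matrix lookup
(TCR class × land-use class). The default matrix relaxes risk on
industrial land and escalates it on residential and conservation land;
each land-use column is monotone in the health level, and that
property is asserted from the loaded matrix rather than assumed. A
cell is nodata iff either input is nodata.

The factory CRI surface (IDW of per-factory CRI on the shared grid)
is a companion layer: it is reported alongside the matrix
classification, not blended into it, because the matrix is defined on
health risk and land use only and any blending rule would be an
invention. For users who want one, an explicit opt-in flag escalates
a cell's integrated class by one level where the CRI surface exceeds
the extreme break (2.5); it is off by default and clearly an
extension.

Outputs carry provenance: config digest, seed and SHA-256 digests of
the input files, which change iff the inputs change.

## Synthetic scenes

The generator emulates the structure of a ~1200 km² industrial/mining
study area on a 40 × 30 km extent:

- **Sampling design**: census points on a 3 km systematic-random grid
  (one uniform jitter per cell, magnitude `jitter_frac`·spacing,
  default 0.3; zero allowed for deterministic spacing tests), plus
  1 km "encrypted" infill grids inside three hotspot rectangles; no
  points inside the central reservoir rectangle, which is nodata on
  every raster. Under the defaults this yields ≈130 census + ≈125
  infill points; counts are emergent from geometry, not forced.
- **Concentration fields**: per-pollutant lognormal backgrounds
  (median, geometric SD at magnitudes typical of polluted industrial
  topsoils) with Gaussian plumes added on the log scale
  (`amplitude·exp(−d²/2ℓ²)`), so concentrations stay strictly positive
  (metals at 100% detection) and the background CV structure survives
  multiplicatively. The default scene has a dominant As plume
  (log-amplitude 3.5, ℓ = 1.5 km) where a residential zone meets the
  oilfield industrial zone, plus smaller Cd and Cr⁶⁺ plumes. Organics
  and Hg are censored: each measurement is detected with probability
  0.08, else recorded as a nondetect.
- **Factories**: 150 records, 80% placed inside hotspot zones and the
  rest scattered, each assigned a latent risk tier (defaults: 50%
  moderate, 46% high, 4% extreme) that drives tier-conditional draws
  of all 22 raw indicators; tiers are recorded in the ground truth so
  recovery tests never re-derive them from outputs.
- **Land use**: rectangle-based, overlaps resolved by the fixed
  priority conservation > residential > industrial > agriculture,
  agriculture as background.

All generators are pure functions of (config, seed); a NumPy
`default_rng` is threaded through explicitly.

What the generator does **not** emulate: real geography, spatially
correlated background noise (backgrounds are i.i.d. between points;
only plumes create spatial structure), soil-type or pH dependence of
concentrations, detection limits varying by analyte, or any
calibration to a specific survey's concentration statistics. Passing
tests therefore demonstrate that the pipeline recovers structure the
generator planted — plume locations, tier orderings, censoring rates —
not that any specific field study's numbers are reproduced.

## Problem sizes and numerical choices

The default raster uses 500 m cells (80 × 60); the end-to-end recovery
check runs 50 seeded replicates of the full pipeline at that
resolution, and the censoring check uses a ~1100-point scene — sizes
at which the whole suite and the acceptance script each finish in
seconds while leaving the statistical checks well-powered. Oracle
agreement tolerances are 10⁻¹² relative for the health engine (pure
arithmetic) and 10⁻¹⁰ absolute for IDW (one distance computation
apart); accumulation order within TCR/THI sums is fixed by the
registry order. Bisection over classifiers uses a 10⁻¹² window. The
nearest-neighbor limit of IDW at large p is only asserted on generic
configurations (second-nearest distance ≥ 1.5× the nearest), since
near-ties genuinely mix values at any finite power.

## Known limitations

- Exposure is deterministic single-receptor (adult); no age
  stratification, probabilistic exposure, bioaccessibility or
  groundwater pathway.
- The factory scoring rules are stand-ins; CRI values are only
  meaningful relative to a reviewed ruleset.
- No CRS handling: coordinates are planar meters by contract.
- IDW with few neighbors produces the familiar bull's-eye artifacts;
  the package deliberately does not offer kriging as an alternative.
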