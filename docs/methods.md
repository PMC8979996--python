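# Methods

## The optical model

Light available to benthic photosynthesis is modelled as a single broadband
quantity: the daily photon dose of PAR (mol photons m⁻² day⁻¹).  Its decay
with depth is governed by one diffuse attenuation coefficient per grid
cell, `KdPAR` (m⁻¹), derived from the 490 nm satellite attenuation product
by the empirical polynomial `KdPAR = a + b·Kd490 − c/Kd490` with defaults
`a = 0.0665`, `b = 0.874`, `c = 0.00121`.  Seabed irradiance is then
`Ez = E0·exp(−KdPAR·z)` with `E0` the satellite surface PAR and `z` the
bathymetric depth (positive down), and any isolume depth follows as
`ln(E0/E)/KdPAR`.

Assumptions inherited by everything downstream:

- **No spectral resolution.**  A single broadband coefficient per cell; no
  inherent-optical-property or radiative-transfer modelling.
- **No air–sea or directionality correction.**  `E0` is the satellite
  surface PAR as delivered; the directional dependence of the attenuation
  coefficients is weak at the depths of interest.
- **Time-mean optics.**  `Kd490` and `E0` enter as multi-year per-cell
  means (the climatology step is a plain average with missing observations
  excluded cell-wise); no seasonal or diurnal cycling.

The polynomial is negative for `Kd490` below the positive root of
`b·k² + a·k − c = 0` (≈ 0.01517 m⁻¹ at the defaults).  Such cells are
*masked invalid* by default rather than clamped — substituting a fabricated
attenuation would bias the lower border seaward — and the count is logged;
`OpticalParams(invalid_policy="clamp")` switches to clamping when a
caller prefers continuity over caution.

## Zone definition and numerical conventions

A cell is mesophotic iff `depth ≥ 30 m` **and** `Ez ≥ e_min` with
`e_min = 10⁻⁴ mol photons m⁻² day⁻¹`.  Both comparisons are inclusive: the
boundary set has measure zero physically, but fixing the convention makes
masks deterministic.  Cells invalid in either input are undetermined
(nodata), never silently non-mesophotic.  No additional deep cutoff is
applied: the exclusion of truly deep seabed is emergent from `e_min`.

Other numerical choices:

- **Grids.**  North-up, cell-center registered, regular lon/lat (WGS84);
  transforms store the upper-left cell corner; NaN marks missing cells in
  memory, a tagged sentinel on disk (single-band float32 GeoTIFF).
  Nodata is absorbing through all arithmetic.
- **Depth sign.**  Positive metres down everywhere; elevation rasters are
  recognized by a negative median over valid cells and negated on read,
  after which residual negative cells (land above datum) become nodata.
- **Harmonization.**  Satellite fields are brought to the bathymetry grid
  by bilinear interpolation of cell centers, with a nearest-valid fallback
  within 2 source-cell widths where the 2×2 support is incomplete
  (shoreline cells of ocean-colour products are routinely masked); beyond
  the fallback radius cells stay nodata.  Bilinear output is a convex
  combination of valid source values, so resampling can never invent values
  outside the observed range.  Attenuation fields are smooth at 4 km, which
  is why bilinear (not blockier nearest) is the default; both are exposed.
- **Areas.**  Computed on the raster mask from exact spherical cell areas,
  `(π/180)·R²·|Δλ|·|sin φ_top − sin φ_bot|` with `R = 6371.0088 km`, so
  every reported km² has a closed form.  Vectorized zone polygons carry the
  same spherical area in their metadata; sub-region membership is by
  cell-center test, a ≤ 1-cell-row error source at polygon boundaries.
- **Borders.**  A zone cell's edge against a valid non-zone neighbour is
  *upper* if the neighbour fails the depth bound (including corner cells
  failing both bounds — the 30 m limit is the definitionally fixed one) and
  *lower* if it fails only the light bound; edges against nodata or the
  raster rim belong to neither.  Edges are chained into polylines
  deterministically and sampled from each line's start at fixed geodesic
  spacing (default 20 km, haversine on the same sphere); values are read
  off the nearest cell — border points sit on cell edges where bilinear
  support is one-sided, so interpolation would be asymmetric.
- **Statistics.**  Group differences along the borders use Kruskal–Wallis
  (mid-rank ties, standard tie-correction, χ² upper tail) and Dunn's post
  hoc z tests with Bonferroni adjustment capped at 1; all-identical input
  degenerates to `H = 0, p = 1`.  Shapiro–Wilk and median-centered Levene
  screening is advisory only and never gates the rank tests; p-values are
  kept at machine precision in all outputs.
- **Records.**  Exclusion precedence is land → outside satellite extent →
  deeper than 500 m, so counts are deterministic; "outside the extent" uses
  the intersection of the Kd490 and PAR grids, and points off the grid
  entirely fall into this class as well.  Record depth comes from the
  bathymetry grid unless the input CSV carries a finite `depth_m` column,
  which is then preferred and flagged.  Classification mirrors the zone's
  inclusive thresholds, so "within" agrees exactly with the mask.

## The synthetic basin

The generator produces a 10° × 6° basin at 0.02° (≈ 2.2 km) resolution —
300 × 500 cells, sized so the full pipeline runs in seconds — with the
large-scale structure of the real inputs: `Kd490` spanning 0.05–0.25 m⁻¹
and decreasing along a NNW→SSE axis, surface PAR spanning 30–42 mol photons
m⁻² day⁻¹ and increasing toward the SE, a northern land strip (8 % of
rows), a bathymetric ramp of 2.5 m/km down to a 3000 m floor, and a ~5 km
coastal strip where the satellite fields are masked.  Smooth seeded noise
(Gaussian-filtered, σ = 5 cells) is added to both satellite fields and
clipped to the stated ranges; a single seed fixes everything.  Occurrence
records are drawn at cell centers (so nearest-cell extraction is
unambiguous) from strata of known status, giving exact ground truth.

A constant-optics variant with a linear bathymetric ramp provides the
closed-form oracle used throughout the tests: with `Kd490 = 0.1` and
`E0 = 40`, the zone is exactly the strip of cells whose center depth lies
in `[30 m, z*]`, `z* = ln(E0/e_min)/KdPAR ≈ 91 m`, and its spherical area
has an analytic expression the delineated area must match to within one
cell row.

What the fixtures do **not** emulate: real coastline geometry, seasonal and
interannual variability, cloud-driven gappiness patterns, correlated
bathymetric roughness, or steep-wall seabed whose true surface exceeds its
horizontal projection.  Passing tests therefore demonstrate correctness of
the computational chain under the stated model, not skill against in-situ
irradiance; with the real multi-year archives the same code reproduces the
published basin-scale figures only to within their sampling errors, and
slope-driven area underestimation remains uncorrected by design.

## Known limitations

- The polynomial's inverse term makes `KdPAR` unreliable in extremely clear
  water near the validity floor; masked cells shrink the mapped zone there.
- Cell-center membership and nearest-cell extraction introduce half-cell
  discretization everywhere; the border invariants in the tests quantify
  the resulting bands (e.g. lower-border irradiance within
  `e_min·e^(±KdPAR·Δz)` for one cell's depth increment `Δz`).
- The 20-km chains restart at each border polyline; with fragmented masks
  the sample density along short fragments is slightly higher than along
  one continuous border.
- No spatial-autocorrelation correction is applied to the rank tests, and
  none is attempted for neighbouring border samples.
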