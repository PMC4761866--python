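# Methods

This note documents the models behind `isohome`, the assumptions baked into
each, the parameters that matter, and what the synthetic test scenarios do
and do not establish about the real system.

## Geomagnetic field model

The main field is the standard internal spherical-harmonic expansion: on the
reference sphere r = a = 6371.2 km,

    V = a Σ_{n=1}^{N} Σ_{m=0}^{n} (g_n^m cos mφ + h_n^m sin mφ) P_n^m(cosθ),
    B = −∇V,

with Schmidt quasi-normalized associated Legendre functions computed by
stable upward recurrence in degree, and the seven standard elements
(X, Y, Z, H, F, I, D) derived from B.  Coefficients are tabulated per epoch
and interpolated linearly in time (the IGRF convention); beyond the last
epoch, tabulated secular-variation rates extrapolate linearly (zero rates
when absent, i.e. the field is held).

Numerical choices:

* evaluation is **geocentric at fixed radius a** — no geodetic↔geocentric
  conversion.  The ellipticity correction is a ~0.2 % effect on element
  values and far below the grid resolution of any isoline analysis here;
  this is a documented simplification, not an oversight.
* latitudes are clipped to ±89.9999° internally so the 1/sin θ factor in
  the east component never blows up at the poles.
* the synthesis is validated two independent ways in the test suite: exact
  closed forms for an axial dipole (F = |g₁⁰|√(1+3 sin²λ), tan I = 2 tan λ)
  and a brute-force oracle that evaluates the potential termwise via
  `scipy.special.lpmv` and takes B = −∇V by finite differences; agreement
  is required to 1e−9 and 1e−8 relative respectively.

### The bundled coefficient table

`isohome/data/igrf_early_epochs.txt` carries the 1900.0–1925.0 epochs at
5-year spacing, truncated at degree 8, with the weakly-constrained degree-7/8
terms held at their 1900 values and no SV column.  It was **transcribed from
reference knowledge of the published IGRF tables** (the authoritative
machine-readable file could not be redistributed here), so isolated
transcription errors in mid-degree terms cannot be excluded.  The historical
drift distances computed from it (85 km for 1900→1905, 413 km for
1900→1925 at Ascension) therefore carry fixture uncertainty of order
10–20 % beyond the grid resolution; the 25-year figure reproduces the
literature-scale value (~350 km), while the much smaller published 5-year
figure (~5 km) is not reproduced — with this table the island's intensity
changes by ≈118 nT over 1900–1905, which no choice of distance metric maps
to a 5 km displacement.  The discrepancy is documented rather than tuned
away.

## Isoline extraction and drift

Isolines of total intensity F are extracted from a regular lat/lon raster by
marching squares (`skimage.measure.find_contours`) with linear interpolation
along cell edges.  The drift question is posed exactly as a navigating
animal would experience it: freeze the level at F(island, t₀), extract the
contour of that level at t₀+Δ, and report the **minimum great-circle
distance from the island to the drifted curve**.  The original isoline
passes through the island, so this nearest-approach metric is the natural
displacement measure; it is also the most conservative (any directional
metric is at least as large).  When a level produces several contour
components, the component nearest the reference point is used (ties broken
by length).  Default window: lat [−25°, 10°], lon [−45°, 5°] (the
Brazil–Ascension corridor) at 0.1°.

Great-circle distances use the haversine formula with R = 6371 km and the
exact cross-track construction for point-to-segment minima.  Segment chords
are interpreted as great-circle arcs; contour segments are sub-grid-cell
short, where the chord/arc distinction is far below 0.1 km.

## Synthetic input generators

All generators are pure functions of (parameters, seed).

**Ocean.**  Velocity derives from a streamfunction
ψ = −ū·y + v̄·x + Σ Aᵢ exp(−|r−rᵢ|²/2R²) on a local equirectangular plane,
so the flow is exactly divergence-free in that metric — passive plumes
neither concentrate nor evacuate, mirroring the near-incompressibility of
assimilative surface flow.  Defaults: 0.08° grid over a ~900×900 km box
around Ascension, westward mean flow of 0.15 m/s (South-Equatorial-Current
scale), 12 Gaussian eddies of radius 80 km and streamfunction amplitude
3×10⁴ m²/s (swirl speeds ~0.3 m/s, mesoscale-typical).  Depth layers get
independently seeded eddy phases over a shared mean flow, a minimal stand-in
for vertical shear.  Features of real mesoscale flow this does *not*
emulate: fronts and filaments with realistic spectra, divergent surface
currents, eddy birth/decay, coastlines.

**Wind.**  A constant vector toward a bearing (default 292.5°, WNW — the
direction the regional trade winds blow *toward*) plus spatially uniform,
temporally AR(1)-correlated gusts (default correlation time 6 h).

**Magnetic.**  A translating intensity pattern is produced by tilting the
dipole axis at a constant angular rate: a tilt of α toward the meridian
opposite the reference longitude shifts the intensity pattern north by α·a
on that meridian — a rigid rotation, hence an *exact* ground truth for
drift-recovery tests (the recovered 25-year drift of a 10 km/yr field is
250.0 km).  Zonal translation components rotate tesseral terms in
longitude.  Static degree ≤ 3 anomaly terms can be superposed to shape
(tilt/curve) the isolines; with anomalies present the translation is exact
only to first order, which the scenarios account for by measuring the
realized drift numerically.

## Particle tracking

Classical RK4 on dλ/dt = v/R, dφ/dt = u/(R cos λ), with bilinear spatial
sampling, nearest-depth layer, and either linear-in-time interpolation or
piecewise-constant "previous snapshot" fields (emulating daily-frozen 00:00
hindcast snapshots; both modes are exposed because the convention of the
original analysis is ambiguous).  Horizontal dispersion is an Euler–Maruyama
Gaussian random walk with per-axis σ = √(2·K_h·Δt); K_h defaults to
10 m²/s, a typical sub-gridscale diffusivity for ~8 km grids (the original
analysis defers its dispersion scheme to the ICHTHYOP description without a
number, so this is an explicit assumption).  Default Δt = 1 h.

Releases follow the waterborne protocol: particles uniform over a
10 km × 10 km zone centered on the island, 100 per layer at 0/10/20/30/50 m
daily from Dec 15 to Apr 29 (calendar-aware, leap days included), with
odorant lifetimes of 15/30/45 days; the airborne variant releases hourly at
0 m with a 48-h lifetime.  Particles whose RK4 stages sample outside the
velocity domain are frozen and flagged *exited* (open-boundary convention:
they no longer count as plume members); particles are removed when age
exceeds lifetime.  Snapshots pool all depth layers into one 2-D point set.

Two determinism guarantees are engineered deliberately:

* identical (schedule, field, seed) ⇒ bit-identical trajectories;
* dispersion noise is drawn for **every released particle** each step,
  alive or not, so trajectories are independent of the odorant lifetime.
  The alive-set at any instant is then exactly nested across lifetimes
  (15 d ⊆ 30 d ⊆ 45 d), which turns the qualitative claim "longer-lived
  odorants intersect isolines at least as often" into a theorem of the
  implementation — testable without any real ocean data.

## Intersection statistics

A plume snapshot intersects an isoline when any particle lies within a
buffer of the polyline; the buffer (default 10 km ≈ one 0.08° ocean-model
cell) stands in for the undefined map-overlay criterion of the original
analysis and is always reported alongside results.  Rates are snapshot
counts (10 evenly spaced waterborne snapshots per season, 5 airborne);
uncertainty is a Wilson score 95 % interval on those counts — appropriate
at n = 10–40 and verified in-suite against the closed form.  Multi-year
summaries pool per-year snapshot flags.

## Homing agents

Agents move at a fixed swim speed (default 0.6 m/s) and are not advected by
the current (the strategy logic, not drift, is under study).  Phases:

* **isoline-following** — heading along the local isoline tangent
  (perpendicular to ∇F, signed toward the travel bearing, default east)
  plus a cross-track correction ∓∇F̂ weighted by
  clip(gain·(F−F_target)/|∇F| / 10 km, ±1); on magnetic plateaus
  (|∇F| < 10⁻⁴ nT/km) the previous heading is held.  ∇F is obtained by
  central differences with a 5 km stencil — a deliberate proxy for gradient
  estimation from along-track samples.
* **plume-following** — up-flow heading (the plume streams downstream from
  the island) blended with the unit vector toward the centroid of currently
  detected particles; the blend keeps the agent near the streak centerline,
  which converges on the source.  Pure gradient-ascent toward detected
  particles is the zero-flow fallback.
* **search** — an Archimedean spiral of pitch 2× detection radius (no gap
  between passes wider than the detection diameter), entered when plume
  contact lapses > 6 h; fresh contact returns the agent to plume-following.

Mode transitions are monotone (isoline → plume ↔ search → arrived/failed);
arrival means passing within the island radius (2.5 km).  Odor detection is
binary proximity (default 10 km) to any living particle — no concentration
model, consistent with the presence/absence plume treatment.  The
**odor-only control** starts on the isoline but, having no magnetic sense,
holds a fixed compass bearing instead of tracking the line; the
**magnetic-only control** never leaves the isoline phase.  None of the
agent parameters are measured animal values; they are modelling choices
exposed in `AgentParams`.

## Standard scenarios and problem sizes

The **eddy scenario** (duration sensitivity): two seasons with
independently seeded eddy fields, 25 particles per layer per day (the full
protocol's geometry at a quarter of its density, keeping a complete
scenario in tens of seconds), K_h = 10 m²/s, scored against the isoline
drifted 100 km north of the island (4 km/yr × 25 yr) with a 10 km buffer
at 10 snapshots per season.  With seed 1 this yields intersection rates of
60 % / 85 % / 85 % for 15/30/45-day odorants — monotone by construction,
with year-to-year spread concentrated in the short-lived odorant, the same
qualitative pattern reported for hindcast-driven plumes.  The absolute
percentages are properties of the synthetic flow, not reproductions of the
hindcast values.

The **navigation scenario** (strategy comparison): the remembered isoline
drifted ~100 km past the island and tilted by a strong synthetic anomaly
(g₃³ = 2200 nT, h₃³ = 900 nT) so that it is not a parallel of latitude; a
steady 0.2 m/s northward current carries a 30-day plume across it; 200
agents start 300–600 km west of the island on the drifted isoline.  With
seed 1: dual 100 %, magnetic-only 0 % (the isoline misses the island by
40× its radius), odor-only 21 % (only agents whose fixed bearing happens
to cross the plume succeed).  The strict ordering dual > each control is
stable across seeds; the exact percentages are scenario properties.

What passing these scenarios shows: the pipeline's bookkeeping, numerics
and statistics behave as designed, and the dual-cue advantage emerges from
the modelled mechanism itself.  What it does not show: anything about real
ocean years, real plume chemistry, or what real turtles do.

## Known limitations

* Geocentric sphere, no ellipticity; external/crustal field sources absent.
* The bundled coefficient table is a transcription (see above) and spans
  only 1900–1925; full-century sweeps need a complete published table,
  which `read_coefficients` parses directly.
* Horizontal-only transport at fixed depths; no vertical advection or
  behavior during dispersal; odorant presence is a proxy for concentration.
* The Figure-style drift metric (nearest approach) is an interpretation;
  the original analysis does not define its distance measure.
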