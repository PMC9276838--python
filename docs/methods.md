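# Methods

## Scope and model chain

`rfasim` simulates an umbrella-electrode RF ablation as three one-way
coupled stages on a shared spatial grid — quasi-static electrical
conduction, Pennes bioheat transport, Arrhenius damage — driven by the
generator's recorded power trace, plus the surface-distance validation
toolkit used to compare a predicted ablation volume with a segmented true
one. The generator's impedance-control behaviour is deliberately outside
the model: the recorded power is an input, imposed exactly.

## Discretisation

Scenes are rasterised onto a uniform, isotropic, cell-centred grid
(default 1–3 mm; the spacing is a user parameter). Cells carry material
classes (tissue/agar, vessel lumen, energised metal, insulated shaft,
ground pad, outside). All operators are assembled from two edge lists:

* free–free faces with harmonic-mean conductance
  `g = h·2kᵢkⱼ/(kᵢ+kⱼ)` — exact for series conduction, so a two-material
  slab reproduces the harmonic-mean flux to round-off;
* free–Dirichlet faces with a Shortley–Weller sub-cell factor
  `g = k·h/θ`, where `θ ∈ (0.05, 1]` locates the true boundary along the
  edge by bisection on the scene's signed-distance function (when the
  scene provides one; staircase labelling otherwise).

Interior rows sum to zero (discrete conservation) and the operator is
symmetric positive definite. Thin tines are sub-grid: cells within the
wire radius of a tine polyline are labelled energised metal, a documented
resolution-dependent approximation. The insulated shaft is labelled metal
but excluded from the energised set (its electrical conductivity is set
six orders below tissue).

The cell-centred placement matters for small electrodes: with the
electrode surface falling between cell centres, the embedded-boundary
correction holds the computed spreading resistance of a 1 mm sphere to
under 1 % at 1 mm spacing, where node-centred labelling gives ~8 %.

## Electrical stage

`∇·(σ∇V) = 0` with Dirichlet `V₀` on the electrode set, 0 on ground, and
natural (insulated) conditions elsewhere, solved by Jacobi-preconditioned
conjugate gradients. Joule power is accumulated per edge as `g(ΔV)²` and
split between the endpoint cells, so the domain integral of the power
density equals the total dissipated power *identically*; the effective
impedance is `V₀²/P`. Each control interval, one unit-potential solve is
rescaled by `P_rec/P_unit` (potential by the square root), so the
delivered power matches the record to round-off at every step.

Temperature-dependent conductivity `σ(T) = σ₀(1 + β(T−T₀))` is available
(default β = 0, i.e. off) with a re-solve triggered when the temperature
has moved more than 5 °C since the last factorisation.

Multiresolution benchmarking: the spreading-resistance benchmark solves
coarse-to-fine with nearest-cell warm starts and a loose fine-level
tolerance (1e-3). The resistance is the Dirichlet energy functional of
the solve and therefore quadratically insensitive to solution error; we
verified the reported resistance moves by <0.01 % between tolerances 1e-3
and 1e-5.

## Thermal stage

Backward Euler (unconditionally stable; the step, default 0.5–1 s, is
matched to the 1 Hz power log held by zero-order hold) on

ρc_eff ∂T/∂t = ∇·(k∇T) + q − wρ_b c_b (T − T_a) + vessel-wall flux.

* **Perfusion** applies only in tissue-class cells; agar phantom runs use
  w = 0 (the phantom has no perfusion).
* **Vessels with flow** act through a convective Robin wall flux with
  `h = Nu·k_f/d`, Nu = 3.66 (laminar, constant wall temperature; the
  bench condition — 5 mm channel, 10.5 cm/s water — has Re ≈ 525), in
  series with the half-cell tissue conductance. Flowing lumen cells are
  tied to the inflow temperature: at 10.5 cm/s the transit time through
  the heated region is ~1 s, far shorter than the heating timescale.
  Zero flow degrades the lumen to an ordinary conducting region. Resolved
  lumen advection is out of scope.
* **Evaporation** is an enthalpy band: between 99 and 101 °C the
  effective volumetric heat capacity is augmented by
  `L·w_water·ρ/ΔT_band`. Because the implicit solve lags the capacity at
  the old temperature, a post-solve step re-maps each cell's received
  energy through the piecewise-linear enthalpy curve, so a step that
  would jump across the band still absorbs the correct latent load. A
  hard ceiling at band-top + 5 °C bounds the temperature; discarded
  energy is booked in the ledger. The band formulation is this package's
  own choice of a standard method; vendor implementations differ.
* **Energy ledger.** Every step accumulates source energy in, perfusion/
  vessel/boundary outflow, clamp discard, and stored enthalpy in a
  scheme-consistent way; closed systems balance to round-off and full
  phantom runs close to ≤1e-6 relative.

Checked closed forms: a uniformly heated, insulated, perfused block
follows `T_a + q/(wρ_b c_b)` relaxation with time constant
`ρc/(wρ_b c_b)` to <0.1 %; a two-material slab with fixed face
temperatures reaches the harmonic-mean steady flux to round-off; halving
dt shows first-order temporal convergence with no oscillation at dt = 1 s.

## Damage stage

`Ω(x,t) = ∫A·exp(−E_a/(R·T_K)) ds`, integrated trapezoidally alongside
the thermal march (all damage math in kelvin). Defaults A = 7.39×10³⁹ 1/s
and E_a = 2.577×10⁵ J/mol, the liver-coagulation pair standard in RF
ablation modelling; both are configuration, not code, as is the threshold
Ω\* (1 ≈ 63 % kill by default, 4.6 ≈ 99 % available). The ablation
surface is the Ω = Ω\* iso-surface by marching cubes on the zero-padded
damage grid (always closed), with the enclosed volume by the divergence
theorem on the triangulation (within 2 % of the closed form on the
analytic radial field `Ω = 2e^{−r²}`).

## Validation toolkit

* **Segmentation**: Otsu-initialised morphological Chan–Vese (region-based
  level set) on grayscale slice scans, largest region kept, holes filled,
  sub-pixel boundary via marching squares on a lightly smoothed
  indicator; output in mm. On seeded synthetic scans (disc and
  disc-with-bite, contrast 0.5, noise σ = 0.05) the boundary is recovered
  to ≲0.25 px RMS. 3-D truths enter as label masks; re-implementing
  manual CT segmentation is a non-goal.
* **Equidistant sampling**: exact arc-length division for 2-D contours
  (64 points by convention); for surfaces, area-weighted sampling plus a
  blue-noise-style repulsion relaxation reprojected to the mesh
  (~10 000 points by convention; on a unit sphere the mean
  nearest-neighbour spacing lands within ~6 % of the uniform value with
  CV ≈ 8 %).
* **Surface error**: exact point-to-triangle (or point-to-segment)
  distances; candidates pruned by a KD-tree over triangle centroids with
  a radius bound that provably cannot miss the minimum. The direction is
  true→model by default, recorded in the report, and never swapped
  silently. Summary statistics are the mean and the maximum; per-case
  maxima feed the paired comparison.
* **Chart comparator**: two half-ellipsoids sharing the equatorial
  radial semi-axis, poles and equator represented exactly (UV
  triangulation), positioned by the electrode pose. The shipped table
  has the published 3 cm row (proximal depth 9 mm, distal 16 mm, radial
  semi-axis 15 mm); other diameters require a user-supplied table.
* **Pose recovery**: Kabsch least-squares rigid fit on the tip plus
  arc-length-matched tine samples; degenerate (collinear) sets are
  rejected. Exact round-trip on noiseless inputs; ~0.1 mm translation
  error under 1 mm point noise.
* **Paired test**: classical two-sided paired t (via scipy, verified
  against the closed form in tests); zero-variance differences raise a
  degenerate-case error instead of returning a meaningless p.
* **Tine detection**: metal-range threshold, seeded connected component,
  3-D skeletonisation, Dijkstra walks from the tip to each branch
  endpoint, azimuthal ordering. Deflection is reported as the distance of
  the measured distal endpoint from the nearest ideal tine curve — the
  endpoint is where tines deflect most and is insensitive to skeleton
  jitter, whereas a max-along-path metric is dominated by it.

## Synthetic fixtures: what they emulate and what they do not

The fixtures reproduce the *geometry and signal structure* of the
validation experiments: a two-litre beaker (r = 62 mm, h = 166 mm) with a
bottom return pad and a 4 cm, 10-tine electrode at mid-height; optional
5 mm vertical water channels at 25/30/35 mm from the shaft carrying
10.5 cm/s room-temperature water; 1 Hz power logs ramping over 30 s to a
90 W plateau for 5 minutes (an optional roll-off dip is available);
noisy grayscale "scans" of known boundaries; CT-like volumes with painted
(optionally deflected) tine curves. All are bit-deterministic under a
seed.

They do not emulate: scanner physics (beam hardening, partial volume),
real agar chemistry or albumin coagulation kinetics, generator
impedance-control dynamics, breathing/deformation, or perfusion
heterogeneity. Passing tests therefore demonstrate the correctness of the
numerical chain and its qualitative physics (power matching, heat-sink
indentation, energy balance), not clinical accuracy on real images — the
published bench and porcine error tables cannot be recomputed without the
original scans and CT volumes, which are not deposited.

## Numerical choices and degenerate inputs

* CG tolerances: 1e-8 (electrical), 1e-10 (thermal, warm-started each
  step); θ clamped at 0.05 to bound boundary-face conductance.
* Dirichlet edges in the thermal stage are insulated by default (tine
  metal is thin, the pad is outside the agar); explicit fixed boundary
  temperatures are available and used by the slab benchmark.
* Zero-power steps, empty super-threshold damage regions, zero-flow
  vessels, and blank images are all defined, non-error or cleanly-erroring
  paths (an empty ablation volume is a flagged result, not a failure).
* Ideal tines are circular arcs (turning angle 160° by default) in
  azimuthal planes — the vendor's true curve is proprietary; deployment
  scales the arc about the tip so the radial extent is
  `deployed_fraction × nominal_diameter/2`.
* The 25/30/35 mm vessel offsets are interpreted as shaft-axis to
  channel-centerline distances (configurable by passing a positioned
  `VesselSpec`).
* Problem sizes in the shipped benchmarks (1.5 mm heat-sink study,
  2.5–3 mm pipeline checks, 1 mm/0.5 mm sphere study) were chosen as the
  coarsest grids on which each property is cleanly resolved.

## Known limitations

* Sub-grid tine labelling makes near-tine power density
  resolution-dependent; total power is exact by construction, but its
  spatial concentration near the wires sharpens under refinement (the
  ablation volume moved ~40 % between 2.5 mm and 1.5 mm in the phantom
  study).
* The near-field potential of electrodes comparable to one cell in size
  is under-resolved pointwise (the integrated resistance is accurate to
  <1 %; the local 1/r profile within ~2 cells of a 1 mm electrode is
  not).
* No vapour mass transport (`--vapor-transport` is reserved,
  experimental, unimplemented); no tissue shrinkage or deformation; no
  frequency-dependent (full Maxwell) electromagnetics.
* The manufacturer-chart table contains only the 3 cm entry.
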