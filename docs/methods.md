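# Methods

This note records the modelling choices behind `clotflow`: the governing
equations and their assumptions, the parameters that matter and their
defaults, what the synthetic data does and does not emulate, and the
numerical decisions made where the design was genuinely open.

## Physical model

Blood is treated as an incompressible Newtonian fluid with averaged
properties µ = 4.0 cP and ρ = 1.06 g/cc; at arteriole scales
(d = 30–100 µm, centerline speeds ~1300 µm/s) the Reynolds number is
ρ(U_peak/2)d/µ ≈ 10⁻³–10⁻², so inertia is nearly negligible and the flow
responds quasi-statically to the moving clot. Flow through the clot
interior is modelled with the Brinkman extension of Darcy flow: the
momentum equation carries a drag term −(µ/K)u wherever the clot indicator
marks a node, so a single velocity–pressure field covers lumen and clot.

The clot is a heterogeneous porous body with two compartments derived from
the imaging channels: a tightly packed core (P-selectin) and a looser
shell (CD41 minus core). Each carries a constant porosity and effective
solute diffusivity:

| region | φ (WT) | φ (diYF) | D (WT) | D (diYF) |
|--------|--------|----------|--------|----------|
| core   | 0.2    | 0.2      | 0.4 µm²/s | 0.5 µm²/s |
| shell  | 0.3    | 0.4      | 0.8 µm²/s | 1.0 µm²/s |
| lumen  | 1.0    | 1.0      | 60 µm²/s  | 60 µm²/s  |

These literature-based values express strongly hindered diffusion inside
the clot relative to free plasma (cAlb). Core values take precedence where
the regions overlap, and the core membership is clipped to the overall
membership.

Permeability follows the Kozeny–Carman relation K = φ³/(150(1−φ)²), which
as printed is dimensionless. The Brinkman term needs an area, so the
package multiplies by L_ref² with L_ref = 3 µm by default — the platelet
length scale, on the argument that platelets are the grains of the packed
bed. L_ref is config-exposed; doubling it multiplies intra-clot speeds by
four and divides the pressure drop accordingly, so any quantitative use
against measured pressures should calibrate it.

The moving clot never deforms the mesh. A fixed structured triangulation
of the channel (with an optional circular-arc bite in one wall at the
injury site, where the laser locally deforms the lumen) carries nodal
indicator fields recomputed each sub-step — the fictitious-domain
viewpoint. One-way coupling only: the imaging dictates the clot kinematics
and the flow responds; no clot material model is used or needed.

## Image processing and geometry

The segmentation chain is binarize → median → Gaussian → k-means (k = 2)
→ Canny → largest-perimeter connected edge component. Notable choices:

- Default binarization is Otsu's rule; a percentile rule is exposed for
  sensitivity studies. Constant frames are flagged as failures.
- k-means runs on the denoised grayscale frame with background suppressed
  by the binary mask, 10 restarts, fixed seed. Clustering operates on the
  ≤256 unique intensity values weighted by counts, which makes it exactly
  deterministic and independent of image size.
- Component perimeter = edge-pixel count; ties break by convex-hull area,
  then lowest centroid row. Spur pixels (degree-1 chains) are pruned off
  the edge ring before ordering; ordering is a nearest-neighbour walk with
  ≤2 px gap bridging and backtracking, with a polar-angle fallback when the
  walk cannot close (exact for star-shaped boundaries).
- Interior pores are deliberately retained: only the outer envelope loop
  is returned.

Boundary loops are fitted with periodic cubic B-splines. The smoothing
budget adapts to the input's stair-step roughness (estimated from local
second differences) so pixelated loops are ironed flat while smooth inputs
round-trip to a fraction of a pixel; a hard cap keeps the curve within one
pixel of the data. Temporal interpolation matches points of equal polar
angle about each frame's centroid (180 rays by default; the nearest
intersection is taken along each ray, which stays single-valued on
non-star-shaped boundaries) and interpolates matched points linearly. The
default sub-stepping n_sub = 11 gives 0.05 s solver steps at the 0.55 s
frame interval. Aspect ratio is defined as √(λ_max/λ_min) of the enclosed
region's second-moment tensor — rotation-invariant and equal to a/b on an
ellipse; the plotted rates are central differences of a 5-frame moving
average, which suppresses frame-to-frame imaging jitter. Frames whose
segmentation failed are filled by interpolating the matched angular
samples of the nearest good frames.

## Domain marking

The Laplace point-set method seeds I = 1 on every node of an element
containing a boundary sample point and I = 0 on the outer domain boundary,
then solves ∇²I = 0 once (a single symmetric sparse solve, much cheaper
than a flow step) and thresholds at 1 − ε with ε = 10⁻². Two refinements
proved necessary:

- The raw seeded ring spans one element layer on both sides of the true
  curve, biasing the marked area outward by O(h) with a coefficient near
  one (+40% for a circle at h = r/6). Seeded members touching a
  non-member neighbour are therefore eroded, after which the marked area
  matches πr² to ~4% at h = r/6 and ~2% at h = r/10 and the disagreement
  with an even–odd point-in-polygon oracle stays within one element layer.
- Where the clot bulges through the injured wall, the outer-boundary
  Dirichlet I = 0 wins on wall nodes, but boundary samples falling outside
  the mesh are snapped to their nearest mesh nodes so the wall-adjacent
  elements are seeded (and the erosion ignores wall neighbours). Without
  this, a spurious one-element free channel opens beneath wall-hugging
  clots and the flow tunnels under the clot instead of accelerating over
  it.

## Flow and transport discretization

Equal-order linear velocity–pressure triangles with SUPG/PSPG
stabilization; the stabilization time scale is

τ = [(2/Δt)² + (2|a|/h)² + (4ν/h²)² + (σ/ρ)²]^(−1/2)

with element advection a, longest-edge h, and Brinkman reaction σ = µ/K.
Including the reaction term gives the correct stabilized-Darcy limit
inside the clot, where σ/ρ reaches ~10⁹ s⁻¹ and the momentum balance is
essentially Darcy's law. A grad-div term with coefficient ν adds mass
conservation robustness. Time integration is backward Euler; the
convective term is Picard-linearized (tolerance 10⁻⁶, max 25 iterations —
at these Reynolds numbers 1–3 iterations suffice). Transient and reaction
mass terms are lumped, which keeps the reaction positive near the sharp
clot interface. The solve runs in SI units internally; geometry enters in
µm, velocities return in µm/s and pressures in Pa. The inflow is steady by
default (the imaging provides a single averaged centerline velocity); an
optional sinusoidal modulation flag exists but is off.

Verified limits: plane Poiseuille is recovered at h = d/20 to <2% in both
the velocity profile and the interior pressure gradient; a uniform φ = 0.2
slab spanning the channel satisfies the 1D Darcy balance Δp/L = (µ/K)·u in
its interior to <1%, with plug-like uniform interior velocity (the √K
boundary layer, ~0.03 µm, is far below resolution and intentionally not
resolved).

Transport uses the non-conservative advective form with φ-weighted storage
and diffusion, SUPG, and a continuous-interior-penalty term on
inter-element gradient jumps with coefficient 0.01, scaled by the local
advective speed. The |u|-scaling means the scheme reduces to plain
Galerkin diffusion in a closed quiescent box, where the φ-weighted mass is
conserved to round-off (verified to 10⁻¹⁰ relative). Inlet carries c = 0,
walls are no-flux, the outlet is purely advective. A Gaussian blob in
uniform flow advects at exactly |u|·t at cell Courant numbers ≲1; at
Courant ~4 the implicit scheme's phase error reaches a few percent, which
bounds the useful sub-step size for fast flows. Concentration overshoots
beyond ±0.05 trigger a warning with the cell Péclet number.

## Quantification

Traction on the clot integrates σ·n = (−pI + µ(∇u + ∇uᵀ))·n over the
boundary polyline with midpoint quadrature; velocity gradients are the
linear-element gradients of the containing triangle, consistent with the
non-body-fitted solve. Pressure and viscous parts are reported separately
and as a vector sum; forces are per unit out-of-plane depth in nN/µm. The
phase portrait plots the magnitude of the vector sum (the sum of the part
magnitudes is also emitted). Sanity identities: zero force on a closed
curve in a constant-pressure quiescent field (to round-off), and
near-zero net force on a fictitious curve enclosing pure fluid (momentum
balance; observed ~10⁻⁴ of the force on an equal-sized porous plug).

Embolization is detected as the first run of ≥3 consecutive checkpoints
with negative smoothed d(area)/dt whose start lies within 5 checkpoints of
the running force maximum; the reported index is the steepest raw
single-checkpoint area decrease inside the run's smoothing window, which
pins a clean step reduction to its exact drop frame. All three constants
are config-exposed. The detector produces no false positives on
monotone-growth schedules with mild noise.

The sensitivity stage draws a seeded Latin-hypercube sample over
segmentation parameters and reports the time-averaged coefficient of
variation of area and aspect ratio across samples. The default
binarization-percentile window (70, 88) is derived from the synthetic
intensity model: the upper edge is the background/foreground rank gap of
the smallest clot in a typical stack (~10% pixel fill), the lower edge
sits in the upper background tail. Windows that cut into the foreground
distribution destabilize the chain and are not meaningful operating
points.

## Synthetic data: what it does and does not emulate

The generator renders 8-bit frames with foreground ~N(180, 30) inside the
scheduled ellipses, background ~N(30, 10), and isolated salt pixels at 255
outside the clot (density 0.02 by default, <0.1 enforced) — i.i.d. per
pixel, bit-reproducible per seed. Growth schedules are linear or
saturating (T(1 − e^(−t/T))) with optional aspect drift, centroid jitter,
and a step area drop for embolization; the core is a scaled copy of the
overall ellipse. Default pixel size 0.5 µm (the source imaging never
states one), frame interval 0.55 s, ~30–300 frames. The cAlb channel adds
a stagnation pool at the injury indentation for qualitative use only.

Not emulated: point-spread functions, photobleaching, depth effects,
non-elliptical or multi-lobed clots, intensity gradients within the clot,
and correlated (structured) noise. Consequently the accuracy figures
measured here (segmentation error ~1%, interpolation distance ~0.07 µm)
are best-case values for images whose noise is spatially white; real
intravital stacks with textured background and irregular clot outlines
should be expected to sit closer to the 10%/1 µm bounds the tests enforce.

## Problem sizes and defaults

Tests and the acceptance script use desk-scale problems chosen for a
single CPU: images of 100–200 px per side over 20–36 frames, meshes of
~900–1700 nodes (h = d/20 = 2.5 µm for a 50 µm vessel), 30-sample LHS
sweeps, and coupled runs of a few dozen sub-steps. All sizes scale up
linearly through the configuration; the direct sparse solver remains
practical to ~10⁵ unknowns.

## Known limitations

- 2D only; the spline/ray machinery would need point-cloud morphing for
  3D reconstructions.
- One-way coupling: no clot material model, no yield-stress or inverse
  identification.
- Single straight vessel; no branches, no extravascular leakage — force
  magnitudes would drop if flow could reroute.
- Kozeny–Carman with a single L_ref is a crude permeability model for
  fibrin-rich clots.
- The embolization detector is a heuristic on smoothed kinematics; abrupt
  partial sheds smaller than the smoothing window can be missed.
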