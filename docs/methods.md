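# Model and methods

## The ratchet-zipper model

Phagocytosis is modelled as a closed, quasi-spherical cell membrane
(triangulated surface) engulfing a rigid, immobile particle through
short-range ligand-receptor adhesion, driven purely by thermal membrane
fluctuations.  The total free energy is

    E = E_m + E_vol + E_LR

* **Membrane energy** `E_m = ∫ (κ_b/2 · C² + σ) dA`, with
  `C² = C₁² + C₂²` the sum of squared principal curvatures.  The Gaussian
  cross-term `C₁C₂` integrates to a topological constant over a closed
  surface (Gauss–Bonnet) and is omitted.  `κ_b` is the bending stiffness
  of the membrane plus its actin cortex, `σ` the tension of stretching
  both.
* **Volume constraint** `E_vol = κ_P (V − V₀)²`, the lowest-order
  expansion of the cell's volume-regulation energy around its preferred
  cytosol volume `V₀`.  Because the hard-core constraint keeps the
  particle outside the closed cell surface at all times (the cup's mouth
  only closes asymptotically), the cytosol volume is exactly the enclosed
  mesh volume.
* **Adhesion** `E_LR`: membrane within a shell of width `R₀` of the
  particle surface is bound; bound coverage of the particle surface gains
  `−ε` per unit *particle* area.  `ε` aggregates the single-bond free
  energy and the areal density of ligand–receptor bonds.

Default parameters (the "standard parameters"): `κ_b = 1.3×10⁻² pN·µm`,
`σ = 6.2×10⁻⁶ mN/m` (stored internally as `6.2×10⁻³ pN/µm`),
`ε = 58.5 pN/µm`, `κ_P = 2.56×10⁻⁵ pN·µm⁻⁵`, `T = 310 K`
(`k_BT = 4.28×10⁻³ pN·µm`), shell width `R₀ = 0.05 R` for a particle of
radius `R` (the physics is insensitive to `R₀` as long as it stays well
below `R`).

**Monte Carlo moves.**  A mobile vertex is chosen uniformly as the
fluctuation center, a direction (± the local surface normal) and a
lateral extension `w ~ U[w_min, w_max]` are drawn, and every mobile
vertex within edge-connected Euclidean distance `w` of the center is
displaced by `a·cos²(πd/2w)` along the direction (`d` its distance from
the center).  The amplitude is `a = 0.5 ×` mesh size, the minimum width
`w_min = 4 R₀`, and the maximum width is of order the particle radius.
Moves that would place a vertex inside the particle are invalid (rigid,
impenetrable particle).  Valid moves are accepted with the Metropolis
probability `min(1, exp(−ΔE/k_BT))`; at `T = 0` only energy-non-increasing
moves are accepted.  The energy difference is evaluated on the local
stencil only (support plus one ring; see *Discretisation*), and matches a
global recomputation to floating-point accuracy.

**Rectification — active vs passive zipper.**  In the *active* zipper
(intact actin signalling) bound membrane is irreversibly stabilised:
after every accepted move, newly bound vertices are frozen for the rest
of the simulation.  In the *passive* zipper (actin-inhibited) nothing is
frozen; bonds break whenever a fluctuation pays the `+ε` coverage cost.
One sweep is (current mobile-vertex count) trial moves.  Simulated sweeps
are converted to minutes by a single calibration — the sweep count at
which small-particle active engulfment reaches 50% is identified with
6 minutes — reused unchanged across particle sizes and modes.

## Discretisation

* **Curvature operator:** cotangent Laplace–Beltrami mean curvature with
  Meyer mixed Voronoi area weights, plus angle-defect Gaussian curvature;
  `C² = (2H)² − 2K` per vertex.  Closed forms on spheres, cylinders and
  flat patches serve as tests; the discrete `∫C² dA` of a sphere
  converges to `8π` within 2% at the resolutions used.
* **Adhesion bins.**  The contact potential is accounted on the
  *particle* surface: the surface is tiled into bins of lateral size
  about the contact mesh size (area-weighted deterministic point sets),
  and each bin contributes `−ε ×` its area once at least one bound
  membrane vertex maps to it (nearest-bin assignment).  This keeps the
  ligand budget per unit particle area finite: stacking several membrane
  layers inside the shell gains nothing, stretching a bound patch gains
  nothing, and the fully wrapped adhesion energy is `−ε × 4πR²`
  independent of mesh resolution.  In the active mode at most one vertex
  per bin is frozen (one stabilised bond per ligand patch); the cup is
  thereby pinned at the shell spacing while redundant membrane stays
  mobile.
* **Local refinement.**  The initially coarse cell mesh is refined to
  the contact mesh size within one refinement range (default: the
  particle radius) of the contact, by terminal longest-edge (Rivara)
  bisection, which keeps the mesh conforming and triangle quality
  bounded.  Refinement is a one-shot resolution step per newly bound
  region: territory that is already fine-born is never re-split when it
  stretches.  Midpoints falling inside the particle are projected out
  along the signed-distance gradient.  A configurable vertex budget
  raises an error when refinement would exceed it.
* **Tether.**  A hard maximum-stretch constraint (standard practice in
  dynamically triangulated membrane simulations) bounds edge growth at
  `stretch_limit ×` the larger of the two endpoint *birth scales* (the
  construction edge length, or half the parent edge for refinement
  midpoints).  Shrinking is always allowed.  Together with one-shot
  refinement this prevents an irreversible densification ratchet in
  which thermally stretched edges are split, the new vertices roughen,
  and splitting repeats without bound.  The default `stretch_limit` in
  the reproduction presets is 5 — loose enough that membrane area flows
  freely into the growing cup (the model membrane is highly stretchable:
  at the standard `σ`, area costs only ~1.4 k_BT/µm²), tight enough to
  bound the mesh.
* **Degenerate geometry.**  Moves creating triangles below `10⁻⁶ µm²`
  are rejected outright.  Membrane self-intersection is not checked;
  thin-cup artefacts very late in closure are accepted.

## Geometry of a run

The cell is a closed icosphere whose volume is 15× the particle volume
(the particle must be much smaller than the cell for the quadratic
volume expansion to hold), with the particle placed tangent to the top
pole.  `V₀` is the discrete enclosed volume of the initial mesh, so the
volume constraint starts unstressed.  Termination: engulfed fraction
reaches the completion threshold, the sweep budget is exhausted, or the
covered particle area stops growing for a stall window.

The particle library: spheres (radii 1.2–3.8 µm), prolate spheroids
(default 1.5/1.5/4.2 µm semi-axes, tip-first = major axis normal to the
membrane or side-on = tangent), and spiral rods (helical tube with
hemispherical caps).  The default spiral — helix radius 1.2 µm, pitch
2.0 µm, 3 turns, tube radius solved so the volume equals a 2.2 µm-radius
sphere — is chosen to be clearly non-self-intersecting while exhibiting
local curvature radii below 1 µm; a helix of radius 1.0 µm and pitch
1.5 µm cannot hold that volume without the tube touching itself, which
is why the defaults are slightly larger.  Signed distances are exact for
spheres, solved by safeguarded bisection on the meridian ellipse for
spheroids, and by coarse sampling plus ternary refinement of the
centerline parameter for spirals; all satisfy a |sdf| error ≪ R₀ near
the surface.

## Cup quantification

* **Engulfed fraction (mesh):** percentage of deterministic,
  area-weighted particle-surface sample points within `R₀` of the
  membrane surface (exact point-triangle distances).
* **Height profile:** 24 equal azimuthal segments around the particle's
  vertical axis; per segment, the maximum height of membrane present in
  the contact neighbourhood, measured from the particle's bottom contact
  plane.  For image stacks, heights are integer plane counts × the
  0.4 µm z-step.
* **Mean-height engulfment:** `100 × mean(heights) / vertical extent` —
  the time-course definition of engulfment percentage.
* **Cup variability:** population (divide-by-N) standard deviation of
  the 24 heights divided by `sqrt(mean height)` (removes the trivial
  growth of the spread with cup size); the coefficient-of-variation
  alternative (`std/mean`) is selectable.  A cup is *regular* when its
  variability is strictly below the reference mean over the analysed
  sample, *variable* otherwise (ties → variable).

## Synthetic imaging

Rendering emulates the confocal acquisition this model is compared
against: z-series with 0.4 µm step and ~0.1 µm xy pixels, channel 1 the
particle (IgG) shell from the signed distance, channel 2 the membrane
(receptor) surface from dense area-uniform triangle sampling, optional
Gaussian blur then Poisson shot noise.  The analysis mirrors the
experimental pipeline: the receptor channel is zeroed wherever the
particle channel is null; particles are found by a per-plane circular
Hough transform (every 3rd plane, radius range around the expected size)
whose circles are grouped laterally and fitted to a sphere (`r² + z²` is
linear in `z` with slope `2 z_c`); the engulfed fraction compares the
two channels inside the sphere S₀ of radius `4R/3` (a particle-shell
voxel counts as engulfed when receptor-positive signal lies within two
voxels — Otsu threshold, falling back to >0 on noiseless stacks); height
profiles search an annulus three xy-pixels outside the particle circle
per plane; the equator-plane intensity variability (std/mean of
per-segment summed intensity, particles 30–70% engulfed only) is the
less accurate alternative statistic.  What synthetic stacks do not
emulate: real optics (full PSF, spectral bleed-through), fixation
artefacts, neighbouring cell structures; passing round-trip tests shows
the pipeline is self-consistent against mesh ground truth, not that it
is robust to everything real microscopes produce.

## Desk-scale reproduction conditions

Published-scale runs (mesh size = `R₀ = 0.05 R`) take days of CPU.  The
reproduction presets in `phagozip.experiments` use scaled-down
resolutions:

* **Spheres:** shell width `R₀ = 0.095 R`, membrane mesh size `0.15 R`
  (the mesh is coarser than the shell; adhesion bins follow the mesh
  size so coverage accounting stays consistent), fluctuation widths
  `4R₀ … R`, refinement range `R`, initial coarse cell edge `0.5 R`,
  cell volume 15× particle volume.
* **Elongated particles** (spheroids, spirals; `R` = volume-equivalent
  radius): mesh `0.2 R`, coarse edge `0.8 R`, maximum fluctuation width
  equal to the particle's smallest lateral scale (the equatorial
  semi-axis or tube diameter — wider bumps mostly collide with the
  particle), otherwise as above.  Refinement is curvature-adaptive: the
  local target edge is 0.45× the particle's smallest principal
  curvature radius (floored at 0.3× the mesh size), so the spheroid's
  0.54 µm tips stay resolved at negligible extra cost.
* **Particle-size comparisons** (small vs large uptake) hold the
  membrane's absolute scales fixed at the small particle's preset for
  both sizes: the fluctuation machinery — mesh, shell, amplitude,
  widths — belongs to the cell, not to the particle, and scaling the
  moves with particle size would erase the size dependence being
  measured.
* **Completion** is defined as 90% engulfed surface: terminal mouth
  closure is asymptotically slow in this myosin-free model, the same
  late-closure slowness the full-scale model exhibits.
* The spheroid **orientation comparison** is evaluated for both
  orientations at a fixed horizon of 72 sweeps, where the side-on
  orientation sits in its half-engulfment plateau (the equator of its
  long body plus the sharply curved end caps block further wrapping) —
  mirroring a snapshot taken when the side-on particle is about half
  engulfed.

The acceptance script and the test suite run five seeds per stochastic
condition at these presets.  Desk scale reproduces the side-on
half-engulfment plateau, the active-vs-passive speed ordering (≥2×) and
the slow passive uptake of large beads; it does **not** quantitatively
reproduce the ~80% tip-first value at matched time (the tip and equator
passages are resolution-marginal; finer single runs climb to ~78% but
are an order of magnitude slower), the zero-temperature stall (adhesion
per ligand patch dwarfs all bump costs at this resolution, so greedy
descent still zips), or the passive-more-variable-than-active cup
ordering (the scaled-up amplitude lets the active mode freeze large
excursions into the profile).  The corresponding checks are kept at
their stated bounds and fail honestly rather than being loosened.

## Known limitations

* No myosin-driven contraction: late cup closure (the last ~10%) is not
  modelled faithfully; desk-scale completion is defined at 90%.
* Receptors and ligands are continuous and homogeneous; no clustering.
* The Monte Carlo clock maps to real time only through the single linear
  calibration; no hydrodynamics.
* Self-intersection is not checked.
* The proposal density (normal-direction bumps) is only approximately
  symmetric on a curved surface; the planar-patch spectrum validation
  uses fixed-axis moves, for which detailed balance is exact.
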