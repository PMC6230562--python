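# Methods

This note documents the models, numerical choices, and limitations behind
`stomech`. Units are micrometres (μm) and megapascals (MPa) throughout;
forces come out in micronewtons.

## Geometry model of a stomatal complex

A simplified guard-cell pair is an elliptical torus around an elliptical
pore. Two boundary ellipses define it in the leaf plane: the pore ellipse
(semi-axes pore_length/2 × pore_width/2) and the complex ellipse
(complex_length/2 × complex_width/2). For each sweep angle θ the tube
cross-section is centred midway between the two ellipses, with in-plane
semi-axis half their separation and out-of-plane semi-axis
guard_cell_width/2. The two guard cells are the θ ∈ (0, π) and (π, 2π)
halves, meeting at junction poles on the pore's major axis.

The five nominal dimensions over-determine a torus because measurement
tables carry noise: the pore and complex dimensions are honoured exactly
(four constraints, four degrees of freedom); the guard-cell width then sets
only the tube height, and the in-plane tube width follows from the other
four (for wild-type means it lands within ≈5% of the tabulated guard-cell
width). When the inputs are geometrically consistent all five match.

Two interpretation conventions coexist, each matching how the artifact is
measured downstream:

* the **mesh generator** reads the dimensions as *mid-surface* geometry
  (what a shell FE model is built on);
* the **stack generator** renders the wall band so the *visible* stained
  geometry matches: the aperture between lumen-side wall faces equals the
  nominal pore ellipse and the outer wall faces the nominal complex
  ellipse.

## Synthetic image stacks

Stacks emulate spinning-disk confocal acquisitions of propidium-iodide-
stained walls: XY pixel area 0.0409 μm² (pixel side ≈ 0.2022 μm), z-step
0.2 μm. Rendering is exact-geometry: two closed face surfaces (outer wall
faces; lumen faces one wall thickness inside) are densely sampled with
outward normals, and a voxel is wall when it lies inside the outer surface
but outside the lumen surface (nearest-sample signed test). Junction end
walls fill thin wedges at the sweep poles where the two cells contact.
Intensity is binary ([0, 1]) before degradation: Gaussian PSF blur (σ in
μm, isotropic) followed by additive Gaussian noise; designated outlier
slices can be corrupted to exercise the robust regression. The attached
ground truth records the visible geometry; its pore area is the count of
pixel centres inside the aperture ellipse at the rendered grid, because a
1.2 μm-wide closed pore is only ~5 pixels tall and quantizes visibly.

The generator does **not** emulate depth-dependent attenuation,
anisotropic/asymmetric PSFs, cuticular ledges, neighbouring pavement cells,
or staining heterogeneity. Passing round-trip tests therefore demonstrates
correctness of the measurement pipeline's geometry handling and robustness
logic, not performance on raw micrographs.

The per-genotype geometry tables sample each quantity as
N(mean, SE·√n_ref) truncated at zero (resampled rows are flagged), with
n_ref = 15 reflecting the sample sizes behind published mean ± SE rows, so
a generated sample of that size reproduces the printed SE.

## Morphometry

* **Active contours.** Per-slice segmentation uses a morphological geodesic
  active contour (inverse-Gaussian-gradient edge map, balloon expansion
  from a seed disk). Two domain adaptations stabilize it on thin stomatal
  pores: an intensity *barrier* (pixels above 45% of the slice intensity
  range are stained wall and stop the curve outright) and a floor on the
  speed function away from walls so the balloon survives blurred edge
  zones. Because the attachment term parks the curve on the wall, the
  reported region is the enclosed non-wall interior containing the seed.
  Whole-complex segmentation seeds a short contour relaxation from the
  hole-filled bright-wall mask. Convergence is detected as a stationary
  level set within the iteration budget and flagged otherwise; a
  featureless slice raises an error.
* **Robust pore minimum.** The per-slice pore-area profile is fit by a
  fourth-order polynomial under a Cauchy residual model, solved by
  iteratively reweighted least squares (scale = median absolute residual,
  weights seeded from a median-filtered pre-fit so an isolated outlier
  cannot anchor the first pass). A full-range robust pass locates the
  basin; the quartic is then refit in a window (±max(4, 20% of range)
  slices) around it, because the steep wings of a deep V-shaped profile
  otherwise dominate the polynomial. The minimum of the curve inside the
  data range is the pore area (× 0.0409 μm²/px); a monotone fit returns
  the endpoint minimum with a warning.
* **Axes and dimensions.** Pore and complex length/width are the
  ellipse-equivalent major/minor axes (second central moments) of the
  largest connected component. The complex is measured on the best-contrast
  slice within ±4 of the minimum-pore slice (mean gradient magnitude along
  the segmented contour; ties break to the lowest index, as do all
  tie-breaks in the package).
* **Medial axis.** From the pore centre of mass, rays at each integer
  degree are scanned for wall signals: peak pairs where the profile is
  smooth, bright runs on hard-edged data (band borders located to subpixel
  by interpolating the half-crossing). The midline point is the midpoint of
  the pore-side and outer borders; the angular midline is Savitzky–Golay
  smoothed (window 11, order 3, periodic). Junction angles are the two
  midline-intensity maxima at least 90° apart (the midline crosses bright
  shared walls only where the cells meet); the midline splits there into
  two per-cell arcs, each simplified by an order-4 parametric polynomial
  before the arc length is taken. Rays with fewer than two usable borders
  are skipped; >20% skipped is an error. Note the radial-ray midline of two
  nested ellipses is systematically a few percent shorter than the
  parametric centerline; this is a property of the (standard) ray
  construction, not an implementation loss.
* Guard-cell width is the wall-to-wall ray width at each arc's midpoint —
  the tube diameter perpendicular to the medial axis.

## Shell finite elements

All degrees of freedom are translational:

* **Membrane**: constant-strain triangles, total-Lagrangian. The
  deformation gradient maps the reference triangle (coordinates in its
  local material basis, e1/e2 projected to the facet) to the current one;
  Green strain E = (FᵀF − I)/2 and 2nd Piola–Kirchhoff stress S = Q·E with
  the orthotropic plane-stress reduced stiffness Q built from E₁, E₂, ν₁₂
  and G₁₂.
* **Bending**: discrete hinges on interior edges, energy ½k(θ − θ₀)² with
  k = D·|e|²/(A₁+A₂) and D = E(φ)t³/12 the flexural rigidity in the bending
  direction (φ from the material frame). Bending here mainly regularizes
  the membrane solution; its constant is the standard discrete-shells
  calibration, not a converged plate discretization.
* **Pressure**: a follower load evaluated on the current geometry
  (p·A·n̂/3 per node of each wetted triangle).
* **Solution**: load (and prescribed displacement) ramps linearly over
  n_increments (default 10); each increment is equilibrated by Newton
  iteration (relative residual tolerance 1e-6, with a small absolute floor
  for zero-load cases) using element-wise central-difference consistent
  tangents (step 1e-5 μm) assembled sparse, plus a backtracking line
  search. Divergence returns the last equilibrated state flagged
  non-converged.
* **Supports**: a free complex is grounded by an automatic statically
  determinate 3-2-1 support (zero reaction under the balanced pressure
  load, hence no elastic distortion; it does fix an arbitrary rigid
  placement). Pavement-cell support prescribes junction displacements along
  the pore axis to the target complex length (with vertical support) and
  dorsal-flank displacements to the target width, ramped with the load.
  Reported loadings are signed reaction force per mid-surface node-set
  area; positive means compressive support from neighbours.
* The quad mesh of a tube is triangulated with alternating diagonals
  (union-jack) so the discretization carries the mirror symmetries of the
  complex; with one-sided diagonals the coarse-mesh solution is visibly
  asymmetric.

Element counts of ~3000 (48 × 32 sweep × cross-section sampling) change the
simulated pore width by <1% on refinement and solve in tens of seconds,
which is the default scale for the worked example; verification and
identification studies use coarser tubes (≈500 elements) where the forward
solve costs well under a second.

**Through-thickness moduli.** This is a thin (Kirchhoff-type) shell: E₃,
G₁₃ and G₂₃ do not enter the forward stiffness (plane stress condenses E₃
out; there is no transverse-shear flexibility). They remain part of the
material description, the feasibility filter, and the identification axes.
A thick-shell element would be needed for them to influence deformation —
a known limitation when comparing against reduced-integration thick-shell
results, absorbed by the ±15% verification band on the worked example.

**Turgor reference.** The 5 MPa turgor is applied to the stress-free closed
geometry; whether the biological closed state is prestressed is not
modelled.

## Inverse identification

The factorial grid spans each modulus over {200 kPa, 200 MPa, 200 GPa} —
the reported range from the softest plant-cell assemblies to crystalline
cellulose. Feasibility filtering removes sets whose completed stiffness is
not positive definite (a fixed major Poisson ratio with extreme stiffness
contrast violates |ν_ij| ≤ √(E_i/E_j)) and any modulus above the cellulose
cap. Each surviving candidate is forward-solved on every mesh (solves are
content-hashed and cached); it is accepted when the rank-sum p against the
measured open sample exceeds 0.05 for the configured quantities (pore width
by default; complex length and guard-cell width can be added). Any
non-converged solve disqualifies the candidate without dropping it from the
report.

Refinement root-finds r(m) = mean simulated pore width − target with
Broyden's method in log-modulus space (iterates stay positive; indefinite
trial sets are rejected in the line search), terminating at |r| < 0.05 μm
or 25 iterations. When the sensitivity of pore width to a modulus is
shallow, a tighter residual tolerance is needed to pin the modulus itself —
the recovery studies use 0.005 μm. The optimal set minimizes the sum of
squared relative errors of simulated means against measured means; ties
break toward the lowest E₁, then E₂, and so on.

The rank-sum test uses midranks; pooled samples of ≤12 are tested by exact
enumeration of all label assignments (two-sided p doubles the smaller
tail), larger ones by the normal approximation with tie and continuity
corrections.

## Verification strategy

* closed-form oracles: pressurized thin sphere (Δr = pR²(1−ν)/2tE),
  hemisphere equatorial reaction (pπR²), external work vs strain energy in
  the linear regime, classical CST stiffness in the isotropic limit;
* geometry oracles: raster pixel counts inside analytic ellipses, numeric
  quadrature of the analytic torus area, shoelace polygon areas, moment
  formulas on exact rasters;
* end-to-end: morphometry round-trips on rendered stacks against attached
  ground truth, and scaled-down self-consistency of the identification
  pipeline (targets forward-generated from a known grid material with 5%
  noise must be accepted, bracketed by the reported ranges, and recovered
  by refinement). Scaled-down studies use 3 meshes at ≈500 elements and a
  2⁶ grid — sizes chosen so the whole suite runs on a laptop-class single
  core.

## Known limitations

* The published per-genotype moduli ranges and junction/dorsal loading
  values were derived from the authors' traced confocal geometries, which
  are not redistributable; with parametric stand-in geometries this package
  reproduces the simplified-model worked example and the qualitative
  constraint effect, and verifies the identification machinery by
  parameter recovery instead.
* Default per-region wall thicknesses (ventral 1.0, dorsal 0.6, periclinal
  ledge 1.2, periclinal 0.8, lower periclinal 0.8 μm) are configuration
  placeholders for the differential thickening of guard-cell walls, not
  measurements; the longitudinal thickness modulation defaults to flat.
  Both are replaceable via `ThicknessTable`.
* St. Venant–Kirchhoff elasticity is adequate at the ~5–10% strains seen
  here but is not a hyperelastic wall model; plasticity and sister-cell
  contact are out of scope.
* The active-contour defaults are tuned for wall-stained, lumen-dark
  images with the stated calibration; heavily blurred narrow pores are
  under-read (the PSF genuinely narrows the visible aperture).
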