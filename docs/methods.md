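# Methods

`tensioncoat` models the physics behind coating fenestrated (window-bearing)
3D-printed scaffolds by dip-coating: surface tension suspends liquid films
across the open windows, which are then crosslinked into solid panes.  The
package has three computational pillars — wetting thermodynamics, a
minimal-surface film simulator, and compression mechanics — plus a
synthetic-data generator that supplies every input with known ground truth.

## 1. Wetting thermodynamics (`tensioncoat.wetting`)

### Model

A two-dimensional square-cell mesh of edge length `l` is filled with liquid
at saturation `α_L` (fractional open area occupied).  Gravity is ignored —
at millimetre scale, capillarity dominates.  Two homogeneous configurations
are compared through their interfacial free energy per cell, reduced by
`γ_L·l` (liquid–vapor surface energy times edge length):

- **Phase I (corner fillets).**  Liquid occupies the four 90° corners,
  bounded by circular arcs meeting each wall at the contact angle `θ`.
  The energy is assembled from the fillet geometry:

      F_I/(γ_L l) = 4 γ_S/γ_L − 8 (x₀/l) cos θ + 4 L_arc/l,

  where `x₀` is the wetted wall length per corner and `L_arc` the arc
  length, with the arc radius set so the four fillets hold area `α_L l²`.
  At `θ = 0` this reduces exactly to

      F_I/(γ_L l) = 4 (1 + γ_SL/γ_L) − (8 − 2π) √(α_L/(4 − π)).

- **Phase II (shrinking hole).**  The cell is full except a circular hole:

      F_II/(γ_L l) = 4 γ_SL/γ_L + 2√π √(1 − α_L),

  independent of `θ` because no three-phase contact line remains.

The three surface energies are tied by Young's equation,
`γ_S = γ_SL + γ_L cos θ`, enforced to 1e-12 on every `WettingSystem`.

### Fillet geometry

For an arc meeting both walls of a 90° corner at contact angle `θ`:

    x₀        = r |cos θ − sin θ|
    area      = r² [cos θ (cos θ − sin θ) − (π/4 − θ)]
    arc angle = π/2 − 2θ   (signed)

The meniscus is concave for `θ < 45°` (arc centre outside the liquid),
exactly straight at `45°` (the closed forms have a removable singularity
there; a finite arc radius then parameterises a zero-size fillet, and the
shape ratio `area/x₀²` is evaluated by series around the point, limit 1/2),
and convex for `θ > 45°`.  The formulas are validated against an
independent polygonal-discretization oracle (`fillet_area_polygon`, shapely
shoelace area on ≥1e5 arc segments) to ~1e-10 relative error.

The **critical saturation** — where adjacent fillets touch (`2 x₀ = l`) and
phase I ends — is the shape ratio itself:

    α_Lc(θ) = [cos θ (cos θ − sin θ) − (π/4 − θ)] / (cos θ − sin θ)²

giving `1 − π/4 ≈ 0.215` at `θ = 0`, `1/2` at `45°`, `π/4` at `90°`, and
reaching 1 at `θ ≈ 114.1°` — beyond that the fillets cannot touch before
the cell is completely full and the phase II branch never opens, which is
why the reference energy-curve family stops at 114°.  `α_Lc` is capped at 1.

Contact angles are stored in radians (the CLI accepts degrees).  The domain
is `[0°, 135°)`; at 135° the construction degenerates (`x₀ → 0` relative to
the arc).  Angles above 105° are admitted but flagged with a warning: the
corner-fillet construction is an extrapolation in that regime.

### Phase separation and coatability

The composite curve (phase I up to `α_Lc`, phase II above, no smoothing)
is convex then concave; the sign change of its discrete second derivative
(central differences, inflection reported at the midpoint of the
sign-change interval) marks the end of homogeneous filling.  Beyond it the
system phase-separates: some cells fill completely while the rest stay in
the fillet state.  The coexistence window is the common-tangent chord
**anchored at the inflection**: the minimum-slope chord from the inflection
to the rest of the curve, which for wetting systems touches again at
`α_L = 1`, giving the window `(α_Lc, 1)`.  A deliberate design choice: the
unanchored lower convex hull of the whole composite curve would leave the
phase I branch earlier (near `α_L ≈ 0.06` at `θ = 0`), because the convex
fillet branch dips below the endpoint chord; but the coexisting states of
the physical system are cells *at the phase-I boundary* and *completely
filled* cells — the fillet state below `α_Lc` is the homogeneous phase
itself, not a coexisting end member — so the chord is anchored where
homogeneous filling ends.

Coatability compares the empty cell (`4 γ_S`) with the filled cell
(`4 γ_SL`): the difference `4 cos θ` makes complete coating favorable for
`θ < 90°`, neutral at 90° (band `|cos θ| < 1e-12`, avoiding float ties),
unfavorable above.

## 2. Film simulator (`tensioncoat.film`)

A suspended film is a triangulated surface pinned to the frame boundary
(the window midline; the pipe diameter `h` is carried as metadata and does
not alter the loop).  The reduced energy is the surface area — one
liquid–vapor face by convention (`two_sided=True` doubles it; the choice
cancels in every stability verdict).  Relaxation is projected gradient
descent on the free vertices:

- analytic per-triangle area gradients, scatter-added per vertex;
- Barzilai–Borwein step initialisation with Armijo backtracking (factor
  0.5, slope parameter 1e-4) — accepted steps never increase the energy;
- optional enclosed-volume constraint (volume measured against the z = 0
  boundary plane by the divergence theorem), enforced each step by Newton
  projection along the volume gradient to relative 1e-6, with the area
  gradient projected onto the constraint tangent;
- convergence when the relative energy decrease over the trailing 50
  accepted iterations falls below `tol` (default 1e-8), or immediately when
  the gradient vanishes (an exactly flat film converges in one iteration);
  `max_iter` defaults to 20 000.

**Stability** is operationalised as convergence with every vertex inside a
bounding box of 10× the frame extent; NaN blow-up or non-convergence is
recorded as unstable, never raised.  The contact line is pinned at the
frame midline rather than sliding on a pipe surface: it makes stability
well-posed without a wall-energy model, and the sweep varies `h` only
geometrically.

Meshing: `subdivisions` counts grid divisions per side (square) or rings
(circle; rings carry 6j vertices, triangulated by Delaunay and oriented
+z).  `refine` performs exact 4-way midpoint subdivision (area conserved to
float precision; boundary-edge midpoints inherit pinning).  Sweeps run
init → relax → (refine → relax) × 3 per `(l, h)` cell with a 2% out-of-plane
perturbation; per-cell failures are recorded as unstable and the sweep
continues.  The default sweep starts at 5 divisions per side and ends at 40
after three refinements — sizes chosen so the benchmarks below resolve to
well inside their tolerances while a 9-cell sweep completes in seconds.

Analytic benchmarks: a perturbed square film relaxes back to the flat plane
(area `l²` within 0.1%); a film on a circular frame of diameter 2
constrained to the volume of a spherical cap of height 0.5 reaches the
closed-form cap area `π(a² + h²)` within 1% already at 6 rings (the
residual is faceting: an inscribed polygon/cone underestimates the smooth
cap, measured at −0.12% at 6 rings, −0.07% at 8).

The liquid volume per window during real dip-coating is not prescribed by
the process, so the sweep default is an unconstrained (flat) film, with a
`volume_fraction` option (of `l³`) for inflated films.

## 3. Mechanics (`tensioncoat.mechanics`)

Instron-style records (displacement mm, force N, both positive in
compression) convert element-wise to engineering stress `σ = F/SA` (MPa,
since N/mm² = MPa) and strain `ε = ΔL/L₀`.  The effective compressive
modulus `K` is the OLS slope of `σ` on `ε` restricted to the first 0.5 mm
of *displacement* (the window is defined in displacement, not strain, and
is configurable); the intercept is fitted and discarded, tolerating small
force offsets at platen contact.  Buckling is the first local stress
maximum followed by a drop exceeding 5% of that peak — the 5% threshold is
not a material property but a robustness margin against 1% force noise
(configurable); monotone curves report no buckling.

## 4. Synthetic data (`tensioncoat.synthetic`)

The generator emulates the study conditions end to end:

- **Device presets** (ground truths for recovery tests): rectangular-window
  cylinders, longitudinal: `K = 77 MPa`, buckling at `ε = 0.026`;
  anisotropic (parallelogram-window), longitudinal: `K = 0.69 MPa`,
  reversible to 30% strain; radial: `K = 3.6` and `4.1 MPa`.  These moduli
  are physical measurements — they are generator inputs, not quantities the
  model predicts.
- **Compression records**: displacement grid to min(`max_strain·L₀`,
  protocol travel: 10 mm longitudinal / 6 mm radial), 200 samples, linear
  stress with an abrupt 20% drop to a plateau past the programmed buckling
  strain (the post-buckling branch is cosmetic — it exercises the detector
  and models no material), multiplicative Gaussian force noise of relative
  s.d. 1% by default, seeded.  SA = 78.5 mm² and L₀ = 20 mm are synthetic
  stand-ins (specimen cross-sections are not published); no quantitative
  claim depends on them, and scaling invariance of `K` is tested instead.
- **Frame specs**: the printed 3×3 grid of window lengths
  {2.25, 5.5, 8.75} mm × pipe diameters {0.25, 0.5, 1.0} mm.
- **Wetting systems**: the nine reference contact angles
  0–114° deterministically first, further draws uniform on [0°, 135°),
  `γ_SL/γ_L` uniform on [0, 2], all closing Young's equation.

What passing recovery tests show — and do not.  The generator's curves are
piecewise-linear with well-behaved noise; real scaffold tests have toe
regions, viscoelastic drift and contact settling.  Recovery within 2%
therefore validates the estimator pipeline (units, windowing, fitting,
detection thresholds), not the measurement physics.

## 5. Reporting (`tensioncoat.cli`)

A single `coat` entry point; JSON/CSV outputs only ('.' decimal separator,
headers required), with a RunManifest (command, parameters, seed, package
version, timestamp) written beside every output set.  `coat repro all
--seed N` regenerates the energy-curve family (nine angles, 501-point
grids), the 3×3 stability sweep and the four-preset mechanics recovery,
bytewise-deterministically for a fixed seed (manifests carry timestamps;
tables do not).  Exit codes: 0 success, 2 validation error, 3 numerical
failure.

## Known limitations

- The Gibbs analysis is strictly two-dimensional and square-celled; 3D
  effects enter only through the film simulator.
- No dynamic wetting, drainage, evaporation, rupture, contact-angle
  hysteresis or gravity; no prediction of contact angles from chemistry.
- The simulator pins the contact line; free-sliding contact lines on pipe
  surfaces are out of scope.
- Above 105° contact angle the fillet construction is an extrapolation
  (flagged at run time); the analytic model's physical support ends near
  114° where the phase II branch disappears.
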