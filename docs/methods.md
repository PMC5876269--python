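# Methods

This note records the geometric model behind the package, the parameter
choices that matter, what the synthetic phantoms do and do not emulate,
and the numerical decisions a maintainer would otherwise have to reverse
engineer.

## Canonical frame

All measurements are made in a canonical knee coordinate system: x
increases medially, y is antero-posterior position (0 at the most
anterior joint-line point, increasing posteriorly), z increases
proximally along the tibial long axis.  Left knees are mirrored into
this frame, so a single medial-is-+x convention serves both sides and
left/right symmetry is exact by construction.

The frame is recovered from the tibial surface alone, deterministically:

* **Long axis** — the largest principal axis of the surface's
  *area-weighted* triangle-centroid covariance.  Area weighting makes
  the axis independent of meshing density; a vertex-weighted version
  flips to the mediolateral direction as soon as the plateau is meshed
  finely, because plateau vertices then outnumber shaft vertices.  The
  proximal end is the one whose extreme 10 % slab has the larger convex
  hull cross-section (the plateau beats the shaft).
* **AP axis** — the minor principal axis of the plateau band's in-plane
  vertex distribution.  The band is every vertex within 10 mm of the
  highest tibial point; the tolerance of 1 µm on the band cut keeps
  vertex layers lying exactly on the boundary inside the band in every
  pose.  A minimal-extent (rotating-calipers) definition was tried and
  abandoned: for outlines dominated by circular arcs, the extent
  function is flat — or even *maximal* — at the AP direction, so its
  minimiser is unstable.
* **Medial sign** — the highest plateau point (the medial tibial spine
  apex) lies medial of the mediolateral midline.
* **Handedness** — y = z × x for right knees; the sign flips for left
  knees, which is exactly the mirror-to-canonical map (the frame matrix
  then has determinant −1).

The y origin is the most anterior plateau-band point, so AP positions
read directly as "mm from the front of the tibia", and
`location_percent` converts them to the 0–100 % scale (0 % = front).

Small in-plane rotation errors are second-order for the AP breadth
(the extent function is flat at its minimum) and first-order but tiny
for landmark positions; the landmark tolerances (±0.2 mm breadth,
±0.5 mm apex) absorb them.

## Phantoms

A phantom emulates what manual segmentation of an asymptomatic knee
produces, with every measured feature available in closed form.

**Tibia.** The medial plateau edge consists of two circular arcs — one
anterior, one posterior of the dividing coronal plane through the spine
apex — that meet continuously at that plane.  The factory
(`PhantomSpec.standard`) places the anterior circle's anterior pole at
y = 0 and solves the posterior radius so the posterior pole lands at
`ap_breadth` with the same mediolateral coordinate; the junction
continuity condition is then satisfied automatically.  The lateral
boundary is the mirrored medial boundary shifted a constant 20 mm
laterally (the plateau's two-condyle mediolateral dominance).  The
mirror construction is deliberate: it makes the plateau band's in-plane
covariance vanish in the construction frame, so the automated frame
reproduces the construction axes to ~0.2°.  A spine cone (apex exactly
at the specified landmark, default 6 mm above the rim), a medial and a
lateral rim wall (6 mm deep), and a 140 mm shaft complete the surface.
The shaft's axis position is solved so the total area-weighted x–z and
y–z covariances are zero — the frame recovery diagonalises exactly that
statistic, so the recovered long axis coincides with the construction
z axis; without the correction the off-centre spine cone tilts it by
about 0.2°.

**Meniscus.** A C-shaped band (default 4 mm thick, 8 mm body width)
whose outer (meniscosynovial) edge sits at radial offset `e(θ)` outside
the tibial edge, where θ is the angle about the owning tibial circle
centre (0° due medial, positive posterior).  `e(θ)` — the true
perpendicular extrusion — is a baseline plus Gaussian bump:

    e(θ) = baseline + A · exp(−(θ − θ*)² / 2σ²)

Real extrusion profiles have no published functional form; the bump
gives two interpretable parameters (peak size and location) for
recovery experiments.  Because the two tibial circles have different
centres, the radial-offset edges of the two regions end a fraction of a
millimetre apart at the dividing plane; a short bridging chord closes
the edge (it vanishes for identical circles).

**Sampling.** Edge-bearing vertices are emitted in columns on coronal
planes spaced `slice_thickness` apart and stacked at z-levels with the
same spacing — the way per-slice segmentation samples a surface.
Noiseless edge vertices lie on the generating curves to 10⁻⁹ mm
(column positions are root-refined on the exact circle/offset-curve
equations, never interpolated).  Optional isotropic Gaussian noise is
added to every vertex afterwards, seeded.  The plateau's exact AP pole
points are always meshed so the breadth of the phantom equals the
specified breadth rather than its grid-quantised value.

**Closed-form truth.** For every phantom: the extrusion profile at 1°
resolution, its continuous maximum and AP location, and
`analytic_slice_extrusion`, the horizontal tibia-to-meniscus gap of the
plane y = station computed from the circle equations (for a uniform
offset it reduces to `√(R_m² − d²) − √(R_t² − d²)`).  This function is
the independent oracle for everything the slice methods measure.

**Default study conditions.**  Cohorts draw AP breadth from
N(52.9, 3.6) truncated to [47.2, 61.6] mm and the spine apex from
N(29.8, 1.7) truncated to [28, 33] mm — the reported spread of
asymptomatic adult knees; truncated normals rather than uniforms keep
range extremes appropriately rare.  The anterior tibial circle radius is
0.55–0.60 of the breadth.  Extrusion bumps default to baseline
1.0–2.5 mm, amplitude 2–6 mm, peak angle 28–36° (posteromedial), width
(σ) 35–45°, with meniscal angular support (−85°, 42°); slices are
0.5 mm with 0.05 mm vertex noise.  Three of these choices carry real
design weight:

* *Bump width.*  The reference method models each regional edge as a
  circle, so it can only represent extrusion profiles that are close to
  circle–circle offsets.  At σ = 35–45° over the posterior region the
  circle model reproduces the bump maximum to < 0.02 mm (a design-time
  feasibility calculation over the full parameter box); much narrower
  bumps are invisible to a circle fit, and recovery degrades — a
  genuine limitation of the method, not of the phantom.
* *Peak angle.*  28–36° keeps the peak identifiably inside the
  posterior region: far enough from the dividing plane that the
  anterior region's fitted circle cannot tie it, and far enough from
  the posterior support end that the maximum is interior.
* *Angular support.*  The anterior horn wraps to near-tangency of the
  anteromedial margin (−85°) while the posterior horn turns toward its
  root attachment earlier (+42°).  This anterior/posterior asymmetry is
  what drives the maximal-slice method's anterior bias on typical
  phantoms: near the front the tibial chord shrinks to zero while the
  meniscal chord does not, so the horizontal gap `√(2 R e + e²)` at the
  front outgrows any posterior station unless the posterior bump is
  extreme.

## Reference measurement (CETCEM)

Pipeline per knee: frame → landmarks → medial-edge extraction →
interpolation → four circle fits → two radial profiles → maximum.

* **Edge extraction** replaces the original manual point picking: the
  most-medial vertex per 1 mm AP bin, with the tibia restricted to the
  plateau height band.  Trace ends whose secant slope |dml/dap|
  exceeds 2.5 (edge tangent ≈ 68° around the circle) are trimmed:
  there the boundary runs mediolaterally and per-AP-bin picks stop
  being the medial edge.  Without the trim, near-pole points pull the
  posterior tibial circle centre millimetres off.
* **Circle fits** use the raw picked points (Kåsa algebraic start,
  Gauss–Newton orthogonal-distance refinement to 10⁻¹⁰ mm).  The
  AP-interpolated traces (0.1 mm default) fill slice gaps for the dense
  profile exports and the polyline oracle but are not fed to the fits:
  interpolation chords sag inward (up to ~0.08 mm on steep segments)
  and would bias the radii.
* **Radial profiles** are sampled at 1° steps by intersecting rays from
  each tibial circle centre with the corresponding meniscal circle
  (far intersection); extrusion is the intersection distance minus the
  tibial radius and may be negative (meniscus inside the rim).  The
  angular support is clipped to within 2° of an observed raw meniscal
  point (no extrapolation past the horns), each region's profile is
  clipped to its own side of the dividing plane (the anterior circle
  must not extrapolate into posterior territory), and samples outside
  [0, breadth] are dropped.  Exact ties for the maximum resolve to the
  posterior region, then the larger angle.
* **Oracle.**  `oracle_perpendicular_extrusion` is the model-free
  cross-check: for each meniscal edge point, the exact perpendicular
  distance to the densely resampled tibial edge polyline, signed
  positive when medial.  On phantoms whose edges are true circular
  arcs it agrees with the circle-based profile to < 0.1 mm at every
  interior angle.  Near the trace ends the nearest-polyline distance is
  to an endpoint rather than a perpendicular foot, so comparisons stay
  1.5 mm inside the trace.

## Slice methods

Stations run from the front to the back of the plateau at exactly
1 mm.  A station's slab holds vertices within ±0.5 mm (stations
partition the AP axis); the measurement is the most-medial meniscus x
minus the most-medial tibia x in the slab, with the tibia restricted to
the plateau band.  Stations where either structure has no slab vertices
are *missing*, never zero — zero-filling would silently bias the
maximal station.  The Coronal Slices result is the maximum over valid
stations (ties → most anterior); the Bony Landmarks result is the
station nearest the spine apex (midpoint ties → anterior), and a
missing slab there is an error rather than a silent fallback.  Each
measurement records the AP positions of the vertices actually used,
because the effective measurement plane can sit anywhere inside the
slab.

## Statistics

The binary call is `extrusion ≥ 3 mm` (inclusive boundary); the
30 %-of-meniscal-width variant is available but off by default.
Wilcoxon signed rank is computed from the exact permutation
distribution for n ≤ 25 pairs (a dynamic program over signed rank sums,
which handles mid-ranked ties exactly) and by normal approximation with
tie correction above; Friedman and Spearman delegate to scipy, with the
all-tied Friedman case special-cased to χ² = 0 (scipy's tie correction
is 0/0 there); Cohen's kappa is computed directly because its
large-sample standard error is reported, and is flagged undefined when
both raters are constant and identical.  All two-sided.  Cohort reports
include medians alongside means and SDs.

## Numerical choices and degenerate inputs

* Vertex welding at 10⁻⁶ mm on STL read (STL stores per-facet
  vertices).  Binary STL is single precision, so round-trips of ~100 mm
  geometry are exact only to ~2·10⁻⁵ mm; unit-scale geometry round-trips
  within 10⁻⁶ mm.
* Collinear circle-fit input (circumradius > 10⁴ × point spread) is a
  named error, as are empty slabs, missing regions (< 3 edge points),
  planar vertex clouds, and rays that miss the meniscal circle (dropped
  with a warning; an error only if all miss).
* The chord prediction `√(R² − d²)` has infinite derivative at |d| = R,
  so closed-form comparisons of slice values are only well-posed away
  from tangency; the phantom's analytic oracle avoids the issue by
  evaluating true circles rather than fitted ones.
* Spine-apex height ties resolve to the more anterior vertex; all other
  tie-breaks are listed with their operations above.

## Problem sizes

The validation experiments use cohorts of 17 phantoms (the size of the
study population the design emulates): 17 noisy 0.5 mm-slice phantoms
for parameter recovery and cohort ordering, 17 noiseless circular-edge
phantoms at 1 mm slices for the overestimation geometry (the 1 mm
meshing matches the 1 mm station grid, i.e. measurements are simulated
on the same slices the segmentation came from), and 10 noiseless
phantoms for the oracle equivalence.  Each cohort takes a few seconds.

## What passing tests do and do not show

The phantoms share the measurement model's own idealisations: circular
medial edges, a smooth single-bump extrusion profile, a clean spine
apex, no osteophytes, no segmentation topology errors, isotropic noise.
Passing tests therefore demonstrate that the implementation measures
what it claims on geometry satisfying those assumptions, and that the
slice methods' biases follow the predicted chord geometry.  They do not
certify accuracy on degenerative knees (excluded by design), on edges
that deviate strongly from circularity — where the circle model itself,
not the code, is the limit — or under anisotropic, spatially correlated
segmentation error.  Absolute cohort numbers (medians, correlation
sizes) are functions of the synthetic parameter distributions; only
their orderings and signs are design-independent findings.
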