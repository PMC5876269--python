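# cetcem — medial meniscal extrusion morphometry

Medial meniscal extrusion — displacement of the meniscal body beyond the
edge of the tibial plateau — is a conventional imaging marker for knee
osteoarthritis risk (≥ 3 mm is the usual pathological threshold).
Longitudinal cohort studies need a measurement that finds the *same*
quantity at the *same* place in the knee at every time point, but in
practice three different measurements are in use:

* **CETCEM** (Circular Edge of Tibia to Circular Edge of Meniscus), the
  reference standard on segmented 3D surfaces: circles are fitted to the
  medial edges of the tibia and meniscus (anterior and posterior of the
  coronal plane through the medial tibial spine apex), and extrusion at
  each angle θ is the *perpendicular* distance
  `e(θ) = |ray ∩ meniscus circle| − R_tibia`
  measured radially from the tibial circle centre;
* **Coronal Slices**: the *horizontal* tibia-to-meniscus gap on the
  simulated 1-mm coronal slice that maximises it;
* **Bony Landmarks**: the horizontal gap on the single slice through the
  medial tibial spine apex.

A coronal slice cut at mediolateral offset `d` from a circle centre meets
circular edges of radii `R_t < R_m` along non-parallel chords, so the
horizontal gap `√(R_m² − d²) − √(R_t² − d²)` always exceeds the
perpendicular extrusion `R_m − R_t` away from the mediolateral extremum —
the geometric reason the maximal-slice method systematically
overestimates and displaces the apparent maximum.

This package implements all three methods end-to-end (automatic
anatomical-frame recovery, landmark detection, edge extraction, circle
fitting, slice simulation, binary classification) together with a
synthetic knee-phantom generator whose extrusion profile is known in
closed form, and the nonparametric cohort statistics (Wilcoxon signed
rank, Friedman, Spearman, Cohen's kappa) used to compare the methods.
It is aimed at researchers validating extrusion measurement protocols or
building reading pipelines for segmented knee MRI.

## Worked example

Generate a phantom with a 5 mm posteromedial extrusion bump on a 1.5 mm
baseline and measure it with all three methods:

```python
import cetcem as c

spec = c.PhantomSpec.standard(
    slice_thickness=0.5,
    extrusion=c.ExtrusionModel(
        baseline_mm=1.5, peak_amplitude_mm=5.0, peak_angle_deg=32.0, peak_width_deg=40.0
    ),
)
tibia, meniscus, truth = c.make_phantom(spec)
knee = c.KneeSpecimen(id="demo", side="right", tibia=tibia, meniscus=meniscus)

detail = c.cetcem_analyse(knee)
cs = c.coronal_slices_measure(knee, detail.frame, detail.landmarks)
bl = c.bony_landmarks_measure(knee, detail.frame, detail.landmarks)

lm = detail.landmarks
print(f"AP breadth {lm.ap_breadth:.1f} mm, spine apex at {lm.spine_apex_ap:.1f} mm "
      f"({c.location_percent(lm.spine_apex_ap, lm.ap_breadth):.0f}%)")
print(f"true maximum extrusion  {truth.true_max_extrusion:.2f} mm at {truth.true_max_ap_location:.1f} mm")
for r in (detail.result, cs, bl):
    print(f"{r.method:<14} max {r.max_extrusion:5.2f} mm at {r.location_ap:5.1f} mm "
          f"({r.location_pct:3.0f}%)  extruded={r.extruded}")
```

prints

```
AP breadth 52.9 mm, spine apex at 29.8 mm (56%)
true maximum extrusion  6.50 mm at 44.2 mm
CETCEM         max  6.49 mm at  44.3 mm ( 84%)  extruded=True
CoronalSlices  max  9.36 mm at  48.0 mm ( 91%)  extruded=True
BonyLandmarks  max  5.68 mm at  30.0 mm ( 57%)  extruded=True
```

The reference method recovers the true peak to 0.01 mm and its location
to 0.1 mm.  The maximal-slice method overestimates it by almost 3 mm
(chord geometry), while the spine-apex slice, anchored 14 mm anterior of
this phantom's peak, underestimates it — the two failure modes the
package is built to quantify.

The same pipeline is scriptable from the shell:

```sh
cetcem simulate --n 17 --seed 1 --out phantoms/
cetcem measure --tibia phantoms/phantom00_tibia.stl \
               --meniscus phantoms/phantom00_meniscus.stl \
               --side right --id phantom00 --out results/
cetcem cohort-stats --cohort results/cohort.csv --out results/
```

`simulate` writes STL pairs plus a ground-truth JSON per phantom,
`measure` appends one row per method to `results/cohort.csv` (plus the
per-knee radial profile and slice table), and `cohort-stats` writes the
summary statistics and method-comparison tests as JSON/CSV.

## Layout

| module | contents |
| --- | --- |
| `cetcem.phantom` | synthetic tibia/meniscus generator, closed-form ground truth, cohorts |
| `cetcem.mesh_io` | STL read/write (ASCII + binary), vertex welding, specimen validation |
| `cetcem.anatomy` | canonical frame recovery, AP breadth, spine-apex landmark |
| `cetcem.reference` | CETCEM: edge extraction, circle fits, radial profiles, polyline oracle |
| `cetcem.slices` | simulated coronal slices; maximal-slice and spine-apex methods |
| `cetcem.stats` | extrusion classification; Wilcoxon, Friedman, Spearman, kappa; cohort reports |
| `cetcem.cli` | `cetcem simulate / measure / cohort-stats` |

See `docs/methods.md` for the geometric model, parameter choices and
known limitations.
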