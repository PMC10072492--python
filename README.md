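# neckangle

Direct CT-based measurement of malrotation in basicervical femoral neck
fractures, with a synthetic goniometer phantom and the reliability
statistics to validate it.

## The problem

After osteosynthesis of a proximal femoral fracture, residual rotational
malalignment (malrotation) degrades function. Standard CT torsion
measurements use the femoral neck as a *pointer* against the distal
condylar plane — which fails exactly when the neck itself is fractured,
as in basicervical femoral neck fractures. The *direct* technique
measures the torsional offset between the two fragments inside a single
neck-aligned axial section, with no reference to the condyles:

1. a supporting **tangent** is drawn along the ventral cortex of the
   greater trochanter;
2. a **parallel line** to it at the dorsal border, crossing the lesser
   trochanter;
3. a best-fitting **circle in the femoral head** and one **in the
   lateral opening of the head** — the line through their centers is the
   medial (head-fragment) neck axis;
4. two **circles inscribed between tangent and parallel** — the line
   through their centers is the lateral neck axis;
5. the signed intersection angle θ of the two axes is the malrotation,
   anteversion positive.

This package implements that construction end to end (oriented
reformat, 5-mm slab, cortex contours, geometry), plus a parametric
voxel phantom of an osteotomised proximal femur mounted in a goniometer
that sets the displacement in 10° increments over ±30°, and the
statistics used to validate the method: per-level descriptives, the
single-measures absolute-agreement intraclass correlation

ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))

with the F-based 95% CI and p of McGraw & Wong (SPSS "two-way mixed,
absolute agreement"), Pearson's r, and paired Student t-tests with 95%
CIs. Audience: researchers validating torsion measurements on phantoms,
and developers of orthopaedic image-analysis pipelines.

## Worked example

```python
from neckangle import (PhantomSpec, build_phantom, MeasurementHints,
                       measure_torsion)

vol = build_phantom(PhantomSpec(set_angle=20.0,           # 20° anteversion
                                voxel_spacing=(0.8, 0.8, 0.8), seed=7))
hints = MeasurementHints.from_phantom_meta(vol.meta)       # operator hints
m = measure_torsion(vol, hints)
print(f"measured torsion: {m.angle_deg:+.2f} deg")
print(f"head circle: center ({m.head_circle.center[0]:.1f}, "
      f"{m.head_circle.center[1]:.1f}) mm, r {m.head_circle.radius:.1f} mm")
```

prints

```
measured torsion: +20.54 deg
head circle: center (2.0, 0.1) mm, r 23.0 mm
```

i.e. the pipeline recovers the 20° goniometer setting to ~0.5° on a
0.8-mm scan; the head circle radius is the head sphere seen 10 mm below
its equator (the section is guided down to the calcar level). The full
construction (tangent, parallel, all four circles, both axes) is kept
on the result for audit and can be rendered:

```python
from neckangle.overlay import plot_construction
```

Command line equivalents:

```bash
neckangle phantom --set-angle 20 --seed 7 -o phantom_p20.nii.gz
neckangle measure phantom_p20.nii.gz -o result.json --overlay fig.png
neckangle validate --levels -30..30:10 --reps 10 --seed 42 -o study_out/
neckangle stats study_out/series.csv -o report/
```

`validate` runs the whole study design: one phantom per level, ten
blinded randomized measurements per level by each of two simulated
raters (rater variability enters as perturbed alignment hints), then
the table battery — per-level descriptives, per-investigation ICC and
Pearson, per-level paired t-tests.

## Layout

| module | contents |
|---|---|
| `neckangle.geometry` | circle fit (Pratt + Gauss–Newton), supporting tangent, inscribed circles, axes, signed angle |
| `neckangle.phantom` | goniometer phantom generator, ground truth, series simulator |
| `neckangle.measurement` | section frame, slab reformat, contour labeling, `measure_torsion` |
| `neckangle.stats` | descriptives, ICC(A,1), Pearson, paired t, validation battery |
| `neckangle.study` | full study harness (`run_study`, `parameter_recovery`) |
| `neckangle.cli` | `neckangle` command (phantom / measure / stats / validate) |

See `docs/methods.md` for the model, parameter choices and limitations.
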