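# bifusion

3D reconstruction of coronary artery bifurcations — lumen, EEM and plaque
components — from segmented IVUS pullback contours fused with vessel
centerlines triangulated from two angiographic projections. Includes the
geometric validation machinery (serial cross-sections, diameter and shape
metrics, z-score regression, Bland–Altman agreement) and a synthetic
bifurcation phantom / virtual pullback simulator with known ground truth.

## What it does

1. **Biplane centerlines** (`angio_centerline`) — a cone-beam C-arm camera
   model, epipolar triangulation of MV (main vessel) and SB (side branch)
   centerlines from two views ≥ 30° apart, and arc-length utilities.
2. **Frame geometry** (`frame_geometry`) — ECG-gated frame selection, frame
   spacing from pullback speed / frame rate, rotation-minimizing frames
   (double reflection) along the centerline, in-plane twist correction by
   aligning consecutive lumen radial profiles, carina-reference roll
   registration between the two stacks, and automated smoothing of the
   virtual catheter path (MAD outlier rule + GCV smoothing spline).
3. **Surfaces** (`surface_builder`) — contour lofting into watertight capped
   tubes, MV/SB boolean union on a signed-distance voxel grid with marching
   cubes, plaque solids chained by frame-plane overlap, mapping-back checks
   (slice the surface at every frame plane, compare to the segmented
   contour) and iterative contour-driven refinement.
4. **Validation** (`validation_metrics`) — carina co-registration, serial
   cross-sections every 0.1 mm, area-equivalent diameter, maximum chord
   (distance X) and perpendicular width (distance Y) with the Y/X shape
   ratio, z-score normalization, OLS regression and Bland–Altman limits of
   agreement.
5. **Phantoms** (`phantom_sim`) — swept elliptical bifurcation lumens with
   optional Gaussian stenosis and Murray-law radius coupling, virtual IVUS
   pullbacks (cumulative twist random walk, smooth catheter-offset field,
   radial contour noise) and virtual biplane projections; all seeded and
   deterministic.
6. **Pipeline** (`pipeline_cli`) — `run_reconstruction` orchestrates
   triangulate → resample → gate → place → twist-correct → carina-register →
   catheter-correct → loft → merge → refine → map-back, with a stage log.

## CLI

```bash
# synthetic phantom -> contour stacks, projection curves, ground-truth mesh
bifusion simulate --spec phantom.yaml --out sim/ --seed 7

# full reconstruction from a YAML config (inputs + parameters)
bifusion reconstruct --config run.yaml --out model/

# compare two reconstructed model directories (regression + Bland-Altman)
bifusion compare model_a/ model_b/ --out comparison --plot

# map segmented contours back onto a reconstructed surface
bifusion mapback --config run.yaml --model model/ --out mapback.csv
```

`run.yaml` example:

```yaml
inputs:
  mv_contours: sim/mv_contours.json
  sb_contours: sim/sb_contours.json
  mv_curve_a: sim/mv_view_a.json
  mv_curve_b: sim/mv_view_b.json
  sb_curve_a: sim/sb_view_a.json
  sb_curve_b: sim/sb_view_b.json
params:
  n_theta: 128
  union_pitch_mm: 0.12
  clinical_mode: true   # enables twist correction (bench pullbacks: off)
```

Contour stacks are JSON (one per pullback): branch, pullback speed, frame
rate, carina frame + in-plane carina direction, and per-frame catheter
point plus labeled contour polygons (lumen, eem, calcium, fibrosis,
fibrolipid) in frame-plane mm with the catheter point at the origin.
Meshes are written as binary STL or ASCII PLY; reports as CSV.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (frame spacing,
centerline round trip, twist recovery, analytic loft/union volumes, metric
oracles, self/dilated model comparison, full-pipeline phantom recovery,
mapping-back refinement). The full suite takes a few minutes; the heavy
phantom fixtures are session-scoped.

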