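# remodel3d

Multi-stack alignment, longitudinal 3D rigid registration and
voxel-based bone remodeling quantification for HR-pQCT density images.

## The problem

High-resolution peripheral quantitative CT (HR-pQCT) images the
metacarpophalangeal joints of rheumatoid-arthritis patients at ~61 µm,
resolving the small cortical erosions that mark disease progression.
Two imaging obstacles stand between the scanner and quantitative
longitudinal analysis:

1. **Stack-shift artifact.** A joint scan is acquired as three 10.2 mm
   axial *stacks* with 25 % (2.55 mm) overlap. Patient motion between
   stack acquisitions rigidly misaligns adjacent stacks, splitting
   erosions that cross a stack boundary and making them unmeasurable.
2. **Repositioning between visits.** Baseline and follow-up scans are
   acquired months apart in different poses, so voxel-wise comparison
   requires rigid registration and a common-volume mask.

`remodel3d` addresses both: it registers each outer stack to the middle
stack over their overlap region and concatenates them into one
contiguous volume; registers a follow-up scan to its baseline, bone by
bone; and quantifies remodeling voxel-by-voxel. It is aimed at
musculoskeletal imaging researchers working with calibrated density
volumes (MetaImage `.mha/.mhd` or NIfTI, values in mgHA/cm³).

## Method

All registrations estimate a rigid transform `x ↦ R(x − c) + c + t`
(proper rotation `R`, translation `t`, center `c`, physical mm
coordinates), initialized from the intensity-weighted mass centers and
moments of inertia of the two volumes and refined by Nelder–Mead
simplex search maximizing the Pearson correlation `r` of overlapping
voxel intensities. Resampling uses cubic B-spline interpolation.

Remodeling is computed inside the largest common volume (LCV) of the
registered pair: with baseline `B` and transformed follow-up `F`,

- formation mask  = clusters of { `F − B > 125` mgHA/cm³ } ≥ 5 voxels,
- resorption mask = clusters of { `B − F > 125` mgHA/cm³ } ≥ 5 voxels,
- fraction = 100 · |mask| / |{`B ≥ 320`} ∩ LCV| (percent of baseline
  bone voxels),

with cluster filtering at 26-connectivity. Scans carrying a motion
score of 4 or 5 on any stack are excluded from quantitative analysis.

Everything is validated against synthetic bone phantoms with known
ground truth (cortical shell, aperiodic trabecular network, erosions,
simulated stack acquisition with motion, simulated formation/resorption
with repositioning and noise); see `docs/methods.md`.

## Worked example

Simulate a scan pair, stitch the stacks, register the pair, and
quantify remodeling:

```bash
remodel3d simulate --seed 5 --spec spec.yaml --out-dir sim
remodel3d stitch --distal sim/stack_distal.mha --middle sim/stack_middle.mha \
    --proximal sim/stack_proximal.mha --stack-length-mm 3.64 \
    --out stitched.mha --transforms-out transforms/
remodel3d register --baseline sim/baseline.mha --followup sim/followup.mha \
    --mask sim/periosteal_mask.mha --out-dir pair/
remodel3d remodel --pair-dir pair/ --out report.json --overlay overlay.mha
```

which prints, for a simulation containing one 0.4 mm formation sphere
and no resorption:

```
wrote synthetic scan pair to sim
stitched: metrics distal=0.9980, proximal=0.9981
registered: metric=0.9937 converged=False iterations=442
formation 0.97%  resorption 0.00%
```

The stitch metrics are the final correlations of the two stack
registrations (≈ 1 means the overlap regions match after alignment; a
value below 0.5 flags the stitch for review). The remodeling line is
the headline result: 0.97 % of baseline bone voxels were detected as
newly formed — the simulated sphere — and none as resorbed. A
`converged=False` registration with a high metric simply means the
simplex used its full iteration budget. `report.json` carries the
fractions, voxel counts and parameters; `overlay.mha` labels baseline
bone / formation / resorption for visual review.

Batch studies run from a YAML manifest (`remodel3d run --manifest
study.yaml --out-dir results/`), producing one row per joint pair with
fractions, the pair's motion grade, registration metrics and exclusion
bookkeeping, as CSV and JSON.

The same operations are available as a library:

```python
from remodel3d import read_image, read_mask, crop_to_bone, \
    register_longitudinal, apply_and_mask, analyze_remodeling

baseline = read_image("baseline.mha")
followup = read_image("followup.mha")
crop, _ = crop_to_bone(baseline, read_mask("mask.mha"))
result = register_longitudinal(crop, followup)
pair = apply_and_mask(crop, followup, result)
remodeling = analyze_remodeling(pair)
print(remodeling.formation_fraction, remodeling.resorption_fraction)
```

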