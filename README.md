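# atlasforge

Toolkit for building and validating probabilistic brain atlases from
multi-observer manual segmentations, modeled on the construction of the
CIT168 subcortical atlas: several observers delineate each nucleus on a set
of group-average validation templates, the delineations are fused by simple
averaging into per-region probability maps, left-hemisphere labels are
carried to the right hemisphere by a *reflection warp* (mid-sagittal
reflection → affine → optional diffeomorphic displacement field, resampled
with third-order B-splines), and the result is characterized by
probability-weighted volumetry, hemispheric laterality, label-uncertainty
curves, and rater-reliability metrics.

It is written for neuroimaging methods developers and atlas builders who
need the construction/validation machinery (not the anatomy): all pipeline
stages run on synthetic phantoms that reproduce the study structure, so the
code is fully testable without any imaging data download.

## What it computes

- **Label fusion** — the probabilistic label of region *R* is the voxel-wise
  fraction of delineations (observers × templates) containing the voxel;
  with 3 observers × 8 templates, `P(v) = k/24`.
- **Reflection warp** — right-hemisphere labels from left-hemisphere ones:
  `x → field(affine(reflect(x)))`, applied by pull-back resampling with
  cubic B-splines and post-hoc clipping to [0, 1].
- **Volumetry and laterality** — `V = Σ_v P(v) · voxel volume` (µl,
  integrated per hemisphere), and `L = 100 (V_l − V_r)/(V_l + V_r)` %,
  positive when the left volume is larger.
- **Uncertainty (CRF)** — the cumulative relative frequency of a label's
  probabilities over its non-zero voxels; labels with unreliable boundaries
  carry more mass at low probabilities (more convex CRF).
- **Rater reliability** — Dice `D = 2|A∩B|/(|A|+|B|)` and the directed
  Hausdorff distance `H(A,B) = max_{a∈A} min_{b∈B} ‖a−b‖` in mm (world
  space), assembled into inter-rater (observer pairs per template) and
  intra-rater (template pairs per observer) report tables.
- **Deterministic labels** — maximum-probability labeling with strict
  `P > 0.5` semantics (a voxel at exactly 0.5 stays background).
- **Phantoms** — ellipsoidal ground-truth nuclei with smooth edges,
  controlled left/right volume asymmetry, and simulated observers whose
  boundary disagreement is spatially coherent with calibrated expected
  displacement.

## Worked example

```python
import atlasforge as af

# a small study: 2 nuclei, 3 observers, 8 validation templates
grid = af.VoxelGrid.create((48, 48, 48), (0.7, 0.7, 0.7), centered=True)
spec = af.PhantomSpec(
    grid=grid,
    regions=[
        af.PhantomRegion("RN", (-8.0, -6.0, 0.0), (5.0, 4.0, 3.0)),
        af.PhantomRegion("HN", (-8.0, 7.0, 0.0), (3.0, 2.5, 2.0)),
    ],
    asymmetry=1.05,   # right nuclei 5% larger than left
    seed=20,
)
study = af.make_study(spec)
atlas = af.fuse_observer_set(study.labels)

for region in spec.regions:
    v = af.prob_volume(atlas.labels[region.acronym])
    print(f"{region.acronym}: {v:7.1f} ul  (truth {region.volume_ul:7.1f} ul)")

for rec in af.volume_table(study.truth_left, study.truth_right):
    print(f"{rec.region}: L = {rec.laterality_pct:+.2f}%")

for s in af.summarize(af.pairwise_report(study.labels, "inter")):
    print(f"{s.region}: Dice {s.dice_mean:.2f} +/- {s.dice_sd:.2f}, "
          f"H {s.hausdorff_mean_mm:.2f} +/- {s.hausdorff_sd_mm:.2f} mm (n={s.n})")
```

prints

```
RN:   256.3 ul  (truth   251.3 ul)
HN:    70.2 ul  (truth    62.8 ul)
RN: L = -2.30%
HN: L = -2.13%
RN: Dice 0.86 +/- 0.02, H 1.21 +/- 0.13 mm (n=24)
HN: Dice 0.76 +/- 0.09, H 1.00 +/- 0.18 mm (n=24)
```

The fused volume of the large nucleus recovers the analytic truth to ~2%,
while the small one is inflated by boundary jitter (curvature bias, see
`docs/methods.md`); the ground-truth laterality for a 1.05 volume ratio is
−2.44%, recovered here to within 0.3 points; and the small region scores a
systematically lower Dice at identical absolute boundary noise — the
volume sensitivity that makes Hausdorff the better metric for small nuclei.
Each n = 24 is the C(3,2) observer pairs × 8 templates bookkeeping of an
inter-rater table.

## Command line

```sh
atlasforge synth --out study/ --seed 7          # phantom study + manifest
atlasforge build-prob --labels study/manifest.tsv --out atlas/
atlasforge volumes --atlas atlas/ --out volumes.tsv
atlasforge metrics --labels study/manifest.tsv --mode inter --out report.tsv
atlasforge crf --atlas atlas/ --out crf.tsv
atlasforge prob2det --atlas atlas/ --thresh 0.5 --out det.nii.gz
atlasforge reflect --in L.nii.gz --affine A.mat --out R.nii.gz --plane-x 0
```

Volumes and transforms are NIfTI-1 (`.nii`/`.nii.gz`); affines are 4×4
whitespace-delimited text matrices (forward world→world maps, mm);
displacement fields are 4-D vector NIfTIs (mm, world space). The shipped
preset `syn_cit168.json` (`af.load_syn_preset()`) records the published SyN
parameters for users computing the diffeomorphic leg with an external
backend such as ANTs.

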