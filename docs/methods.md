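# Methods

## Model and procedure

The toolkit implements the construction and validation pipeline of a
multi-observer probabilistic atlas on a fixed voxel grid (RAS+ world
coordinates, mm; the voxel-to-world affine is authoritative, and
1 mm³ ≡ 1 µl so voxel volume is the product of spacings).

1. **Fusion.** Each manual delineation is a binary label; per region the
   probabilistic label is the unweighted voxel-wise mean over all
   delineations (observers × validation templates). No observer weighting
   (STAPLE-style performance estimation) is applied — with mutually
   exclusive regions per delineation, the fused per-voxel probabilities sum
   to at most 1, which is verified at fusion time.
2. **Reflection warp.** Left-hemisphere labels are carried to the right
   hemisphere by the forward composition *reflection about x = 0* → *affine*
   → *optional dense displacement field*. Volumes are resampled by pull-back:
   every output voxel centre is mapped through the chain inverse and the
   input interpolated there (cubic B-spline for probabilistic labels, with
   post-hoc clipping to [0, 1]; nearest for binary/index). The displacement
   field is inverted by fixed-point iteration (tolerance 0.01 voxel, max 20
   iterations). The diffeomorphic *optimizer* is out of scope: fields are
   supplied externally, and the published SyN settings are shipped verbatim
   in `syn_cit168.json` for users driving such a backend.
3. **Volumetry.** Region volume is the spatial integral of the probability
   map per hemisphere; voxels centred exactly on the mid-sagittal plane
   contribute half to each side (the midline rule is otherwise undefined and
   halving avoids systematic bias). Laterality is
   L = 100 (V_l − V_r)/(V_l + V_r), positive when left is larger. Volumes are
   reported at full precision; rounding (integer µl, one-decimal L) is a
   display option only, because L recomputed from rounded volumes does not
   reproduce full-precision L for small nuclei.
4. **Uncertainty.** CRF(t) = #{voxels: 0 < p ≤ t} / #{voxels: p > 0};
   zeros are excluded from the denominator. Default 100 evenly spaced
   thresholds in (0, 1].
5. **Reliability.** Dice 2|A∩B|/(|A|+|B|) and directed Hausdorff
   H(A,B) = max over A of min world-space Euclidean distance (mm) to B,
   computed via an exact Euclidean distance transform with mm sampling on
   axis-aligned grids (KD-tree on world coordinates otherwise). Inter-rater
   reports pair observers within each template; intra-rater pairs templates
   within each observer (all unordered pairs by default; split-half
   "complement" pairing is an option). One symmetrized H (mean of the two
   directions) is reported per pair; both raw directions are retained in the
   detail table. Empty or missing labels are excluded and counted, never
   silently scored 0 or 1.
6. **Deterministic labels.** A voxel gets the region of maximal probability
   if that probability strictly exceeds the threshold (default 0.5; exactly
   0.5 is background). Ties are broken by vocabulary order and logged.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| grid spacing | 0.7 mm isotropic | template resolution used throughout the examples |
| fusion weights | equal | simple averaging; optional non-negative weights |
| prob2det threshold | 0.5 (strict >) | maximum-probability deterministic labels |
| CRF thresholds | 100 in (0, 1] | bin count unconstrained by the method |
| field inversion | 0.01 voxel, ≤20 iter | fixed-point inversion of displacement fields |
| probability clip tolerance | 1e-6 at load | B-spline overshoot clipped, larger excursions rejected |

### Affine registration

The affine leg of the reflection warp is estimated internally: 9 DOF
(translation, rotation, anisotropic log-scale about the fixed-image centre),
multi-resolution (downsampling factors 4, 2, 1 with Gaussian pre-smoothing
of σ = factor/2 voxels), minimizing mean-squares (or 1 − cross-correlation)
between the pulled-back moving image and the fixed image. The optimizer is
derivative-free Powell descent with identity initialization — chosen over
plain gradient descent because trilinear-interpolation gradients are noisy
at coarse levels, while Powell is deterministic and robust there; repeated
runs give bit-identical transforms. On budget exhaustion the best-so-far
transform is returned flagged `converged=False`. With a single compact blob
the 9-DOF problem is near-degenerate (rotation/scale trade against
translation); registration test phantoms therefore contain several tilted
ellipsoids. Translation recovery on such phantoms is ≤0.2 mm
(≲0.15 voxel at 1.4 mm spacing) across a 20-case seeded suite.

## Synthetic phantoms

`phantom` generates the full study structure: ground-truth nuclei are
ellipsoids (radial signed distance passed through a Gaussian edge of scale
`boundary_softness_mm`, default 0.7 mm = 1 voxel), mirrored to the right
hemisphere with per-region volume ratio `asymmetry` (semi-axes scaled by
asymmetry^(1/3), so ground-truth laterality is exactly 100(1−r)/(1+r)), plus
an intensity image (region fields at graded contrasts on a broad central
blob whose scale is tied to the grid so it decays to ~0 inside the field of
view — otherwise boundary truncation biases registration tests).

**Observer model.** Raters disagree by spatially coherent boundary
displacement, not independent voxel flips. A simulated delineation includes
voxel x when d(x) < δ(x), where d is the truth's latent signed boundary
distance (inverted analytically from the probability profile when the edge
scale is known, else a signed Euclidean distance transform of the 0.5-mask)
and δ is a smooth zero-mean Gaussian random field (correlation scale 2×
boundary softness, floor one voxel) with amplitude calibrated so
E|boundary displacement| = `jitter_mm` exactly (σ_δ = jitter·√(π/2)). Zero
jitter reproduces the 0.5-thresholded truth bit-exactly. All draws flow
from one master seed through per-(template, observer, region) seed
sequences, so a fixed spec is byte-identical across runs.

**Defaults as study conditions.** The stock study is 16 regions × 3
observers × 8 templates on a 64³ grid at 0.7 mm. Jitter defaults to 0.3 mm:
the reported inter-rater Dice ≈ 0.94 for the largest nucleus at this
resolution implies a mean boundary disagreement of ≈0.3–0.4 mm via the
first-order relation 1 − D ≈ 3·E|δ₁−δ₂|/(2r). Default region semi-axes are
graded 5.5–6.5 mm (smallest axis ≥ 3.85 mm): boundary jitter inflates the
expected fused volume by a curvature term ≈ 3σ_δ²/r², so regions were sized
(before any test was frozen) to keep that bias well under the 5%
volume-recovery tolerance; with r_min ≈ 3.9 mm and σ_δ ≈ 0.38 mm the
predicted bias is ≤ 3%, matching the observed worst case. The same formula
says sub-2.5 mm nuclei *cannot* meet 5% under this noise level — small-region
volume inflation is a real property of threshold-and-average pipelines, not
an artifact, and the worked example in the README shows it.

**What the phantoms do not emulate.** MRI contrast, bias fields and noise
spectra; inter-subject registration error; systematic (shared) observer
bias — fused phantom labels are unbiased around the truth boundary, whereas
real observers can be collectively wrong; non-ellipsoidal, interdigitated
anatomy. Passing recovery tests therefore demonstrates the correctness of
the fusion/volumetry/reliability machinery, not the anatomical accuracy of
any real atlas.

## Numerical choices and degenerate inputs

- Cubic B-spline interpolation overshoots at sharp probability edges; maps
  are clipped to [0, 1] after resampling (and `apply_chain(..., clip=False)`
  exposes the raw overshoot for inspection). At load time, overshoot within
  1e-6 is clipped with a warning; more is a validation error.
- The mid-sagittal reflection is an exact lattice flip whenever the plane is
  on-lattice (and hence an exact involution for binary maps); off-lattice
  planes snap binary/index flips to the nearest voxel (logged) and resample
  continuous maps through the B-spline path.
- Dice/Hausdorff on empty labels raise `UndefinedMetricError`; laterality on
  two zero volumes raises; CRF on an all-zero map raises. Silent 0/1
  defaults would corrupt summary tables.
- `prob2det` ties (equal maximal probabilities above threshold) are broken
  by vocabulary order and counted; raising the threshold can only shrink
  regions (monotone by construction).
- Validation splits (n subjects into two halves) use seeded permutation;
  the original study's RNG is unrecoverable, so reproducibility within this
  toolkit is the goal rather than matching any historical draw.
- The right-hemisphere resampling grid defaults to the native template grid
  (not upsampled); whether clipping followed B-spline interpolation in the
  original pipeline is unstated, so clipping is applied and documented here.

## Problem sizes used in the test suite

Tests run on 32³–64³ grids at 0.7–1.4 mm spacing: large enough that
discretization error is a small fraction of every tolerance tested, small
enough to iterate on a laptop. The registration suite recovers 20 random
translations on a 32³ phantom; the Hausdorff implementation is checked
exactly against a brute-force all-pairs oracle on ≥200 random label pairs up
to 12³ voxels; volume/laterality recovery uses the stock 64³ study.

## Known limitations

- Only the affine leg of registration is estimated; diffeomorphic fields
  must come from an external tool (preset provided).
- Grids must be axis-aligned for `reflect_midsagittal` and for the EDT fast
  path (the Hausdorff KD-tree fallback handles oblique grids; reflection has
  no oblique fallback).
- Hemisphere assignment is a fixed plane (default x = 0); curved
  inter-hemispheric boundaries are out of scope.
- No NIfTI-2/CIFTI/DICOM support, no on-the-fly reorientation of oblique
  acquisitions, and no bit-compatibility guarantee with any released atlas
  files.
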