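# Methods

## Model and pipeline

`lesionlong` segments white-matter lesions in a co-registered,
skull-stripped, bias-corrected T1/FLAIR pair at two time points.  Four
stages run in order:

1. **Cross-sectional analysis** (per time point).  A 3-class Gaussian
   mixture with spatially varying priors segments the T1 image into
   CSF/GM/WM by EM.  FLAIR class parameters are estimated from the T1
   posteriors; voxels brighter than every normal class mean whose
   smallest Mahalanobis distance to a normal class exceeds κ are lesion
   candidates, scored `1 − 2·Φ̄(z_min)` (one minus the best two-sided
   Gaussian tail consistency).  Candidate T1 intensities are refilled
   with seeded draws from the WM Gaussian and the loop repeats until
   the candidate count changes by <1% (max 10 rounds).  The lesion map
   is folded into the tissue posteriors as a fourth class.
2. **Difference image.**  The non-reference FLAIR is divided by the
   exponential of the Gaussian-smoothed (FWHM 30 mm, masked) log-ratio
   with the reference — removing only the *differential* bias field —
   then histogram-matched to the reference at 256 quantile anchors
   (monotone piecewise-linear mapping, linear tail extrapolation), then
   subtracted.  The difference is always oriented (t2 − t1) in both
   reference spaces, so lesion growth is the positive mode everywhere.
   The transition model only applies inside an analysis mask: voxels
   whose WM+LES membership exceeds 0.5 in at least one time point,
   which excludes brain-contour and CSF/GM voxels whose difference
   values are artifact-dominated.
3. **Joint EM.**  Per voxel the model is
   `P(I1|L1,θ1)·P(I2|L2,θ2)·P(D|L1,L2,ζ)·P(L1)·P(L2)` over the 16
   ordered label pairs.  The transition table maps (WM,WM) and
   (LES,LES) to *static*, (WM,LES) to *growth*, (LES,WM) to
   *shrinkage* — each a Gaussian on `D` — and the remaining 12 pairs to
   a fixed uniform density.  E- and M-steps are closed-form; the
   observed-data log-likelihood (summed log E-step normalizers) is
   tracked and must be non-decreasing, which is asserted at run time.
   Marginal sums over the other time point's label give each time
   point's soft segmentation.
4. **Pruning.**  In order: hyperintensity gate (FLAIR above the
   WM-soft-weighted mean + 2·SD), WM-region gate (inside the
   cross-sectional WM+LES region dilated 1 mm), optional exclusion
   mask, binarization at posterior > 0.9, and removal of connected
   components below 0.005 ml.  The gate order follows the narrative
   order of the rules, with the volume rule necessarily after
   binarization; both thresholds are strict inequalities.

Stages 2–4 run with each time point as reference, and the whole block
iterates: iteration 1 takes LES priors from the cross-sectional stage,
later iterations convert the previous pruned masks to priors (LES mass
0.9 inside the mask, tissue priors rescaled to the remaining 0.1,
untouched outside).  The loop stops when the worst per-time-point
(1 − Dice) between consecutive masks is below 0.01 (max 10 iterations;
phantoms typically converge in 2–3).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `kappa` | 3.0 | Mahalanobis threshold for FLAIR lesion candidates (unitless SDs) |
| `fwhm_mm` | 30 | differential bias smoothing kernel (mm) |
| `n_levels` | 256 | quantile anchors for histogram matching |
| `analysis_threshold` | 0.5 | WM+LES membership gate for the difference analysis mask |
| `prior_floor` | 1e-3 | floor applied to class priors in the joint E-step |
| `posterior_threshold` | 0.9 | lesion binarization level (strict >) |
| `min_volume_ml` | 0.005 | minimum lesion component volume (ml) |
| `dilation_mm` | 1.0 | WM-region dilation margin (mm) |
| `connectivity` | 18 | lesion component connectivity (face+edge) |
| `min_voxels` / `min_inslice` | 20 / 5 | lesion-change qualification rule |
| `convergence_tol` | 0.01 | outer-loop (1 − Dice) tolerance |

The 0.9 and 0.005 ml values are the method's empirically established
pruning constants; κ, the smoothing FWHM, anchor count, analysis and
region thresholds, connectivity and slice axis are not pinned down by
the method description and are exposed as configuration with the
defaults above.

## Design choices where the design was open

- **Prior floor.**  Class priors are floored at 1e-3 before
  normalization in the joint E-step.  A hard zero LES prior would
  forbid any posterior lesion mass at that voxel, making cross-time
  lesion recovery — the model's central benefit — impossible; real
  soft segmentations are never exactly zero, and the floor makes the
  implementation honor that.
- **Difference sign.**  (t2 − t1) in *both* reference spaces, so one ζ
  parameterization (growth positive, shrinkage negative) serves both
  directions.
- **ζ initialization.**  Static mean/variance from difference values
  where both priors agree on WM or on LES; growth/shrinkage means at
  ±the 95th percentile of in-mask |D| with the static variance.  The
  uniform density is fixed at 1/(range of in-mask D) and is *not*
  re-estimated — maximizing it would degenerate the M-step.
- **Parallel direction passes.**  Within one outer iteration both
  reference-space passes read the same prior snapshot and their
  updates are applied together.  This makes the pipeline exactly
  symmetric: swapping the two time points yields bit-identical swapped
  masks (the per-time-point RNG streams are keyed to the image bytes,
  not the argument position).
- **Lesion-wise F1.**  Defined as the harmonic mean of LTPR and the
  lesion-wise positive predictive value (1 − LFPR).  A harmonic mean
  of LTPR with LFPR itself would *reward* false positives; the PPV
  form is the meaningful score and is what this package computes.
- **Degenerate-mass guards.**  Variances are floored at
  1e-6·(intensity range)²; a mixture class with less than ~10 voxels
  of prior mass is rejected as degenerate (scaled down for tiny
  inputs); an M-step class with less than 10 voxels of responsibility
  keeps its previous parameters instead of erroring.
- **Empty-mask conventions.**  Dice of two empty masks is 1; LTPR is
  NaN for an empty reference; LFPR is NaN for an empty automatic mask;
  Pearson correlation is NaN under zero variance.  Division errors are
  never raised.
- **No MRF, no atlas.**  The spatial regularization and atlas priors
  of full clinical pipelines are out of scope here; tissue priors are
  caller-supplied and an optional Gaussian posterior smoothing (off by
  default) is the only spatial coupling.
- **Interface shape.**  Functions are the primary interface; the
  `lesionlong` CLI is a thin layer for shell use (phantom generation,
  per-stage runs, full pipeline, evaluation reports).

## The phantom, and what the tests do and do not show

The generator emulates the *structure* of serial MS imaging: nested
ellipsoids (CSF ventricle ⊂ WM core ⊂ GM shell) inside a brain mask;
spherical lesions placed fully interior to the WM with ≥2 voxel
clearance and minimum pairwise separation; evolution by type (new,
disappearing, enlarging = dilation by a radius factor, shrinking =
erosion, static); FLAIR lesions hyperintense (mean 160 vs WM 100, SD
8 → contrast-to-noise 7.5, comfortably above the WM-mean + 2·SD gate)
and T1 lesions GM-like (95 vs GM 90); independent smooth multiplicative
bias fields per time point (amplitude 0.1, scale 20 mm, built from
smoothed seeded white noise); optional additive scanner noise (default
0 — the per-class sampling SD already provides the within-class
variability the mixture models).  Default: 64³ voxels at 1 mm³, 9
lesions (3 static, 2 new, 1 disappearing, 2 enlarging, 1 shrinking)
with radii 2.2–3.2 mm, i.e. every lesion and every growth shell is
large enough to qualify under the 20-voxel/5-per-slice rule.

The phantom has no partial-volume mixing, no anatomy, no registration
error, no motion or ghosting, and its classes are exactly Gaussian —
the model's assumptions hold by construction.  Passing tests therefore
demonstrate *correctness of the algorithm* (EM monotonicity, the
factorization limit, parameter and lesion recovery, rule behavior,
determinism), not clinical-grade accuracy: phantom Dice scores near
1.0 say nothing quantitative about performance on clinical MRI, where
partial volume, registration residue and non-Gaussian intensity
structure dominate the error budget.

## Numerical policy

All densities are computed in log space and per-voxel normalization
uses log-sum-exp; a post-normalization zero is an error, never a NaN.
EM stops on relative bound improvement < 1e-5 (inner tissue EM) /
1e-5 (joint EM, max 50 iterations); a bound decrease beyond 1e-8
relative aborts with an error since it can only be an implementation
bug.  A tolerance of 0 disables early stopping (used when comparing
against an iteration-matched independent-EM oracle).  NIfTI affines
round-trip through the float32 header representation; volumes
containing NaN are rejected at load.  Grids must match exactly — the
package never resamples.

## Problem sizes

Tests and the acceptance script run on 64³ phantoms (~83k brain
voxels), the package's reference configuration; the full pipeline
takes a few seconds there and scales linearly in brain voxels times
the 16 label pairs per joint-EM iteration.

## Known limitations

Two time points only (chain pairs for longer series); single-channel
(FLAIR) intensity model in the joint stage; no atlas priors or MRF; no
registration or skull stripping; the exclusion mask must already be in
subject space; phantom realism as described above.
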