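# lesionlong

Two-time-point white-matter lesion segmentation for multiple sclerosis
follow-up imaging, built around a **joint expectation-maximization (EM)
model** that couples the two scans through the FLAIR difference image.

MS lesions are hyperintense on FLAIR and GM-like on T1-weighted MRI.
Segmenting each scan of a longitudinal pair independently wastes the
strongest signal available — what changed, and what stayed the same,
between visits.  `lesionlong` segments both time points *jointly*: a
lesion confidently seen at one visit and a quiet difference signal pull
the segmentation of the other visit toward consistency, recovering
lesions a single-time-point method misses, while true change (new,
enlarging, shrinking, disappearing lesions) is carried by the
difference image.

## The model

Per brain voxel, with tissue labels `L1, L2 ∈ {CSF, GM, WM, LES}` for
the two time points, FLAIR intensities `I1, I2` and the normalized
difference image `D`:

```
P(I1, I2, D, L1, L2, γ) = P(I1|L1, θ1) · P(I2|L2, θ2) · P(D|L1, L2, ζ) · P(L1) · P(L2)
```

- `P(I|L, θ)` — per-class Gaussian intensity model, one per time point;
- `P(D|L1, L2, ζ)` — the transition model: the ordered label pair maps
  to a transformation class — *static* for (WM,WM) and (LES,LES),
  *growth* for (WM,LES), *shrinkage* for (LES,WM) — each modeled as a
  Gaussian on the difference intensity; every other pair gets a fixed
  uniform density (only WM↔lesion transformations are modeled);
- `P(L1), P(L2)` — soft priors from each time point's own
  cross-sectional segmentation (EM tissue mixture + Mahalanobis lesion
  outlier detection + lesion filling).

EM maximizes a Jensen lower bound of the log-evidence: the E-step is
the per-voxel posterior over the 16 ordered label pairs, the M-step is
closed-form weighted Gaussian updates for `γ = {θ1, θ2, ζ}`.
Marginalizing the joint posterior over one time point's label yields
the other's soft segmentation.  Pruning then removes non-lesion
candidates (below WM-mean + 2·SD FLAIR intensity, outside the WM
region, inside an optional exclusion mask, or smaller than 0.005 ml)
and binarizes at posterior 0.9.  The whole joint+pruning stage runs in
both reference spaces and is iterated with updated lesion priors until
the masks stop changing (typically ~3 iterations).

A seeded synthetic phantom (nested-ellipsoid brain, evolving WM
lesions, per-scan bias fields, Gaussian noise) provides ground-truthed
inputs for every test.

## Worked example

```python
import lesionlong as ll

spec = ll.PhantomSpec(seed=3)           # 64³ phantom, 9 evolving lesions
t1a, fla, t1b, flb, mask, truth = ll.generate_phantom_pair(spec)
pa = ll.tissue_priors_from_truth(truth.tissue_t1, mask, 2.0, spec.spacing, "t1")
pb = ll.tissue_priors_from_truth(truth.tissue_t2, mask, 2.0, spec.spacing, "t2")

res = ll.run_longitudinal(t1a, fla, t1b, flb, mask, pa, pb,
                          config=ll.PipelineConfig(seed=42))
print("Dice t1:", round(ll.dice(res.mask_t1.data, truth.lesions_t1), 3))
print("Dice t2:", round(ll.dice(res.mask_t2.data, truth.lesions_t2), 3))
print("change:", res.change)
```

prints

```
Dice t1: 0.997
Dice t2: 0.99
change: LesionChangeCounts(new=2, disappearing=1, enlarging=2, shrinking=1)
```

i.e. both time points' lesion masks overlap the phantom truth almost
voxel-exactly, and all lesion-change events (2 new, 1 disappearing, 2
enlarging, 1 shrinking, using the >20-voxel / ≥5-per-slice
qualification rule) are counted exactly.

The same flow is available from the shell:

```
lesionlong phantom --seed 3 --out work/
lesionlong run --t1-a ... --flair-a ... --t1-b ... --flair-b ... \
    --mask work/brain_mask.nii.gz --priors-a ... --priors-b ... \
    --out work/out --seed 1
lesionlong eval --ref-t1 ... --ref-t2 ... --auto-t1 ... --auto-t2 ... --out report.json
```

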