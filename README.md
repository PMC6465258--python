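# marrowtex

SVM texture classification of diffuse bone-marrow infiltration on
sagittal T1-weighted lumbar-spine MRI — as a tested, reproducible
pipeline on synthetic spine phantoms.

## The problem

On T1-weighted images, normal adult vertebral marrow is bright (fatty)
while diffuse hematologic infiltration (multiple myeloma, leukemia,
lymphoma, …) lowers and roughens the signal *everywhere at once* — no
focal lesion stands out, so the pattern is easy to miss. This package
implements the complete analysis chain for detecting that pattern with a
support vector machine over raw marrow pixels, and the statistics used
to compare such a classifier against human readers and to plan the
training-set size a target accuracy requires. It is written for imaging
scientists who want to study, stress-test, or extend each stage in
isolation; patient data are replaced by a seeded synthetic phantom, so
every result is exactly reproducible from a seed.

## The method

1. **Disk normalization** — subtract the mean intensity of the annulus
   fibrosus (outer fifths along the anterior–posterior extent) of the
   most cranial non-degenerated intervertebral disk; removes global
   per-scanner intensity offsets.
2. **GrowCut segmentation** — a seeded 3D cellular automaton: voxel *p*
   is conquered by neighbor *q* when `g(|I_p − I_q|)·θ_q > θ_p` with
   `g(x) = 1 − x/Δ`, synchronous updates, until no label changes.
3. **Raw-pixel windows** — one population-minimal rectangular window per
   vertebral body S1–L1, read at 1, 3 or 9 consecutive sagittal slices;
   feature dimension `6·h·w·n_slices`, min–max scaled to [0, 1] on the
   training set.
4. **C-SVM** (libsvm backend) with 3rd-order polynomial, tangent
   hyperbolic, or radial-basis-function kernel; `(C, γ)` by grid search
   maximizing stratified 5-fold cross-validation accuracy.
5. **Diagnostics** — Wilson 95% CIs for accuracy/sensitivity/
   specificity, Mann–Whitney AUC with DeLong variance and the paired
   DeLong test, McNemar on discordant calls, Cohen's κ with qualitative
   bands, 0–4 reader-confidence binarization at 3.
6. **Learning curve** — fit `y = (1 − a) − b·xᶜ` (Levenberg–Marquardt;
   SSE and `RMSE = √(SSE/(n − 3))`), invert in closed form for the
   training size that reaches a target performance, with delta-method
   95% prediction bounds.

Details, defaults and design rationale: [`docs/methods.md`](docs/methods.md).

## Worked example

`examples/` holds one short script per capability. End to end
(`python examples/03_features_and_svm.py`, 30:30 training and 15:15
test subjects on a compact phantom):

```
population-minimal window: 6x20 -> dimension 720
grid search: C=0.125, gamma=0.0078125 (5-fold CV accuracy 1.000)
test accuracy    100.0% [88.6-100.0]
test sensitivity 100.0% [79.6-100.0]
test AUC         1.000 [1.000-1.000]
```

The window is the smallest marrow bounding box in the cohort (6×20
pixels; 6 vertebral levels × 1 slice → 720 features); at the default
class contrast (30 intensity units, 10× the noise SD) the held-out set
separates perfectly, and the bracketed Wilson intervals quantify what a
45-subject test set can actually certify. Segmentation quality
(`python examples/02_segment_and_normalize.py`, full-size phantom):

```
reference disk: level 6 (most cranial non-degenerated)
annulus mean before normalization:   50.04
annulus mean after  normalization: -2.21e-15
GrowCut converged in 5 iterations; Dice vs ground truth = 1.000
```

Sample-size planning (`python examples/05_sample_size.py`):

```
fitted a=0.0204 b=0.8429 c=-0.2807 (true 0.12, 1.0, -0.45)
SSE=2.12e-03  RMSE=0.0153  asymptote=0.980
training size required for 85% accuracy: 790
curve at that size: 0.8500
95% prediction bounds there: [0.7987, 0.9013]
```

`run_full_experiment` in `marrowtex.orchestrate` chains everything —
kernel × dimension sweep, training-size sweep with repeated draws,
classifier-vs-simulated-reader comparison — into CSV/JSON report files
from a single master seed.

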