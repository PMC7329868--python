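# Methods

This note documents the models and procedures `ctseg` implements, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Data model

Volumes are held as `(slice, row, column)` arrays — through-plane axis
first, 0-based, half-open ranges. NIfTI input in any orientation is
reoriented to this convention from the header affine; files the package
writes read back with no further permutation. Intensities are Hounsfield
units stored as integers in [−1024, 3071] (the common 12-bit CT
convention); z-score normalisation moves data off the HU scale, recorded in
the volume's `unit` field. Labels are non-negative integers with 0 =
background, stored as uint8 on disk. Orientation metadata is carried
opaquely; no spatial resampling is performed — all processing is in voxel
space, with anisotropy tracked through per-axis spacing.

## Synthetic phantoms

The phantom generator produces the statistical structure the framework
assumes, not a physically realistic CT simulation (no sinogram or
beam-hardening model):

* an air background calibrated at −1000 HU, a soft-tissue body ellipse
  (+40 HU), one organ ellipsoid (+60 HU) and an optional tumour ellipsoid
  (+100 HU) intersecting it — tumour/organ contrast is deliberately small
  so that intensity windowing matters;
* per-tissue Gaussian intensity spreads plus global acquisition noise,
  clamped to the 12-bit HU range. The air spread defaults to 10 HU so the
  −1024 HU storage floor stays ≈ 2.3σ below the air mean; a wider spread
  would be truncated by the floor and bias the air mean above −1000 HU;
* variable slice counts and slice thicknesses across a cohort, so
  slice-count-sorted cross-validation is non-degenerate;
* `perturb_cohort` applies a global affine intensity map
  `v → scale·v + shift` emulating vendor/patient-specific intensity
  variation — the distribution shift the CWVRS augmentation anticipates.

Everything is a pure function of `(config, seed)`; per-case seeds are the
cohort seed plus the case index. Ellipsoids yield the small-ROI first/last
slices that are the hardest real cases; what phantoms do **not** contain is
anatomical texture, multiple organs, or partial-volume effects, so passing
results here demonstrate the pipeline's mechanics and relative effects (for
example augmentation vs none), not clinical accuracy.

## Preprocessing

Order: window → z-score → slice sampling → in-plane downsampling.

* **Windowing** clips each volume to its (`0.6`, `0.99`) percentile bounds
  (linear-interpolation quantiles). Per-volume scope is the default; a
  cohort-pooled scope is available. The percentile pair is configurable per
  segmentation problem.
* **Normalisation** uses pooled mean/std over a random subset of at most 10
  windowed cases (a full-dataset statistic is rarely available in a
  clinical deployment; statistics must come from the data at hand). A
  zero-variance subset is a hard error.
* **Slice sampling** reduces each volume to a fixed count (default 16) of
  slices drawn at random positions; background slices (no foreground label)
  are excluded during training, matching their exclusion from test scoring.
  Sampling is without replacement when enough candidate slices exist, with
  replacement otherwise (short volumes must still emit a full stack without
  upsampling). Re-sampling each epoch doubles as augmentation.
* **Downsampling** resizes slices to 128×128 by local-mean (area)
  interpolation; labels use nearest-neighbour so no new label values can
  appear. Tests run at 32×32 for speed; the operators are size-agnostic.

At test time the full volume is windowed, normalised and predicted — no
slice sampling, no augmentation; 2D models run per slice, 3D models on
overlapping 50%-stride slabs with probability averaging.

## CTIA augmentation

Operator order is fixed as rotation → patch → slice skip/interpolate →
CWVRS → noise (spatial before intensity, so intensity statistics apply to
the final geometry). A batch is augmented with probability 0.9 (2D) / 0.8
(3D); CWVRS additionally gates per volume at 0.2.

* **Rotation** draws one angle in [−16°, +16°] shared by all slices of a
  volume (a patient rotates rigidly); bilinear for intensities, nearest for
  labels, out-of-frame fill at the stack minimum / label 0.
* **Slice skipping** removes 1–k non-adjacent interior slices jointly from
  image and labels (coarser effective spacing); **slice interpolation**
  inserts voxel-wise midpoints of adjacent pairs, with the inserted label
  slice copied from one parent. When both are enabled, one of the two is
  chosen per volume by coin flip, and the stack is re-padded/trimmed to the
  fixed slice count so the model shape contract holds.
* **CWVRS** perturbs each predefined tissue window independently — a shift
  of at most ±20 HU and bound changes of at most ±10% of the window width —
  and linearly remaps in-window voxels onto the perturbed window. Voxels
  outside every window are left bit-identical. The default window table
  (soft tissue −150..250, lung −1000..−300, bone 200..2000 HU) uses
  standard radiology presets; when augmentation runs on z-scored data the
  table and shift magnitude are transformed through the same z-score.
  Perturbation magnitudes are kept small relative to typical window widths
  (hundreds of HU): the operator models *slight* vendor/patient intensity
  variation, not a different tissue.
* **Noise** adds an independent zero-mean Gaussian map to intensities only.

Every operator preserves the image/label pairing, never introduces label
values absent from its input, and reduces to the identity at zero
magnitude.

## Loss and metrics

The training loss is `α·L_Tanimoto + β·L_CE` with α = 0.6, β = 0.4. The
Tanimoto loss is computed per class from squared-magnitude sums,

    L_c = 1 − (Ŷ·Y + s) / (|Ŷ|² + |Y|² − Ŷ·Y + s),    s = 10⁻⁵,

then averaged over classes unweighted — each class counts equally however
rare, which is the point under heavy class imbalance. The smooth factor
turns the absent-class 0/0 into loss 0. Crossentropy clamps probabilities
at 10⁻¹² before the log. The analytic gradient of the combined loss is
implemented alongside (the NumPy engine has no autograd) and is verified
against finite differences in the tests.

Evaluation uses per-class Dice on label volumes, with 0/0 → 1 for a class
absent from both prediction and truth (such volumes are identifiable in the
raw score table). On crisp masks Tanimoto and Dice are related by
T = D/(2−D), which the tests verify as smoothing vanishes. Aggregation is
reported both two-level (volumes within fold, then across folds — the
headline) and pooled over all volumes, since "averaged over volumes and
folds" admits both readings.

## Backbones and training

Both architectures replace batch normalisation with instance normalisation
(well-defined at batch size 1) and use LeakyReLU at slope 10⁻². The U-Net
is a plain encoder/decoder with skip connections (default depth 4, base
width 24, doubling per level); the MS-D net keeps full resolution and
appends one densely connected single-width dilated convolution per layer
(default 40 layers, dilations cycling 1..10). 3D variants convolve through
the slice axis but pool only in-plane — CT stacks are short and anisotropic
through-plane. 2D models consume single slices as one channel; the
16-slice stack is a sampling unit, not a channel stack.

The networks run on a small NumPy layer engine written for this package:
dimension-agnostic stride-1 "same" convolution with dilation (tap loops
over BLAS tensordots), instance norm, LeakyReLU, 2× in-plane max-pool and
nearest upsampling, softmax, and ADAM with the standard configuration
(lr 10⁻³, β₁ 0.9, β₂ 0.999). All layers carry hand-written backward passes,
checked against finite differences. This keeps the package dependency-light
and CPU-friendly; the flip side is that production-scale training (full
128×128×16 volumes, full-width networks) is out of reach — defaults exist
for completeness, and tests/experiments use reduced widths and 32×32
phantoms.

Training batches are 28 slices for 2D and 1 volume for 3D. An epoch is a
fixed number of sampled batches (sampling is with replacement, so there is
no natural data pass). Per step: sample volumes → preprocess (fresh slice
sampling) → augment per policy → forward → combined loss → ADAM update. A
non-finite loss aborts with the offending batch identifiers. Runs are fully
reproducible from the seed.

Cross-validation sorts cases by (slice count, slice thickness, identifier)
and cuts the sorted sequence into k contiguous, near-equal folds: each fold
is validated on volume geometries absent from its training data, the
worst-case deployment scenario.

## Stacked ensemble

Member sets follow the division of labour: 3D MS-D nets trained
binary (organ vs background) localise; 2D U-Nets classify all tissue
classes. Within each set, probability maps are averaged; top-k selection
(default 5) by validation score with input-order tie-breaks keeps the
selection deterministic. Three fusion rules are provided, none claimed to
be uniquely correct:

* **mask_gate** (default, training-free): final background probability is
  `max(M_bg, 1 − B)`; remaining mass splits across foreground classes
  proportional to the multi-class map. Encodes the veto role of the binary
  localisers directly.
* **prob_product**: class-wise product fusion, renormalised.
* **meta_learner**: per-voxel multinomial logistic regression on
  (B, M) features, fitted on held-out labelled cases — the "learn to
  balance the members" reading.

## Scaled-down robustness experiment

`ctia_robustness_experiment` is the package's headline protocol at desk
scale: 20 phantoms (32×32 in-plane, 10–28 slices), 2 slice-count-sorted
folds, a 2D U-Net of depth 2 / width 8 trained for 4 epochs × 30 batches of
8 slices, once under CTIA and once without augmentation; each fold's model
is evaluated on its held-out cases after a global intensity shift
`v → 1.05·v + 40 HU`. The compared quantity is the standard deviation of
volume-wise total Dice: augmentation that anticipates intensity variation
should (and does) yield the tighter distribution. Problem sizes were chosen
so the whole experiment runs in a few minutes on one CPU.

Limitations worth knowing: at this scale the tumour class sits near the
detection limit, so its per-volume Dice is nearly bimodal (0 when missed;
1 via the 0/0 convention on the ~10% of tumour-free phantoms). The
tumour-class std is therefore dominated by detection luck rather than
intensity-shift sensitivity, and absolute Dice values are far below what
full-scale training on real data reaches. The experiment demonstrates the
*relative* stabilising effect of CTIA under intensity shift, nothing more.

## Numerical conventions

* Quantiles: linear interpolation between order statistics.
* Dice 0/0 → 1; Tanimoto absent-class → 0 via the smooth term.
* Crossentropy clamp 10⁻¹²; instance-norm ε 10⁻⁵; softmax is max-shifted.
* CWVRS resamples a perturbation up to 16 times if it would collapse a
  window (lower ≥ upper), then skips that window.
* Degenerate inputs fail loudly: empty cohorts, zero-variance normalisation
  subsets, non-integer labels, inverted window bounds, non-square slices
  where squareness is required, cohorts smaller than the fold count.
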