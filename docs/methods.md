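# Methods

## The network and its open design points

The architecture is declaratively specified (`ArchitectureSpec`) and
compiled to NumPy layers. The published description of the block family
fixes the parallel filter counts at 16 (B1), 32 (B2, B3), 64 (B4), 128
(B6), 256 (B8) and 512 (B10) but leaves several points open; the package
resolves them as follows, and each choice is a config knob rather than a
hard-coded constant:

- **Filter counts for B5, B7, B9** are set to 64, 128 and 256, so every
  pair follows the same (f, 2f) progression the stated blocks follow:
  (16,32), (32,64), (64,128), (128,256), (256,512).
- **1×1 reduction width** is `min(filters_parallel, 32)` per block. The
  reduction layer is described only as producing "optimal" channels; the cap
  of 32 keeps the whole binary model at 2,189,810 trainable parameters,
  comfortably inside the published ~3.24 M budget, while leaving the stated
  parallel widths untouched. `default_fabnet_spec(reduce_cap=...)` changes it.
- **Batch normalization** is applied once per block, after the 1×1
  reduction; ReLU follows each parallel conv and the block's BN.
- **Stage extensions C1–C5** are parameter-free average-pool bridges taking
  each post-pool pair fusion down to the final spatial size (7×7 at 224×224
  input) before concatenation. Learned bridges would add parameters the
  budget does not account for; pooled bridges are the simplest reading
  consistent with the published parameter count.
- **Pair 5** receives the same 2×2 average pooling as pairs 1–4 (yielding
  7×7) before stage fusion.
- **Feed direction within a pair** is forward (B5→B6 etc.); the source
  description is self-contradictory on this point and forward order matches
  the B1→B2 case.
- **Initialization** is uniform fan-in, `U(±sqrt(6/fan_in))`, from an
  explicit seed; convolutions carry biases; BN contributes a trainable scale
  and shift per channel.

Parameter accounting exists twice on purpose: `count_trainable_parameters`
sums the actual arrays of a compiled model, while
`parameter_count_formula` is a closed-form summation over the spec fields
(25cf+f and 9cf+f for the parallel convs, 2fr+r for the reduction, 2r for
BN, plus the dense head). The two are compared exactly in tests, so a
regression in either the compiler or the formula is caught by the other.

The engine (`fabnet.nn`) implements stride-1 same-padded convolution via
im2col, batch norm with running statistics (momentum 0.9, eps 1e-5), 2×2
average pooling, global average pooling, a dense layer, and softmax
cross-entropy, each with an explicit backward pass verified against central
differences. Adam, SGD, RMSprop, Adadelta, Adamax and Nadam are provided;
Adam at learning rate 1e-3 is the default protocol.

## Stain normalization

`rgb_to_od` uses base-10 logarithms with incident intensity I0 = 255 and a
+1 guard (`OD = -log10((I+1)/255)`), making the RGB↔OD round trip exact up
to 8-bit quantization. Stain estimation discards pixels with all-channel OD
at or below 0.15, takes the two leading eigenvectors of the tissue-pixel
covariance, and reads the stain vectors off the 1st/99th percentile angles
in that plane; concentrations come from a per-pixel least-squares solve with
negative values clipped to zero; normalization rescales each stain's
concentrations so their 99th percentile matches the reference maxima
(1.9, 1.0) and re-renders through the reference basis, hematoxylin
(0.65, 0.70, 0.29) and eosin (0.07, 0.99, 0.11) normalized. These are the
canonical defaults for this normalization family; all are exposed as
arguments. Hematoxylin is identified as the vector with the larger
blue-channel OD component. Degenerate inputs are errors, not passthroughs:
fewer than 100 tissue pixels raises a no-tissue error; an effectively
rank-1 OD cloud (second/first eigenvalue ratio below 1e-4, or an extreme
angle spread under 1°) raises a degenerate-stain error.

One method is applied uniformly to both dataset styles. The original study
used a different, structure-preserving normalization (SPCN) for the breast
cohort; that method has its own publication and is out of scope here, so
Macenko is the package-wide substitute and the reference basis is a package
choice rather than a reproduction of the original preprocessing.

## Patch budgeting and extraction

The per-class quota `N_i = ceil(mean(x)/x_i · β)` is evaluated in exact
integer arithmetic (`ceil(S·β / (n·x_i))`). The printed formula's glyph
between the class mean and `x_i` is read as a fraction bar — the only
reading under which every class ends up with nearly the same patch total,
which is the formula's stated purpose. Patches are placed uniformly at
random over the valid in-bounds offsets (0-based, half-open windows),
seeded; a fixed-stride grid is available as an option but random placement
matches the "arbitrary extraction" description. Whether the original work
budgeted per image (as here) or pooled per class is not determinable from
the text; per image is implemented. Images smaller than the window raise an
error rather than being upscaled; whole-image mode resizes bilinearly.

## Cohorts, splits, evaluation

The native filename encoding of the breast dataset is not parsed; the
ingestion contract is a documented directory layout
(`category/subclass/patient/magnification/*.png`, or `class/*.png` for the
colorectal style) plus a CSV manifest. Users holding the real data can map
it in by materializing that layout or writing the manifest directly.
Class-folder datasets carry no patient structure, so each image becomes its
own pseudo-patient — image-level and patient-level metrics then coincide by
construction. The printed census of the breast cohort (7,909 images, 82
patients) is embedded as metadata and expanded into a counts-only manifest
for arithmetic checks.

Splits shuffle patients by seed and cut at round-half-up of 0.7·n; CV
assigns shuffled patients round-robin to 5 folds (sizes differ by ≤1). CV
is applied within the training side only; how the original study combined
CV with its 70:30 split is not specified.

The published patient-score and image-accuracy ratios are printed inverted
(they would exceed 1 as written); both are implemented in the conventional
correct/total orientation, which is the only way the patient-score mean can
be a probability. Aggregation is soft: patch probability vectors are
averaged per image and argmaxed afterwards (ties to the lowest class
index); this can disagree with majority voting, and the contract is pinned
by a test. Multiclass precision/recall/F1 are one-vs-rest per class plus
macro averages (the original averaging is unstated). Zero-denominator PRF
cases return 0 with a degenerate flag instead of raising. AUC is a
trapezoidal integral over the threshold sweep and equals the Mann–Whitney
U statistic divided by n_pos·n_neg, which the tests assert.

## Synthetic data: what it does and does not show

The generator emulates exactly the properties the pipeline depends on:
two-stain Beer–Lambert color formation (so stain estimation has a ground
truth and the normalization fixed point is exact by construction),
class-dependent nuclear density and size (so classes are separable and
training can succeed), the patient→image→magnification hierarchy (so
patient-level splitting is meaningfully exercised), and byte-level
determinism under a seed. Nuclei are Poisson-counted ellipses with
hematoxylin concentration ~U(0.8, 1.2) that displace 90% of the local
eosin background (0.35 ± a smooth low-frequency modulation); magnification
is a nucleus scale factor (0.5× at 40X up to 2× at 400X), with no optical
modeling. It does not emulate tissue texture, chromatin structure, stain
artifacts, or tumor morphology — so passing the end-to-end tests shows the
pipeline's plumbing, optimization and bookkeeping are correct, not that the
classifier reaches any particular accuracy on real histology.

Default study conditions for the end-to-end run: two classes at nuclear
densities 5 vs 50 per 100×100 px (well separated: a bare nucleus-count
threshold already classifies >90% of images), 5 patients per class, 3
images per patient at 96×96, β = 8 with 32×32 patches, a 70:30 patient
split, and a reduced two-block variant (filters 8/16, reduction cap 8)
trained 25 epochs with Adam at 1e-3, batch 16. The full 10-block network
at 224×224 with 100 epochs is the published protocol and remains the
package default for real data (`default_fabnet_spec`, `TrainConfig`); the
reduced variant exists because the pipeline's correctness properties are
architecture-size-independent and the small model makes them cheap to
verify. Patch-level accuracy on the synthetic task sits below image-level
accuracy because a 32×32 patch from a sparse-class image can genuinely
contain a nucleus cluster (and a dense-class patch can miss all nuclei);
soft-averaging over an image's patches removes most of that noise, which is
precisely the reason the pipeline aggregates before deciding.

## Numerical choices and degenerate inputs

- Shape validation rejects inputs whose spatial size is not divisible by
  2^(number of pairs) before any compute happens.
- Average-pool backward spreads gradients uniformly (÷4 per 2×2 window);
  bridge pools of k halvings compose k such steps.
- Training is single-threaded NumPy: identical seeds give bit-identical
  parameter trajectories, which the bit-reproducibility test relies on.
- Budget ceilings, split cuts and fold assignment use integer arithmetic;
  no float comparison decides a partition.
- Empty manifests, single-class ROC inputs, images with zero patches, and
  label/head mismatches raise typed errors naming the offending entity.

## Known limitations

- CPU-only NumPy compute: the full 10-block network at 224×224 trains far
  too slowly for real-data experiments; the package targets correctness and
  desk-scale verification, with reduced variants for iteration.
- Macenko-only normalization (no SPCN/sparse-NMF), no color augmentation.
- No tissue-mask–guided patch rejection; patches may sample background.
- The synthetic generator's realism limits are listed above; benchmark
  accuracies on the real breast/colorectal datasets are out of scope.
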