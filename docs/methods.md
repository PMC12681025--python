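# Methods

## Problem setting

A hyperspectral reflectance cube `data[row, col, band]` samples a skin
lesion at 120 band centres uniformly spaced over 460–830 nm
(spacing 370/119 ≈ 3.11 nm). The ground truth is a per-pixel annotation
with three codes: healthy skin (0), tumour visible by dermoscopy (1), and
subclinical extension verified only by histopathology (2). The analysis is
a binary pixel-wise classification — tumour (codes 1∪2) versus healthy —
so that the predicted probability map delineates the full lateral margin,
including the part dermoscopy misses.

## Synthetic phantoms

No clinical cubes are distributed with the package; phantoms with exactly
known margins play their role.

**Spectra.** Each tissue class is an endmember: a baseline reflectance
multiplied by Gaussian absorption dips,
`R(λ) = b · Π_k (1 − d_k · exp(−(λ−c_k)²/2w_k²))`.
Defaults: healthy `b = 0.65` with a broad 575 nm dip (d 0.20, w 35 nm),
an oxyhaemoglobin-like feature; tumour `b = 0.52` with a deeper 575 nm dip
(0.38) plus a 690 nm dip (0.22, w 45 nm) where healthy tissue is flat.
These are not measured tissue spectra — they are the simplest parametric
family that gives each class a distinct signature with a controllable
separation.

**Geometry.** The visible tumour core is an ellipse (default semi-axes
55 × 42 px in a 200 × 200 image, ≈ 25 % tumour prevalence); subclinical
extension is modelled by 2–4 elliptical lobes seeded on the core boundary
and pushed outward so each stays connected to the core — isolated satellite
foci are deliberately out of scope. The per-pixel tumour fraction α ramps
linearly with the signed distance to the margin over `boundary_blur_px`
(default 3 px, i.e. ≈ 45 µm at the emulated 15 µm/px scale), so the margin
is band-limited rather than a hard edge; α is exactly 1 in the interior and
0 in the far field.

**Image formation.** `cube = illum · [α·T(λ) + (1−α)·H(λ)] · (1 + ε)` with
a smooth Gaussian-bump illumination field (mean 1, peak deviation 10 %) and
i.i.d. multiplicative noise ε ~ N(0, 0.05) per pixel and band. Cohorts
jitter geometry and endmember baselines per lesion; lesion *i* depends only
on `(seed, i)`, so any single phantom can be regenerated alone.

**What the phantoms do not model:** spatially correlated noise, specular
glints, within-class biological texture (every healthy pixel shares one
endmember), curvature/shading of real anatomy, and any depth dimension
(deep margins are not assessed). Passing tests on phantoms therefore
demonstrates that the machinery — sampling, training, validation hygiene,
metrics — is correct and that the classifier recovers a recoverable signal;
it does not predict clinical performance.

## Per-pixel samples

Each eligible pixel yields two views of its 25×25 neighbourhood
(reflect-padded at image borders, so column −1 maps to column 1):

* **spatial**: the 25×25×3 slab at the bands nearest 487, 604 and 795 nm
  (indices 9, 46, 108 on the default grid; nearest-band ties break to the
  lower index);
* **spectral**: the neighbourhood's mean spectrum over all 120 bands,
  z-scored by its own band mean and standard deviation. A constant spectrum
  maps to the zero vector with a logged warning.

The z-scoring makes the spectral branch invariant to the multiplicative
illumination field. The per-patch mean spectrum is the functional reading
of "the mean spectrum, normalized": a single half-image mean spectrum would
give every pixel of a half an identical spectral input and could not
support pixel-wise discrimination. That literal constant-per-half variant
remains available (`DatasetSpec(spectral_mode="half_mean")`) for
comparison.

Training pixels are a stratified seeded subsample (default 2,000 per class
per lesion; full enumeration available); a seeded 20 % of them serve as the
validation set for early stopping only. Augmentation applies random
horizontal/vertical flips and 90° rotations to the spatial slab per epoch —
these map the square grid onto itself without interpolation; arbitrary-angle
rotation with reflect fill exists behind a flag. The spectral vector and
label are untouched by augmentation (the window mean is invariant under
these transforms anyway).

## Validation splits

**Vertical half-split.** Columns `[0, ⌊W/2⌋)` train, `[⌊W/2⌋, W)` test,
membership decided by patch centre. A guard band (default 12 px =
⌈25/2⌉−1) excludes columns within that distance of the split line from
*both* sides, so no training patch's 25-wide receptive field can read a
test-half pixel; setting it to 0 recovers literal centre-membership
splitting. One model is trained on the pooled left halves of all lesions
and evaluated on every right-half pixel, pooled across lesions — the
optimistic "large diverse dataset" design.

**Leave-one-out.** Each lesion in turn is held out entirely; the model
trains on all pixels of the remaining lesions and predicts every pixel of
the held-out one — the conservative generalization estimate. Metrics are
computed per fold and aggregated as mean ± sample (n−1) SD; a metric with
an empty denominator in some fold is flagged absent and excluded from that
metric's aggregation with a logged note, never coerced to 0.

## Classifier

* Spatial branch: Conv2D 3→8 and 8→16 (3×3, stride 2), ReLU after each,
  global average pooling → 16 features (25→12→5 spatial size).
* Spectral branch: Conv1D 1→8 (kernel 7, stride 2) and 8→16 (kernel 5,
  stride 2), ReLU, global average pooling → 16 features (120→57→27).
* Head: concatenation (32) → dense 32 + ReLU (optional dropout) → 1 logit;
  tumour probability = sigmoid(logit).

Either branch can be disabled for ablations; the head then consumes the
remaining branch alone. He initialization, Adam (lr 10⁻³, batch 64),
binary cross-entropy with logits with an optional positive-class weight
(`"auto"` sets it to #neg/#pos), at most 30 epochs with patience 5 on
validation loss; the best-epoch parameters are restored. The implementation
is plain NumPy with hand-written backpropagation (im2col convolutions);
with one CPU the default half-split experiment (six 200×200×120 phantoms,
24,000 training samples) trains and predicts all 105,600 test pixels in
about a minute. A layer-by-layer deep-learning framework would add nothing
here: the network is small, and full determinism on CPU is worth more than
GPU speed for a reproducibility-first pipeline. Hyperparameter optimization
is a generic seeded random search over user-declared candidate lists,
reporting the full trial table and the argmin trial.

Pixel-wise prediction evaluates every pixel of a region in batches through
the exact same forward pass as single samples (verified to 10⁻⁵) using a
sliding-window view for patches and a box filter (mirrored boundary,
identical to the patch padding rule) for the per-pixel mean spectra.

## Metrics

A pixel is called positive when its probability is **≥** the threshold
(closed bound, default 0.5; the Youden-J-optimal threshold is reported
alongside, never silently substituted). Accuracy, sensitivity and
specificity come from the confusion counts; the ROC sweeps all unique
probabilities and AUC is the trapezoidal area, which equals the
Mann–Whitney concordance probability with ties counted ½ (asserted to
10⁻⁹ against an independent pairwise-count oracle in the tests). The exact
identity `accuracy = π·sensitivity + (1−π)·specificity` with
π the prevalence is used as a consistency check. Four-colour maps encode
TN/TP/FP/FN as green/blue/red/yellow; their colour histogram equals the
confusion counts by construction.

## Determinism and seeding

A single master seed fans out via
`SeedSequence((master_seed, stage_code[, index]))` with fixed stage codes
(cohort 1, dataset 2, model init 3, shuffle 4, augmentation 5, label
permutation 6). Everything downstream — phantom noise, subsampling,
initialization, batch order, augmentation draws — derives from these, so
identical config + seed reproduces every output file byte for byte, and a
single fold or lesion can be recomputed in isolation.

## Known limitations

* The phantom's within-class spectral homogeneity makes the two classes
  near-separable point clusters after the 625-pixel window averaging. One
  consequence, measured and documented rather than hidden: the
  **permutation-null AUC is an unstable statistic** in this regime. A model
  trained on label-permuted data retains (or random-walks through) a tiny
  systematic between-cluster logit offset; because AUC is scale-free, the
  pooled null AUC lands near 0 or 1 essentially at random instead of
  concentrating at 0.5 (measured per-seed values 0.06, 0.999, 0.90; the
  freshly initialized, untrained network already scores ≈ 0.95). A null
  band like 0.42–0.58 presumes noise-dominated, effectively independent
  per-pixel predictions and is not attainable under these phantom
  conditions; detecting label leakage here requires rank-based or
  permutation-of-the-statistic designs instead.
* Pooled half-split results are optimistic by design (the model has seen
  the same lesions' left halves); leave-one-out is the conservative
  counterpart. Both are reported, never mixed.
* The cohort metadata table is carried verbatim as a fixture; summaries are
  recomputed from its rows (recomputed medians: size 14.5 mm, age 72 y).
* Reflectance is assumed radiometrically calibrated; raw-count cubes and
  flat-field correction are out of scope, as are camera control and
  registration between repeated acquisitions.
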