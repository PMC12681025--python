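# hsimargin

Pixel-wise tumour-margin classification for hyperspectral skin imaging.

High-risk basal cell carcinomas (BCC) frequently extend laterally beyond the
border a dermatologist can see with dermoscopy; this *subclinical extension*
is what makes staged excision (Mohs micrographic surgery) necessary. A
snapshot hyperspectral imager records a reflectance cube — two spatial
dimensions plus 120 narrow wavebands spanning 460–830 nm — over the lesion
and surrounding skin, and the question is whether a supervised classifier
can recover the histopathologically verified margin pixel by pixel.

`hsimargin` implements that analysis as a tested, reusable pipeline for
researchers working on hyperspectral margin delineation:

* **Synthetic skin phantoms** with known ground truth: an elliptical tumour
  core, irregular subclinical lobes growing out of it, Gaussian-dip tissue
  spectra, a smooth illumination field, and multiplicative noise — so every
  stage of the pipeline can be validated against a margin that is known
  exactly.
* **Per-pixel sampling**: each pixel becomes an independent sample described
  by the 25×25 patch around it at three informative wavelengths (487, 604,
  795 nm) and by the patch's mean spectrum, z-scored over bands.
* **A dual-branch classifier**: a compact 2-D convolutional stack on the
  spatial patch and a 1-D convolutional stack along the spectrum, with the
  pooled features concatenated into a small classification head producing
  the tumour probability σ(z) of the central pixel. Training uses
  binary cross-entropy with logits, Adam, flip/rotation augmentation, and
  early stopping on validation loss. The network is pure NumPy, CPU-only,
  and bit-deterministic given its seeds.
* **Two validation designs**: a vertical half-split (left half of every
  image trains, right half tests, with a 12-pixel guard band so no training
  patch can read a test pixel) and image-level leave-one-out
  cross-validation.
* **Pixel-wise evaluation**: confusion counts, accuracy, sensitivity,
  specificity, ROC/AUC (trapezoidal, equal to the Mann–Whitney concordance),
  per-fold mean ± SD aggregation, and four-colour classification maps
  (TN green, TP blue, FP red, FN yellow).

## Worked example

Run the half-split experiment on the default six-phantom cohort
(200×200×120 cubes, 2,000 training samples per class per lesion):

```bash
hsimargin train-halfsplit --seed 1 -o runs/halfsplit
```

```
pooled: accuracy=0.9822 sensitivity=0.9902 specificity=0.9804 auc=0.9988 (n=105600 pixels, 19629 positive)
```

The pooled numbers are computed over every right-half pixel of all six
phantoms (105,600 pixels, of which 19,629 are truly tumour). With clearly
separated tissue spectra and 5 % noise the classifier recovers the known
margin almost perfectly — accuracy 0.98 and AUC 0.999 at the 0.5 operating
threshold; the residual errors sit on the blurred margin itself, visible in
the four-colour maps written to `runs/halfsplit/maps/`. The directory also
contains `metrics.csv` (per-lesion and pooled rows), `roc.csv`, and the
echoed `config.yaml`; re-running with the same config and seed reproduces
every file byte for byte.

The cohort metadata tallies mirror a 30-lesion Mohs-surgery case series:

```bash
hsimargin evaluate
```

```json
{
  "n_lesions": 30,
  "n_subclinical_positive": 19,
  "size_min_mm": 5.0,
  "size_max_mm": 21.0,
  "size_median_mm": 14.5,
  "age_median_years": 72.0,
  "age_min_years": 38.0,
  "age_max_years": 86.0
}
```

i.e. 19/30 lesions show subclinical lateral extension and diameters span
5–21 mm. Other subcommands: `generate` (write a phantom cohort to disk with
RGB previews and annotation overlays), `train-loo` (leave-one-out), and
`render-maps`.

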