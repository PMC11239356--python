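# Methods

`stainlab` re-implements, at desk scale, a virtual-staining experiment:
train a Pix2Pix conditional GAN to paint CD3+ T-cell signal onto H&E
images of lung-cancer tissue, and compare two ways of deriving the
ground-truth cell labels the model is trained on — from the *same*
tissue section as the H&E image (via multiplex immunofluorescence) or
from an *adjacent serial* section. Because the original cohorts are
private, a synthetic paired-section simulator stands in for the tissue;
it gives exact per-cell truth, which makes every downstream mask
operation checkable.

## The synthetic tissue model

A section is a set of elliptical nuclei on a canvas (default 512x512 px,
~150 cells, 20% CD3+). CD3+ cells carry a membranous CD3 signal
rendered as an annulus (ring spanning 0.80–1.30 of the nuclear ellipse,
i.e. 2–3 px at the default scale) in a fluorescence CD3 channel; all
nuclei appear in a DAPI channel. Both fluorescence channels sit on a
uniform 0–20 noise floor, deliberately below the marker threshold of 50
so thresholding is exercised but labels never flip. Brightfield
renderings (H&E and H-DAB IHC) are produced through the standard
optical-density model with the published stain vectors, so the standard
deconvolution matrices separate them exactly (up to 8-bit quantization).

Two modelling choices matter:

* **Morphology cue** (on by default): CD3+ nuclei are drawn smaller and
  rounder (semi-major 3.5–4.5 px, near-circular) than CD3- nuclei
  (6–8.5 px, elongated), mimicking the fact that lymphocytes are
  visually distinctive in real H&E. Without some H&E-visible
  correlate of CD3 status the prediction task would be unlearnable by
  construction. With the cue disabled, nuclear geometry is sampled
  independently of the label and the H&E rendering is invariant under
  label permutation — a property the tests assert.
* **Serial-section corruption**: the adjacent section is the same cell
  population with a rigid offset (default 8 px), per-cell Gaussian
  jitter (sigma 3 px), independent cell dropout (p = 0.25), and
  optionally unmatched new cells. Retained cells keep their ids, so
  tests can measure label-transfer fidelity exactly. The physical
  inter-section distance of real tissue is not characterized by any
  public measurement we rely on; these defaults are free parameters of
  the simulation, not estimates of a real cohort.

Nuclei are placed by rejection sampling with an adaptive minimum
centroid separation (sum of the two semi-major axes + 6 px), which keeps
each cell's dilated CD3 ring from touching neighbouring nuclei; a
bounded attempt budget turns infeasible requests into an explicit
placement error. A fixed `min_dist` override builds "well-separated"
sections for round-trip tests (see below).

## Label derivation

Same-section: threshold the CD3 channel at >= 50, dilate the binary mask
with a 5x5 square structuring element (capturing the membranous signal
around the nucleus), and label every nucleus whose footprint intersects
the mask (logical AND) as CD3+. Chromogenic route: unmix H-DAB RGB with
the Ruifrok–Johnston stain matrix, threshold the DAB channel at >= 100
(both thresholds use the inclusive rule), then proceed identically.
Deconvolution outputs are min-max rescaled to 0–255 per image; a channel
whose optical-density range is below 0.02 maps to all zeros rather than
having numerical unmixing residue stretched across the full range —
without this guard a DAB-free image would produce spurious positives.

Serial-section: labels are derived on the adjacent section's own nuclei
and transferred to the H&E section's nuclei by nearest-centroid
matching — greedy, one-to-one, in ascending Euclidean distance, with
ties broken by the target then source centroid (row, col), so the result
is independent of input row order. There is no distance cap by default
(`max_dist` is configurable). Only CD3+ source cells are transferred;
unmatched nuclei default to CD3-.

Nuclear segmentation is pluggable. Tests use exact truth masks from the
simulator. The default image segmenter is deliberately simple: global
Otsu threshold (floored at half the channel maximum, because Otsu
mislocates the cut when foreground covers well under 1% of a
fluorescence image), hole filling, connected components, and a
distance-transform watershed to split touching blobs. It is a baseline,
not a re-implementation of a learned segmenter.

## Training-image encoding

An H&E image and its label table become a three-channel [0, 1] image:
R = CD3+ nucleus footprints, dilated (5x5) and Gaussian-blurred
(kernel 101, sigma 11.875 at full scale) then peak-normalized so the
maximum is 1; G = eosin; B = hematoxylin (both per-image min-max
normalized after H&E deconvolution). Inference inputs carry only G and
B; R is zero. Images are zero-padded bottom/right to a multiple of the
patch size and tiled without overlap — a 3228x3228 image pads to
3328x3328 and yields exactly 169 256x256 patches. Tiles whose CD3 stain
area (the binary pre-blur mask) is below 10% of the patch are flagged
and excluded, with the boundary kept inclusive; kept tiles are split
90/10 into train/held-out sets (train size = round(0.9 n), seeded).

The blur kernel size and sigma are treated as two independent
configuration constants (no standard kernel-size formula links them).
Min-max normalization is per image; per-cohort normalization would
couple tiles across patients and is not modelled. The 90/10 split is
per tile, not per patient — a known leakage caveat inherited from the
recipe itself, acceptable here because the synthetic "patients" share a
generating distribution anyway.

## The GAN

Generator: U-Net with log2(patch) stride-2 encoder levels (filters
doubling, capped at 8x base), mirrored transposed-conv decoder with
skip concatenation, batch norm on interior blocks, and a scaled-tanh
output bounding values to (-0.5, 0.5). Discriminator: conditional
patch discriminator over the concatenated (input, candidate) pair —
three stride-2 and two stride-1 4x4 conv blocks — yielding a 30x30
logit map for 256x256 patches (6x6 at 64, minimum patch 24 px). Inputs
are images in [0, 1] shifted to [-0.5, 0.5]; inference shifts back.

Four losses: L1 (mean absolute difference, weight 100 throughout), a
soft IoU loss on the R channel after shifting to [0, 1]
(1 - (sum ab + eps)/(sum a + sum b - sum ab + eps), eps = 1e-6; equal to
the Jaccard complement on binary masks), generator adversarial BCE
against an all-ones score map, and the discriminator's BCE (real vs
ones + fake vs zeros). The IoU weight follows a schedule: 300 epochs at
100 then 150 at 250 for the same-section recipe, 250 then 500 for the
serial recipe. Batch size defaults to 350 and is clamped (with a
warning) when it exceeds the dataset. Optimization is Adam at lr 2e-4,
beta1 0.5 — the published Pix2Pix defaults; the adversarial BCE is
computed from logits in numerically stable form, and the probabilities
reported by the loss API match it.

The network layers (convolution, transposed convolution, batch norm)
and Adam are implemented in numpy with explicit backward passes,
validated against finite differences in the test suite. This keeps the
whole experiment single-threaded, dependency-light and bit-reproducible
for a fixed seed. Batch normalization always normalizes with the
statistics of the batch at hand (the Pix2Pix convention at inference
too), so predictions depend on the composition of the inference batch;
`predict` therefore processes inputs in fixed-size chunks, which keeps
it deterministic for a given input array. Dropout and data augmentation
are not used.

## Decoding and metrics

Generated patches are decoded by thresholding the R channel at
intensity > 2 on the 0–255 scale (strict), then calling a nucleus CD3+
when strictly more than half of its pixel area overlaps the thresholded
mask. Per-tile accuracy is the fraction of nuclei whose call matches
the truth label, over a shared segmentation; an optional
centroid-matching mode (match within a radius, count agreements) exists
for real data where the two segmentations differ. Tiles without nuclei
have undefined accuracy and are excluded from means.

Counts are compared with Pearson's r plus a Huber robust regression
(epsilon 1.35, the default robustness constant), reporting the Huber
line's coefficient of determination 1 - SS_res/SS_tot on the data.
Ordinal agreement uses Spearman's rho (average ranks for ties);
inter-rater agreement uses Cohen's kappa. Patients are stratified by
predicted CD3+ density: per-patient density is the mean over that
patient's images, and a patient is "above mean" only if strictly above
the cohort mean (ties go below). Survival is compared within a
five-year window — events after 60 months are censored at 60 — with a
two-group log-rank test and a single-covariate Cox model whose hazard
ratio is reported for above vs below.

## The comparison experiment

`run_comparison_experiment` generates paired sections, derives both
label sets, trains two models with identical seeds/architecture — they
differ only in the labels encoded into their training targets — and
scores both on the same held-out sections against exact truth labels,
reporting mean per-tile accuracy, count correlations, and a paired
bootstrap CI on the accuracy difference.

Desk-scale configuration (one CPU, minutes not days): 25 training
sections of 300 cells at 40% CD3+ (a TIL-rich regime, chosen so the
fixed 10% CD3-area flag rule keeps roughly eight 64x64 tiles per
section, ~200 training tiles in total), 4 evaluation sections, 64x64
patches, base 8 filters, batch 8, 24 epochs with the IoU schedule
scaled to (16, 100) + (8, 250). The CD3 blur is scaled with the patch
(256 -> 64 is a factor 4: kernel 25, sigma 3), preserving the
full-scale kernel/sigma ratio; with the full-scale sigma of 11.875 on
4x-smaller geometry the blur floods each tile and the tiny 2/255 decode
threshold calls every nucleus positive, erasing the quantity under
study. Under-trained generators leave low-level background haze above
2/255 with the same collapsing effect, which sets the lower bound on
the training length used here.

## What passing tests do and do not show

The simulator reproduces the *statistical structure* the analysis
depends on — membranous marker signal on a labelled subset of cells,
stain-separable brightfield renders, imperfect serial correspondence —
not the appearance of real tissue. There is no optical PSF, no scanner
or staining variation, no tissue deformation beyond rigid offset +
jitter, and the morphology cue is a clean, learnable surrogate for the
messier real association between lymphocyte morphology and CD3 status.
Passing the in-silico comparison shows that the pipeline detects
label-derivation noise when it exists; it does not certify the
published effect sizes, which depend on private cohorts and full-scale
training. Exact round-trip tests (label -> encode -> decode with
accuracy 1.0) hold on well-separated nuclei, where no nucleus sits
inside the blur tail of another cell's signal; at realistic densities
the blur deliberately spreads signal across neighbours and the decoding
is only approximately invertible.

## Numerical and degenerate-input choices

Inclusive (>=) thresholds for markers, strict (>) for the prediction
threshold and the majority rule, as stated by the recipe. Uniform
images deconvolve to all-zero channels with a warning instead of
dividing by zero. Empty masks stay empty through blur (no peak to
normalize). An empty tile set cannot be split. `n_cells = 0` yields a
valid blank section. Seeds fan out from a single root via
`numpy.random.SeedSequence`; every stochastic component takes an
explicit seed and all tests run derandomized.
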