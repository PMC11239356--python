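# stainlab

Virtual staining of CD3+ T-cells on H&E histology with a Pix2Pix
conditional GAN, built to answer one methodological question: **does it
matter whether the ground-truth cell labels used for training come from
the *same* tissue section as the H&E image, or from an adjacent
*serial* section?**

H&E staining is cheap and ubiquitous; multiplex immunofluorescence
(mIHC) and chromogenic IHC, which actually reveal markers like CD3, are
not. Models that predict marker signal from H&E are therefore trained
on labels *transferred* from a stained section — conventionally an
adjacent 4 µm serial section, where cell-to-cell correspondence with
the H&E section is imperfect (cells drop in and out between sections,
and positions shift). `stainlab` reproduces this comparison end to end
at desk scale, replacing the private patient cohorts with a synthetic
paired-section tissue simulator that provides exact per-cell ground
truth.

The package is aimed at computational-pathology researchers who want a
fully testable, dependency-light reference implementation of the
pipeline: simulation → label derivation → RGB encoding → GAN training →
decoding → statistics.

## The method in brief

* **Labels.** The CD3 fluorescence channel is thresholded at ≥ 50,
  dilated with a 5×5 square element (the signal is membranous), and
  combined with the nuclear mask by logical AND: intersecting nuclei
  are CD3+. Chromogenic images go through Ruifrok–Johnston H-DAB
  deconvolution with a DAB threshold of 100. Serial-section labels are
  transferred to the H&E nuclei by greedy nearest-centroid matching.
* **Encoding.** Each training image is a 256×256 RGB patch with
  R = Gaussian-blurred CD3+ signal (kernel 101, σ ≈ 11.875),
  G = eosin, B = hematoxylin; patches with < 10 % CD3 stain area are
  excluded, the rest split 90/10. A 3228×3228 source image yields
  exactly 169 patches.
* **Model.** U-Net generator G and conditional patch discriminator D
  (30×30 score map at 256×256), trained with

  `L_G = BCE(D(x, G(x)), 1) + λ_L1 ‖G(x) − y‖₁ + λ_IoU L_IoU(G(x)_R, y_R)`

  with λ_L1 = 100 and λ_IoU scheduled 300 epochs @ 100 then 150 @ 250
  (serial recipe: 250 → 500); soft IoU loss
  `1 − (Σab + ε)/(Σa + Σb − Σab + ε)`. Inputs live in [−0.5, 0.5];
  the generator ends in a scaled tanh. The conv-net layers and Adam are
  implemented in numpy with explicit backward passes (validated against
  finite differences), so the whole experiment runs single-threaded and
  bit-reproducibly on a CPU.
* **Decoding.** The generated R channel is thresholded at intensity > 2
  (0–255 scale); a nucleus is called CD3+ if strictly more than half of
  its area overlaps the mask. Per-tile accuracy, Pearson/Huber count
  correlations, Spearman, Cohen's kappa, and a five-year Kaplan–Meier /
  log-rank / Cox survival comparison complete the readout.

See `docs/methods.md` for assumptions, parameter rationale, and what
the synthetic benchmark does and does not demonstrate.

## Worked example

```python
import numpy as np
from stainlab import simulate, labeling, encoding, calling
from stainlab.config import PipelineConfig

sec = simulate.generate_section(n_cells=150, frac_cd3=0.2,
                                canvas=(512, 512), seed=1)
nuclei = simulate.truth_mask(sec)
labels = labeling.derive_labels_mihc(sec.cd3, nuclei)   # threshold 50, dilate 5, AND
truth = {c.id: c.label for c in sec.cells}
print("cells:", len(sec.cells), "CD3+:", sec.n_cd3_pos)
print("label agreement vs truth:",
      np.mean([truth[i] == l for i, l in zip(labels['id'], labels['label'])]))

ser = simulate.make_serial(sec, simulate.SerialParams(seed=99))  # offset 8, jitter 3, drop 25%
src = labeling.derive_labels_mihc(ser.cd3, simulate.truth_mask(ser))
transferred = labeling.transfer_labels(src, nuclei)
print("serial-transfer agreement:",
      np.mean([truth[i] == l for i, l in zip(transferred['id'], transferred['label'])]))
```

Output:

```
cells: 150 CD3+: 30
label agreement vs truth: 1.0
serial-transfer agreement: 0.9133333333333333
```

Same-section derivation recovers the simulator's truth exactly; routing
the labels through a simulated adjacent section (25 % cell dropout,
8 px offset, 3 px jitter) already corrupts ~9 % of them before any
model is trained — that corruption is precisely what degrades the
serial-section model downstream.

The full paired-model experiment (trains two small GANs, ~3 min on one
CPU per seed):

```bash
stainlab compare --seed 0 --full
```

reporting each model's mean per-tile accuracy on shared held-out truth
tiles, count correlations, and a bootstrap CI on the paired accuracy
difference. `stainlab all --preset smoke --out run/` executes every
pipeline stage end to end with a manifest of per-stage checksums.

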