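# vqradiomics

Shareable vector-quantized imaging features ("deep radiomics") for tumor
MRI analysis: a segmentation encoder–decoder whose bottleneck snaps every
latent position to the nearest codeword of a learned codebook
**e** = {e₁, …, e_K} ∈ ℝ^{K×D}. Because the codewords are fixed across the
population after training, they behave like radiomics features extracted
by a deep network: per-volume histograms of codeword occurrences feed a
transparent logistic-regression classifier of glioma-like grade, and a
feature-ablation procedure maps each discriminative codeword back to the
image region it encodes.

## The method

1. **Vector-quantized segmentation.** A slice **x** ∈ ℝ^{C×W×H} is encoded
   to **z**_e; each spatial latent vector is assigned
   zᵢ = argmin_k ‖z_{e_i} − e_k‖₂ and replaced by e_{zᵢ} to give **z**_q,
   which the decoder turns into an S-label logit map. Training minimizes

       L_total = ‖sg[z_e] − e‖² + β‖z_e − sg[e]‖² + L_Dice + L_focal

   with straight-through gradients across the quantization (sg is the
   stop-gradient; the codebook can instead be updated by an exponential
   moving average).
2. **Histogram features.** Per volume, c_k counts occurrences of codeword
   k over all slice latent grids; Σ_k c_k = I·W′·H′.
3. **Grade model.** logit(p) = β₀ + Σ_k β_k c_k on standardized counts
   (HGG-like is the positive class), with stratified 5-fold
   cross-validation and an l2 fallback under perfect separation.
   Codewords significant by an effect likelihood-ratio test and a rank
   comparison between grades are *responsible vectors*.
4. **Responsible regions.** Replacing a codeword by the *background
   vector* (the modal codeword outside the body) and decoding again gives
   a per-pixel L1 logit-difference map; summing map values inside each
   ground-truth label (Kruskal–Wallis + Dunn across NET/ED/ET) shows
   which tumor sub-region a grade's features occupy.
5. **Robustness.** Foreground intensities are shifted/scaled after
   normalization; the *difference ratio* Σ|c_k − c′_k| / Σc_k quantifies
   histogram stability, and the fixed classifier is re-evaluated on
   perturbed histograms.

Everything runs on synthetic phantoms: skull-stripped-style multi-channel
volumes containing an ellipsoidal tumor whose composition differs between
two classes (bright ET-like core + wide rim vs dark NET-like core +
narrow rim), with class-realistic volume variability. The neural network
is a self-contained NumPy engine (im2col convolutions, group
normalization, residual blocks, Adam) with gradient correctness enforced
by numerical-oracle tests, so the package has no deep-learning framework
dependency and is bit-reproducible on CPU.

## Worked example

```python
from vqradiomics.experiment import run_phantom_experiment

res = run_phantom_experiment(seed=1, epochs=8)
print(res.dice.summary())
print(res.cv_report.summary())
print(res.responsible.hgg_responsible, res.responsible.lgg_responsible)
print(res.overlap_hgg.medians, res.overlap_lgg.medians)
```

prints (seed 1, one CPU, ≈2 minutes):

```
{'NET': '0.486 ± 0.486', 'ED': '0.901 ± 0.034', 'ET': '0.588 ± 0.480',
 'tumor_core': '0.974 ± 0.003', 'whole_tumor': '0.950 ± 0.022'}
{'accuracy': '1.000 ± 0.000', 'precision': '1.000 ± 0.000', 'recall': '1.000 ± 0.000',
 'specificity': '1.000 ± 0.000', 'npv': '1.000 ± 0.000'}
[22] [3, 4, 11, 15, 18, 19, 21, 27, 29]
{'NET': 0.0, 'ED': 6752.921427592635, 'ET': 24858.68998527527}
{'NET': 50835.28320833668, 'ED': 16068.300345111638, 'ET': 0.0}
```

Reading: the quantized bottleneck still segments well (whole-tumor Dice
0.95 on held-out phantoms; per-core-label Dice is bimodal because each
core type exists only in its own class, so volumes of the other class
score 0 whenever a stray voxel is predicted, hence the large stds); the
histogram classifier separates the grades perfectly; one codeword is
HGG-responsible and nine are LGG-responsible; and their ablation maps
concentrate in the bright (ET-like) core for the HGG side and the dark
(NET-like) core for the LGG side — the model discriminates grade by the
presence or absence of enhancement-like signal, and the region
statistics make that legible.

The same stages are scriptable per capability in `examples/`, and a thin
CLI (`vqrad synth|train|features|classify|responsible|ablate|robustness|run-all`)
wraps them for shell use with NIfTI/CSV/JSON/YAML artifacts.

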