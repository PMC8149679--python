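# Methods

## Model

The segmentation network is an encoder–decoder over 2D axial slices with a
vector-quantized bottleneck. The encoder stacks residual blocks (two
[3×3 convolution + group normalization + LeakyReLU] stages with an
additive skip; a 1×1 convolution aligns channels when they change), each
followed by a stride-2 downsampling convolution except the last, and ends
in a 1×1 projection onto the codeword dimension D. At the bottleneck each
spatial latent vector is assigned to its nearest codeword in Euclidean
distance, ties broken toward the lowest index for determinism. The
decoder mirrors the encoder: a 1×1 projection from D, nearest-neighbour
2× upsampling + 3×3 convolution stages before each residual block, and a
1×1 head with one logit channel per label.

The full-scale configuration (encoder widths 32-64-128-128-128-128,
decoder reversed, input 4×256×256, latent 64×8×8, K = 512, D = 64) is
constructed and shape-checked in the tests; the stated trunk width (128)
and latent depth (64) are bridged by the final 1×1 projection. The
desk-scale configuration used throughout the experiments is two levels
(widths 8-16), input 4×64×64, latent grid 32×32, K = 32, D = 16. The
fine grid matters for interpretability: the decoder's ablation halo — the
neighbourhood whose logits react when one latent cell is replaced — scales
with the latent cell size, and with 8 px cells (an 8×8 grid) it is as
large as a phantom tumor core, so responsible-region maps cannot
localize. At 2 px cells maps localize well and rim, core and boundary
textures receive dedicated codewords instead of straddling ones.

### Losses and training

* Latent loss: codebook term ‖sg[z_e] − e‖² plus β·commitment term, both
  with mean reduction over all latent elements (value
  (1+β)·mean((z_e−z_q)²)); β = 0.25, the usual vector-quantization
  convention. Gradients route per the stop-gradient contract, and the
  decoder gradient passes straight through the quantization. With the
  EMA codebook option (decay 0.99, Laplace smoothing 1e-5) the codebook
  term leaves the backpropagated objective.
* Segmentation loss: multi-label soft Dice (smoothing ε = 1e-5 in
  numerator and denominator, so a perfect one-hot prediction scores
  exactly zero) plus focal loss (γ = 2, no class weighting).
* Optimizer: Adam (lr 1e-4 full scale; 1e-3 at desk scale, where the
  problem is small and easy), batch 16, 8 epochs at desk scale.
  Augmentation at desk scale: horizontal flips and intensity
  shift/scale jitter; random rotation is implemented but disabled in the
  desk preset for speed. Adam's moment buffers are kept in float64:
  group normalization of all-background slices has (near-)zero variance
  and produces legitimately huge raw gradients whose squares overflow
  float32; Adam's per-coordinate normalization keeps the updates benign,
  but the buffers must not overflow. All axial slices stay in the
  training pool — the network must also learn to handle slices with no
  foreground (the degenerate zero-variance normalization case), which it
  only does if it sees them.
* Codebook initialization: seeded k-means over encoder latents of the
  training set, run once before the first step (a TrainConfig flag,
  default on). With K = 32, randomly initialized codewords are claimed
  almost entirely by the hugely over-represented background (~85% of
  latent cells, made slice-dependent by group normalization); measured on
  a pilot run, ~26 of 32 codewords encoded background variants and the
  whole tumor collapsed into one or two straddling codewords. K-means
  spreads the initial codewords over the latent manifold so tumor
  sub-regions keep dedicated codewords.
* Everything is seeded and bit-reproducible on CPU; group normalization
  has no running statistics, so inference equals training-mode forward.

The network, its gradients and the optimizer are implemented directly in
NumPy (im2col + GEMM convolutions); every layer's backward pass is tested
against central-difference oracles at float64.

## Phantom generator

Each volume is a C=4-channel, 64×64×16 array, background exactly zero
(emulating skull-stripping), containing one axis-aligned ellipsoidal
tumor made of a concentric core and rim. Class 1 (HGG-like) cores are
bright in the designated contrast channel (ET-like, label 3); class 0
(LGG-like) cores are dark there (NET-like, label 1); both rims are
edema-like (label 2, bright in the T2/FLAIR-like channels). Intensity
levels are drawn per volume from per-sub-region profiles (std 0.05), and
voxel-wise Gaussian noise (std 0.05) is added to tumor voxels only, so
labels delineate sub-regions exactly and the background stays zero.

Geometry is drawn from the same distributions for both classes: in-plane
core radii uniform on 7–12.5 px, axial radius 0.18–0.40 of the stack,
rim-to-core factors 1.32 (class 0) vs 1.38 (class 1) — a nominal
"wider rim" for the high-grade class kept below statistical
detectability at cohort size. This mirrors real glioma volumetrics, where
per-region volumes overlap almost completely between grades (per-region
coefficients of variation near 1), so at n = 40 geometry does not
separate the grades; composition — the presence or absence of
enhancement-like core signal — is the class signal, which is exactly the
discriminative feature the analysis is meant to recover. What the
phantoms do **not** emulate: MRI physics (bias fields, partial volume,
registration error), anatomy (no brain, so "background" is the whole
exterior), irregular tumor shapes, 3D context, and inter-scanner
variability. Passing tests therefore show that the pipeline recovers
planted compositional structure at desk scale, not that it reaches any
particular performance on real MRI.

## Preprocessing and histograms

Z-score normalization uses per-volume, per-channel statistics over
non-background voxels only (threshold: all-channel |intensity| < 1e-6 on
the raw image); background remains exactly zero, which keeps
background-vector identification well-posed. Images are resized
bilinearly, labels by nearest neighbour. Histograms count codeword
occurrences over all slice latent grids; conservation Σc_k = I·W′·H′ is
exact. Perturbations act on normalized foreground voxels:
shift x′ = x + m, scale x′ = x·(1 + m) (so m = 0 is the identity; the
functional form is a recorded convention). The difference ratio divides
the summed absolute count change by the original histogram's total
count; a variant dividing by the number of distinct codewords is
available behind a switch.

## Grade model and responsible vectors

The logistic model is fit by unregularized maximum likelihood on
standardized counts; under perfect separation — the norm at desk scale —
it falls back, with a warning, to an l2 penalty (λ = 1 on standardized
counts). Cross-validation is stratified 5-fold with a fixed seed,
HGG-like positive; after CV the model is refit on all volumes for the
responsible-vector analysis.

Two effect likelihood-ratio tests are computed:

* **Leave-one-out** (the classical effect test): refit without codeword
  k; 2(ℓ_full − ℓ_reduced) ~ χ²(1). Under the penalized fallback the
  penalized objective is used on both sides, keeping the statistic
  nonnegative; an independent recomputation oracle checks it to 1e-6.
* **Marginal**: single-codeword model vs intercept-only, with ℓ = 0 at
  complete separation (the limiting unregularized fit).

Candidate selection for responsible vectors uses the **marginal** test.
Rationale: with 40 volumes and several strongly correlated informative
codewords the histograms are perfectly separable and no codeword is
individually necessary, so every leave-one-out statistic is near zero
for any penalty strength — the conditional test is powerless in exactly
the regime where the method is meant to find grade-associated features.
The marginal test asks the intended question (is this codeword's
frequency associated with grade?) and is consistent with the downstream
per-codeword rank comparison. Both sets of p-values are recorded.

The candidate gate applies a Benjamini–Hochberg step-up across the K
codewords (informative codewords sit many orders of magnitude below α,
so only chance admissions are pruned). Two codeword families are
excluded from candidacy by construction: the modal background vector,
and every codeword whose occurrences lie mostly (> 50%) at background
latent cells — such codewords describe the region outside the body, not
an imaging phenotype, and their large counts otherwise couple to tumor
size through the fixed latent-grid budget.

Candidates are then compared between classes. Normality is checked per
class with Shapiro–Wilk (recorded as a gate); the comparison defaults to
the Mann–Whitney rank-sum test because the grades are unpaired — a
literal Wilcoxon signed-rank on size-matched sorted subsamples is
available as ``test="signed-rank"`` and the choice is recorded. A
significant codeword joins the responsible set of the class with the
higher median count.

## Responsible regions

The background vector is the modal codeword over latent positions whose
receptive footprint is majority-background (strict > 50% of the
reduction × reduction pixel block), pooled over volumes; ties go to the
lowest index. Ablation replaces **all** spatial occurrences of the
target codeword, decodes, and takes the per-pixel L1 difference across
logit channels. By default the replaced latent is decoded under the
group-normalization statistics captured from the original decode
("controlled ablation"): without this, replacing a few latent cells
shifts every group's statistics and the difference map acquires a
spatially uniform component proportional to region size rather than to
the codeword's footprint. The naive re-decode is available via
``frozen_norm=False`` and is what the position-by-position
reconstruction oracle tests.

Maps aggregate additively over a responsible set (one-at-a-time
ablations, summed), keeping per-codeword attribution recoverable. For
quantification, raw map values are summed inside each ground-truth label
per volume; per-patient z-scoring exists only for display. Each grade's
responsible region is quantified on the volumes of that grade; a label
absent from a volume contributes a flagged zero sum. Groups are compared
with Kruskal–Wallis and Dunn's all-pairs post-hoc test on joint ranks
(tie-corrected standard errors, Bonferroni adjustment), both validated
against hand-ranked oracles. Per-volume (not per-slice) sums match the
patient-level grading.

## Desk-scale study and what it shows

One experiment per seed: 20 + 20 study volumes, 5 + 5 held-out volumes
(generated from seed + 10000), 8 training epochs, then histograms,
5-fold CV, responsible vectors, background vector, region overlap per
grade, and optionally the robustness sweep on a class-balanced 10-volume
subset (11 magnitudes × {scale, shift}). These sizes keep one full
experiment near two minutes on one CPU. Across five seeds the test suite
verifies: held-out whole-tumor Dice ≥ 0.7, CV accuracy ≥ 0.9, histogram
conservation, difference ratio non-decreasing in perturbation magnitude,
and the region-recovery structure (the grade's responsible region scores
its highest median in the planted core label, with Kruskal–Wallis
significance and a significant Dunn contrast between the two core
labels).

## Known limitations

* **Context-pure rim codewords.** In a noise-free geometric phantom,
  every rim latent cell's receptive field contains the core, so "rim
  surrounding a bright core" becomes a codeword in its own right. Such
  codewords are genuinely and strongly grade-associated (their counts
  are near zero in the other class), survive any honest statistical
  gate, and their ablation maps concentrate — correctly — in the rim.
  Whether one of them dominates a cohort's responsible set depends on
  the codebook layout for that seed, so the bright-core region result
  recovers in most but not all seeds (the dark-core side is more
  robust). Real MRI breaks this context purity through anatomical
  heterogeneity, and a large codebook (K = 512) fragments rim context
  across many low-frequency codewords; neither mechanism is available at
  desk scale, and filtering candidates by where their maps lie would
  assume the conclusion. The per-codeword occupancy diagnostic used to
  establish this is reproducible from the library API.
* The conditional (leave-one-out) effect test is recorded but powerless
  under separation; see above.
* Dice for a core label averaged over mixed-grade volumes is bimodal
  (the label is structurally absent in the other grade, where any stray
  predicted voxel scores 0), so per-label means carry large stds.
* Dead codewords are left in place (no re-seeding); usage counters
  expose them.
* The NumPy engine is CPU-only and 2D; it is not intended for
  full-scale (K = 512, 600-epoch) training, though the architecture
  constructs and runs at that size.
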