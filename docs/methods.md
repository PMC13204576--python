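# Methods

## Problem and pipeline

`strokegraph` segments ischemic stroke lesions in 2-D CT-perfusion (CTP)
slices by casting segmentation as node classification on a superpixel
region-adjacency graph:

1. **Preprocessing.** Intensities outside the Hounsfield window [0, 150] are
   *replaced with zero* (the window acts as a crude tissue mask, so
   out-of-window pixels are removed rather than saturated), the image is
   mapped to [0, 1] via a bit-depth scale, and standardized to 256×256 by
   center crop / zero padding. Training slices may additionally be augmented
   with rotations in [−20°, +20°] and horizontal flips, applied identically
   to image and mask (bilinear interpolation for the image,
   nearest-then-threshold ≥ 0.5 for the mask so it stays binary).
2. **Graph construction.** SLIC partitions the slice into ≈100 superpixels
   ("zones"). Each zone is a node; zones sharing a 4-connected pixel
   boundary are joined by an edge with Gaussian weight
   `w_ij = exp(−d_ij² / 2σ²)` of the Euclidean centroid distance `d_ij`.
   A node is labelled *lesion* when ≥ 50% of its pixels lie in the
   ground-truth mask.
3. **Classifier.** Five stacked graph-convolution blocks
   (ChebConv → BatchNorm → LeakyReLU → BatchNorm), channel widths
   16→16→16→16→16→2, followed by dropout (rate 0.3, training only) and a
   per-node softmax. A ChebConv layer computes
   `Σ_k T_k(L̃) X θ_k + b` with the Chebyshev recurrence
   `T_k(x) = 2x·T_{k−1}(x) − T_{k−2}(x)` on the rescaled graph Laplacian;
   it holds `order·in·out + out` parameters, plus 2 per batch-norm channel.
4. **Evaluation.** Patient-level k-fold cross-validation (all slices of a
   patient share a fold), pixel-level Dice/Jaccard/sensitivity/precision/
   accuracy from predictions painted back onto the pixel grid, ROC on node
   probabilities, paired t / Wilcoxon fold comparisons, and an
   SNR-controlled robustness sweep.

## Spectral machinery and numerical choices

The combinatorial Laplacian is `L = D − A`. Chebyshev filtering needs a
spectrum inside [−1, 1], so the model uses the symmetric-normalized
Laplacian `L_n = D^{−1/2} L D^{−1/2}` rescaled as `L̃ = 2 L_n / λ_max − I`
(a combinatorial `comb` mode is available). λ_max is computed exactly by a
dense symmetric eigensolver — region graphs have N ≈ 100 nodes, so this
costs ~1 ms and keeps the spectrum strictly inside [−1, 1]; a power-iteration
estimator (`estimate_lmax`) is provided and cross-checked for larger graphs.
Isolated nodes are given unit degree, making their `L_n` row zero: they pass
their own signal through unchanged. An edgeless graph yields `L̃ = −I`.

The dense eigendecomposition path (`SpectralDecomposition`, evaluating
`U T_k(Λ) Uᵀ x` with `T_k(cos t) = cos(kt)`) exists **only as an independent
test oracle** for the recurrence; the model never eigendecomposes.

All forward/backward passes, batch normalization, dropout, the
cross-entropy loss, and the optimizers are implemented directly on numpy
arrays. Gradients are exact and are verified against central finite
differences in the test suite (tolerance 1e-4 + 1e-2·|g|, loose only because
the LeakyReLU kink makes finite differences locally one-sided).

Batch normalization operates over the node axis of the single graph in the
current optimization step (one graph per step), with running statistics
(momentum 0.1, ε = 1e-5) used in evaluation mode; a single-node graph
degrades to the identity, since normalizing one sample is undefined.

## Optimization

Defaults: Adadelta, cross-entropy loss, weight decay 6e-4 on the Chebyshev
coefficient tensors, 150 epochs, one step per graph per epoch in a seeded
shuffled order, Chebyshev order 3 in every layer, dropout 0.3.

Adadelta is implemented in its original form, where the per-parameter step
is the ratio of accumulated update RMS to gradient RMS (ρ = 0.9,
ε = 1e-6) — the method has no learning-rate hyperparameter of its own.
The `learning_rate` field (default 1e-4) carries its conventional meaning
for the gradient-descent family (`optimizer="sgd"`); applying it as a
multiplier on Adadelta's adaptive step would bound each update by
`lr·√(E[Δx²]+ε) ≈ 1e-7` and provably freeze the network at its
initialization, so Adadelta's step multiplier is exposed separately
(`adadelta_step_scale`, canonical value 1.0). `learning_rate = 0` disables
updates for every optimizer. Optional inverse-frequency class weights in
the loss are available but off by default.

All randomness (initialization, epoch shuffling, dropout, augmentation,
phantoms, noise) flows from explicit numpy Generators, so seeded runs are
bit-reproducible.

## Design choices where the design was open

- **Node features.** The region descriptor is a 16-bin normalized intensity
  histogram over [0, 1] (`hist16`), matching the fixed 16-wide first layer;
  it is an information-preserving superset of the region mean. `mean` (F=1)
  and `mean16` (mean replicated 16×) modes are selectable.
- **Edge distance.** `d` is the Euclidean centroid distance in pixel units;
  σ defaults to the mean neighbor centroid distance of the graph, which
  keeps weights in a usable range across zone counts (25–150).
- **Adjacency.** Gaussian weights are stored directly in A; only regions
  sharing a pixel boundary are connected; no self-loops (the order-0
  Chebyshev term already passes self-information).
- **SLIC compactness = 0.3.** Unregularized SLIC on noisy slices fragments
  and then merges into far fewer, larger regions, violating the expectation
  that the realized zone count stays within [0.5k, 1.5k]. 0.3 is the
  smallest value that keeps the count stable on both clean and heavily
  degraded phantom slices, and it also maximizes the clean
  label-quantization ceiling (the Dice score of repainting the *true* node
  labels, ≈ 0.98 at 100 zones).
- **Metric aggregation.** Default is globally pooled confusion counts over a
  test fold, which makes `J = D/(2−D)` exact; a per-slice-mean mode exists.
  0/0 conventions: a metric whose denominator-defining reference set is
  empty returns 1.0 (relevant for lesion-free slices).
- **Noise injection point.** AWGN is added to the raw HU-scale slice
  *before* windowing and graph construction, framing noise as acquisition /
  motion degradation. Signal power is the mean squared intensity of the
  whole slice (a brain-only variant is a trivial caller-side change).
- **Augmentation scheduling.** Augmentation is exposed as an operation on
  training samples; the pipeline applies it as offline copies before graph
  construction rather than per-epoch, because each augmented image requires
  a fresh SLIC partition.

## What the phantom emulates — and what it does not

`PhantomSpec` defaults generate per-patient stacks of 2–22 slices of
256×256, an elliptical brain (fixed geometry per patient) with base
intensity drawn per slice from 40–90 HU, smooth low-frequency texture
(sd 6 HU) plus fine noise (sd 4 HU), 0–3 irregular perturbed-ellipse lesion
blobs of radius 10–40 px at +35 HU contrast with internal variation, lesion
area capped at 25% of the brain, a guaranteed lesion-free slice per cohort,
and 0.2% of pixels forced outside [0, 150] so window clipping is exercised.

The phantom reproduces the *structure* of the segmentation problem (class
imbalance, per-patient slice correlation, HU windowing, boundary ambiguity
under SLIC) but not CT physics: no perfusion time series, no skull or CSF
compartments, no spatially correlated acquisition noise, no inter-scanner
intensity shifts. Passing the phantom study therefore demonstrates that the
pipeline's machinery is correct and that the classifier can exploit
regional contrast; it does not certify performance on clinical CTP data.

## Noise robustness: an honest account

On clean-trained models, the phantom sweep shows the expected monotone
degradation with falling SNR. At −4 dB, however, the noise standard
deviation (≈ 50–55 HU for these phantoms) exceeds the lesion contrast
(35 HU), and re-running SLIC on the degraded image dissolves the superpixel
partition: the best Dice achievable by repainting the *true* node labels of
the noisy-image partition is ≈ 0.28. No node classifier on top of that
partition can retain half of a ≈ 0.95 clean Dice, and the trained model
does not. Per-graph normalization at inference, mean-only features, and
injecting noise after the HU window were all measured and none lifts this
ceiling — the limit lives in the graph-construction stage, not in the
classifier. Pixel *accuracy* remains high at −4 dB because the task is
heavily imbalanced.

## Problem sizes used in the test and acceptance runs

The end-to-end study uses a 10-patient cohort (≈ 100–130 slices), 100
zones, Chebyshev order 3, 150 epochs, 10-fold patient-level CV — about 5
minutes on one CPU; unit tests use 2–3-patient cohorts of 64–128 px slices.
The robustness protocol accumulates held-out folds until at least 20 test
slices are covered.

## Known limitations

- Single-channel slices only; no fusion of multiple perfusion maps and no
  3-D supervoxel graphs across slices.
- One graph per optimization step (no mini-batching across graphs).
- Batch-norm running statistics assume training and evaluation slices share
  an intensity distribution; strong covariate shift (e.g. heavy noise)
  violates this, as discussed above.
- The checkpoint format stores arrays as JSON lists: simple and exact, but
  not compact.
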