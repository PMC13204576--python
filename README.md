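# strokegraph

Superpixel-graph Chebyshev GCN segmentation of ischemic stroke lesions in
CT-perfusion slices — for researchers in medical image analysis who want a
fully reproducible, CPU-only reference implementation of graph-based lesion
segmentation, testable end to end on synthetic brain phantoms.

## The method

A 2-D CTP slice is windowed to the Hounsfield range [0, 150] (out-of-window
intensities are replaced with zero), normalized to [0, 1], and partitioned
into ≈100 SLIC superpixels. Each superpixel becomes a node of a
region-adjacency graph: node *i* carries a 16-bin intensity histogram, and
spatially adjacent regions *i, j* are joined with Gaussian weight

    w_ij = exp(−d_ij² / 2σ²),      d_ij = ‖centroid_i − centroid_j‖₂.

Segmentation is node classification with a five-block Chebyshev spectral
GCN. Writing L = D − A for the graph Laplacian and L̃ for its
symmetric-normalized rescaling to spectrum [−1, 1], each layer computes

    X ↦ Σ_k T_k(L̃) X Θ_k + b,    T_k(x) = 2x T_{k−1}(x) − T_{k−2}(x),

followed by batch-norm, LeakyReLU and a second batch-norm; widths are
16→16→16→16→16→2 with Chebyshev order 3 throughout (a 16→16 layer holds
3·16·16+16 = 784 parameters, the final layer 98). After dropout (0.3) a
per-node softmax yields lesion probabilities, which are painted back onto
the pixel grid and scored with Dice (DSC = 2TP/(2TP+FP+FN)), Jaccard,
sensitivity, precision and accuracy under patient-level k-fold
cross-validation. Training uses Adadelta with cross-entropy loss and weight
decay 6·10⁻⁴ for 150 epochs. A robustness protocol injects white Gaussian
noise at target SNRs (−4…+5 dB) into the raw slices and re-runs the whole
pipeline. Everything — including the GCN's forward/backward passes and the
optimizer — is plain numpy; see `docs/methods.md` for the full account.

Because real stroke CTP benchmarks require registration and download, the
package ships a first-class phantom generator (`strokegraph.phantom`)
emulating per-patient stacks of 256×256 slices with textured elliptical
brains and 0–3 irregular lesion blobs, on which the entire pipeline runs in
minutes on one CPU.

## A worked example

```python
import numpy as np
from strokegraph import PhantomSpec, PipelineConfig, generate_cohort, run_cv

cohort = generate_cohort(PhantomSpec(seed=7, n_patients=4))
cfg = PipelineConfig(seed=7)
cfg.eval.k = 4
cfg.train.epochs = 60
out = run_cv(cohort, cfg)
for r in out["reports"]:
    print(f"fold {r.fold_id}: DSC {r.dsc:.3f}  Jaccard {r.jaccard:.3f}")
print("mean DSC:", round(float(np.mean([r.dsc for r in out['reports']])), 3))
```

prints (exactly, given the seed):

```
fold 0: DSC 0.621  Jaccard 0.450
fold 1: DSC 0.883  Jaccard 0.790
fold 2: DSC 0.924  Jaccard 0.859
fold 3: DSC 0.999  Jaccard 0.997
mean DSC: 0.857
```

Each fold holds out one patient entirely; the reported numbers are globally
pooled pixel metrics on the held-out slices, so `J = D/(2−D)` holds exactly.
The narrative scripts in `examples/` walk through each capability (phantom +
graph construction, cross-validated training, the SNR sweep, and the
spectral machinery with its eigenbasis cross-check).

A thin CLI mirrors the library:

```sh
strokegraph phantom --out cohort/ --patients 10 --seed 1
strokegraph run --seed 1          # full pipeline -> artifacts/
```

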