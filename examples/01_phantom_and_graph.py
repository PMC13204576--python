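"""Generate a synthetic CTP-like cohort and turn one slice into a region graph.

The phantom emulates what a stroke CTP study looks like on disk: per-patient
stacks of 256x256 axial slices with an elliptical textured brain, 0-3
irregular lesion blobs, and Hounsfield-like intensities.  A slice becomes a
graph whose ~100 nodes are SLIC superpixels ("zones"), with Gaussian edge
weights between spatially adjacent zones.
"""

import numpy as np

from strokegraph import (PhantomSpec, build_graph_for_slice, generate_cohort,
                         lesion_fraction)

cohort = generate_cohort(PhantomSpec(seed=42, n_patients=3))
print(f"cohort: {len(cohort)} slices from 3 patients")
fracs = [lesion_fraction(s) for s in cohort]
print(f"lesion fraction per slice: min {min(fracs):.4f}, max {max(fracs):.4f}")
# the task is highly imbalanced: even the largest lesion covers a few
# percent of the image.

sample = next(s for s in cohort if s.mask.sum() > 0)
graph, spmap, mask = build_graph_for_slice(sample)
A = graph.adjacency
print(f"\nslice {sample.patient_id}/{sample.slice_index}: "
      f"{spmap.n_regions} superpixel nodes, "
      f"{int((A > 0).sum() / 2)} edges, sigma = {graph.sigma:.1f} px")
print(f"feature matrix: {graph.features.shape} (16-bin intensity histograms)")
print(f"lesion nodes (>=50% lesion pixels): {graph.node_labels.sum()}")
w = A[A > 0]
print(f"edge weights in ({w.min():.3f}, {w.max():.3f}] -- "
      "closer region centroids get weights nearer 1")
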