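"""Segment a synthetic MSI datacube by bisecting k-means.

Builds a small datacube from a rendered scene, clusters the
TIC-normalised pixel spectra, and compares dendrogram cuts against the
planted plaque map (adjusted Rand index).  Also derives a single-ion image
for A-beta 1-40, whose brightest pixels coincide with cored-plaque cores.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from plaquemap.panel import build_abeta_panel
from plaquemap.segmentation import bisecting_kmeans, cut_tree, single_ion_image
from plaquemap.synthio import CLASS_CODES, make_microscopy_scene, make_msi_dataset

panel = build_abeta_panel()
_, truth = make_microscopy_scene(counts={"CP": 3, "DP": 2, "CGP": 2},
                                 field_um=(500, 500), rng_seed=3)
msi, truth = make_msi_dataset(truth, panel, noise_cv=0.10, rng_seed=4,
                              mz_step=2.0)

tree = bisecting_kmeans(msi, max_leaves=6, seed=5)
foreground = truth.msi_class_map > 0
for n in (2, 3, 4):
    labels = cut_tree(tree, n)
    ari = adjusted_rand_score(foreground.ravel(), labels.ravel())
    print(f"cut at {n} clusters: plaque-vs-background ARI = {ari:.3f}")

pep = next(p for p in panel if p.name == "Abeta1-40")
img = single_ion_image(msi, pep.mz_obs, pep.mz_obs / 1000)
iy, ix = np.unravel_index(np.argmax(img), img.shape)
kind = {v: k for k, v in CLASS_CODES.items()}.get(truth.msi_class_map[iy, ix])
print(f"\nbrightest A-beta 1-40 pixel lies in a {kind} plaque — the x-40-rich "
      "dense deposits (cored-plaque cores and coarse-grained plaques).")
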