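"""Build analysis-ready SC and FC matrices from raw-style inputs.

Streamline counts become symmetric streamline-proportion matrices, a
correlation matrix becomes a Fisher-z FC matrix, low-consensus SC edges are
zeroed across a small panel, and excluded regions are dropped.
"""

import numpy as np

from devconn import (
    apply_region_exclusion,
    consensus_threshold,
    fisher_z_transform,
    normalize_and_symmetrize_sc,
)

# --- SC: streamline counts -> proportions, averaged over both directions ----
counts = np.array(
    [
        [0, 120, 30, 10],
        [100, 0, 20, 40],
        [25, 30, 0, 5],
        [15, 35, 10, 0],
    ],
    dtype=float,
)
labels = ["PFC", "Parietal", "Temporal", "Occipital"]
sc = normalize_and_symmetrize_sc(counts, labels, subject_id="demo", timepoint=1)
print("SC weights (proportions, symmetrized):")
print(np.round(sc.weights, 3))

# --- FC: Pearson correlations -> Fisher z --------------------------------
r = np.array(
    [
        [0.0, 0.61, 0.20, -0.15],
        [0.61, 0.0, 0.33, 0.05],
        [0.20, 0.33, 0.0, 0.44],
        [-0.15, 0.05, 0.44, 0.0],
    ]
)
fc = fisher_z_transform(r, labels, subject_id="demo", timepoint=1)
print("\nFC weights (Fisher z); z(0.61) =", round(fc.weights[0, 1], 4))

# --- consensus thresholding across a panel of SC scans -------------------
rng = np.random.default_rng(0)
panel = []
for k in range(4):
    noisy = counts * rng.uniform(0.5, 1.5, counts.shape)
    if k < 3:
        noisy[2, 3] = noisy[3, 2] = 0.0  # edge absent in 3 of 4 scans
    panel.append(normalize_and_symmetrize_sc(noisy, labels, f"s{k}", 1))
mask, thresholded = consensus_threshold(panel, fraction=0.75)
print("\nConsensus mask (75% rule) keeps", int(mask.sum() / 2), "of 6 edges;")
print("the Temporal-Occipital edge, present in only 1 of 4 scans, is removed:",
      not mask[2, 3])

# --- region exclusion ------------------------------------------------------
trimmed = apply_region_exclusion(sc, ["Occipital"])
print("\nAfter excluding 1 region the matrix is",
      f"{trimmed.n_regions}x{trimmed.n_regions}", "with labels", trimmed.region_labels)
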