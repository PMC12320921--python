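"""Cohort QC statistics and attention-task scoring.

Fingerprint match rate (can scans be re-identified by subject?), the QC-FC
motion benchmark, exclusion-ledger bookkeeping, and the attention scoring /
harmonization rules.
"""

import numpy as np
import pandas as pd

from devconn import (
    SyntheticCohortSpec,
    exclusion_ledger,
    fingerprint_match_rate,
    generate_cohort,
    generate_motion_confound,
    harmonize_behavior,
    panel_pca_variance,
    qcfc_summary,
    score_executive,
    score_selective,
    score_sustained,
)

# --- fingerprinting --------------------------------------------------------
spec = SyntheticCohortSpec(n_subjects=20, n_regions=100, fingerprint_icc=0.8, seed=5)
cohort = generate_cohort(spec)
rate = fingerprint_match_rate(list(cohort.fc.values()))
print(f"Fingerprint match rate at ICC 0.8: {100 * rate:.1f}% "
      f"(chance would be ~{100 / 39:.1f}%)")

# --- QC-FC motion benchmark -----------------------------------------------
motion, edges, bad = generate_motion_confound(spec, contaminated_edges=0.2,
                                              strength=2.0)
qc = qcfc_summary(edges, motion, alpha=0.05)
print(f"QC-FC with 20% contaminated edges: {100 * qc.fraction_significant:.1f}% "
      f"significant edges, median r = {qc.median_correlation:.3f}")

# --- panel PCA variance -----------------------------------------------------
frac = panel_pca_variance(edges, n_components=5)
print("Variance explained by first 5 PCs of the edge panel:",
      np.round(frac, 3))

# --- exclusion ledger -------------------------------------------------------
ledger = exclusion_ledger(203, [("T1 QC", 24), ("dMRI QC", 3), ("fMRI QC", 46),
                                ("incomplete pairs", 52)])
print("\n" + ledger.report())

# --- attention scoring ------------------------------------------------------
v, a, total = score_sustained(visual=(25, 2, 1), auditory=(20, 0, 0))
print(f"\nSustained attention: visual {v}, auditory {a}, total {total}")
print(f"Selective attention (12 of 18 targets): {score_selective(12)}")
print(f"Executive attention (9 failed trials):  {score_executive(9)}")

table = pd.DataFrame(
    {
        "subject_id": [f"s{i}" for i in range(5)],
        "sustained_visual": [22.0, 24.0, 23.0, 25.0, 24.0],
        "sustained_auditory": [20.0, 21.0, 19.0, 22.0, 20.0],
        "sustained": [21.0, 22.5, 21.0, 23.5, 22.0],
        "executive": [-12.0, -8.0, np.nan, -15.0, -10.0],
    }
)
harmonized, log = harmonize_behavior(table)
print("\nHarmonization changes:")
for entry in log.entries:
    print(" -", entry)
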