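"""Regional structure-function coupling.

For each region, coupling is the Spearman rank correlation between that
region's SC connectivity profile and its FC profile over all other regions.
All connections, including zeros, enter the ranking (indirect structural
paths may support functional connections), and only the structurally-zero
self entry is excluded.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .io import ConnectomeMatrix

logger = logging.getLogger(__name__)

__all__ = ["regional_scfc_coupling"]


def regional_scfc_coupling(sc: ConnectomeMatrix, fc: ConnectomeMatrix) -> np.ndarray:
    """Per-region Spearman correlation between SC and FC profiles.

    Returns a length-N vector; regions whose SC or FC profile has zero
    variance get NaN (undefined) and are logged.  Ties receive average ranks.
    """
    if sc.region_labels != fc.region_labels:
        raise ValueError("SC and FC region labels do not match")
    n = sc.n_regions
    out = np.full(n, np.nan)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        a = sc.weights[i][mask[i]]
        b = fc.weights[i][mask[i]]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            logger.warning(
                "SC-FC coupling undefined for region %s (constant profile)",
                sc.region_labels[i],
            )
            continue
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        out[i] = np.corrcoef(ra, rb)[0, 1]
    return out
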