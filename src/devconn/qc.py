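"""Cohort-level quality-control statistics.

Covers connectome fingerprinting (identifiability of subjects from their FC
matrices), the QC-FC motion benchmark (fraction of edges whose values
correlate with head motion), exclusion-ledger arithmetic for sample flow
reporting, and principal-component variance summaries of metric panels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import ConnectomeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionLedger",
    "fingerprint_match_rate",
    "qcfc_summary",
    "QCFCSummary",
    "exclusion_ledger",
    "panel_pca_variance",
]


def fingerprint_match_rate(fc_scans: Sequence[ConnectomeMatrix]) -> float:
    """Fingerprint match rate of a set of FC scans.

    Each scan's vectorised upper triangle is Pearson-correlated with every
    other scan; the scan "matches" if its most-correlated partner belongs to
    the same subject.  The rate is matches divided by the total number of
    scans — scans without a same-subject partner stay in the denominator and
    can never match (they serve as potential false matches).
    """
    if len(fc_scans) < 2:
        raise ValueError("need at least 2 scans")
    keys = [(m.subject_id, m.timepoint) for m in fc_scans]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (subject, timepoint) keys in scan list")
    vecs = np.vstack([m.upper_triangle() for m in fc_scans])
    corr = np.corrcoef(vecs)
    np.fill_diagonal(corr, -np.inf)
    best = np.argmax(corr, axis=1)
    subjects = np.asarray([m.subject_id for m in fc_scans])
    matches = int(np.sum(subjects[best] == subjects))
    return matches / len(fc_scans)


@dataclass
class QCFCSummary:
    """QC-FC benchmark: edgewise motion-correlation summary."""

    fraction_significant: float
    median_correlation: float
    n_edges: int
    n_undefined: int


def qcfc_summary(
    edge_panel: np.ndarray, motion: np.ndarray, alpha: float = 0.05
) -> QCFCSummary:
    """Fraction of edges correlated with head motion at uncorrected ``alpha``.

    ``edge_panel`` is scans x edges; ``motion`` holds one mean framewise
    displacement value per scan.  Pearson correlations are tested two-sided
    and uncorrected.  Zero-variance edges are undefined and excluded from the
    fraction's denominator (reported via ``n_undefined``).
    """
    x = np.asarray(edge_panel, dtype=float)
    mot = np.asarray(motion, dtype=float)
    if x.shape[0] != mot.shape[0]:
        raise ValueError("edge panel and motion vector lengths differ")
    if np.ptp(mot) == 0:
        raise ValueError("motion vector has zero variance")
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    mc = mot - mot.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sm = np.sqrt((mc**2).sum())
    defined = sx > 0
    r = np.full(x.shape[1], np.nan)
    r[defined] = (xc[:, defined] * mc[:, None]).sum(axis=0) / (sx[defined] * sm)
    r = np.clip(r, -1.0, 1.0)
    rd = r[defined]
    with np.errstate(divide="ignore"):
        t = rd * np.sqrt((n - 2) / np.maximum(1 - rd**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    n_def = int(defined.sum())
    frac = float(np.mean(p < alpha)) if n_def else 0.0
    med = float(np.median(rd)) if n_def else float("nan")
    return QCFCSummary(frac, med, x.shape[1], x.shape[1] - n_def)


@dataclass
class ExclusionLedger:
    """Sequential scan-exclusion bookkeeping mirroring a sample-flow diagram."""

    initial: int
    stages: list[tuple[str, int]]
    remaining: int
    total_excluded: int

    def report(self) -> str:
        lines = [f"Initial dataset: {self.initial} scans"]
        current = self.initial
        for label, n in self.stages:
            current -= n
            lines.append(f"  - {label}: {n} excluded ({current} remaining)")
        lines.append(
            f"Total excluded: {self.total_excluded}; final sample: {self.remaining}"
        )
        return "\n".join(lines)


def exclusion_ledger(
    initial: int, stages: Sequence[tuple[str, int]]
) -> ExclusionLedger:
    """Apply per-stage exclusion counts sequentially to an initial scan count."""
    if initial < 0:
        raise ValueError("initial count must be non-negative")
    current = initial
    for label, n in stages:
        if n < 0:
            raise ValueError(f"stage {label!r} has negative count")
        if n > current:
            raise ValueError(
                f"stage {label!r} excludes {n} scans but only {current} remain"
            )
        current -= n
    total = initial - current
    return ExclusionLedger(initial, [(str(l), int(n)) for l, n in stages], current, total)


def panel_pca_variance(panel: np.ndarray, n_components: int = 10) -> np.ndarray:
    """Variance fractions of the leading principal components of a panel.

    The panel (scans x features) is column-centered; fractions are the
    squared singular values over their total, non-increasing.  If fewer than
    ``n_components`` non-null components exist the result is truncated with a
    warning.
    """
    x = np.asarray(panel, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 scans for a PCA")
    xc = x - x.mean(axis=0)
    s = np.linalg.svd(xc, compute_uv=False)
    total = (s**2).sum()
    if total == 0:
        return np.zeros(0)
    frac = s**2 / total
    rank = int(np.sum(s > s[0] * 1e-12))
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    return frac[:n_components]
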