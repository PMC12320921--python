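"""Reading, normalising, and assembling connectivity matrices.

Structural connectivity (SC) matrices hold non-negative streamline
proportions: the streamline count between a pair of regions divided by the
total number of streamlines sent from the seed region, averaged over the two
seeding directions.  Functional connectivity (FC) matrices hold Fisher
z-transformed Pearson correlations of regional BOLD time series; negative
weights are retained.  Both are square, symmetric, zero-diagonal, and
label-indexed by region name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-12

__all__ = [
    "ConnectomeMatrix",
    "CohortPanel",
    "fisher_z_transform",
    "normalize_and_symmetrize_sc",
    "apply_region_exclusion",
    "consensus_threshold",
    "build_cohort_panel",
    "read_matrix",
    "write_matrix",
    "read_region_labels",
    "write_region_labels",
    "read_cohort_panel",
    "write_cohort_panel",
]


def _default_labels(n: int) -> list[str]:
    return [f"ROI{i + 1:03d}" for i in range(n)]


@dataclass
class ConnectomeMatrix:
    """One scan's square symmetric weighted network.

    Parameters
    ----------
    weights
        N x N symmetric matrix of edge weights with a zero diagonal.
    region_labels
        Ordered region names, one per row/column.
    modality
        ``"SC"`` (non-negative streamline proportions) or ``"FC"``
        (Fisher-z correlations; negative weights permitted).
    subject_id, timepoint
        Identify the scan within a paired longitudinal cohort.
    """

    weights: np.ndarray
    region_labels: list[str] = field(default_factory=list)
    modality: str = "FC"
    subject_id: str = ""
    timepoint: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not self.region_labels:
            self.region_labels = _default_labels(w.shape[0])
        if len(self.region_labels) != w.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {w.shape[0]} regions"
            )
        if not np.allclose(w, w.T, atol=SYMMETRY_TOL, rtol=0.0):
            raise ValueError("weights must be symmetric within 1e-12")
        if np.any(np.diagonal(w) != 0.0):
            raise ValueError("diagonal (self-connections) must be exactly zero")
        if self.modality not in ("SC", "FC"):
            raise ValueError(f"modality must be 'SC' or 'FC', got {self.modality!r}")
        if self.modality == "SC" and np.any(w < 0):
            raise ValueError("SC weights must be non-negative")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Vectorised strictly-upper-triangular edge weights."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.weights[iu]


@dataclass
class CohortPanel:
    """Scans x regions matrix of one regional metric, paired by condition.

    Rows are ordered as all condition-1 scans followed by all condition-2
    scans, with the same subject order in both blocks — the canonical layout
    for a two-condition PLS design.
    """

    values: np.ndarray
    subject_ids: list[str]
    condition: np.ndarray
    metric_name: str = "metric"
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        cond = np.asarray(self.condition, dtype=int)
        if v.shape[0] != len(self.subject_ids) or v.shape[0] != cond.shape[0]:
            raise ValueError("values, subject_ids and condition lengths differ")
        conds = np.unique(cond)
        counts = [int(np.sum(cond == c)) for c in conds]
        if len(set(counts)) != 1:
            raise ValueError(f"unequal scans per condition: {dict(zip(conds, counts))}")
        per_cond_subjects = [
            [s for s, c in zip(self.subject_ids, cond) if c == cc] for cc in conds
        ]
        for subj_list in per_cond_subjects:
            if len(set(subj_list)) != len(subj_list):
                raise ValueError("a subject appears more than once in a condition")
        if any(subj_list != per_cond_subjects[0] for subj_list in per_cond_subjects):
            raise ValueError("subject order must match across condition blocks")
        if not np.all(np.diff(cond) >= 0):
            raise ValueError("rows must be grouped: condition 1 block then condition 2")
        if not self.region_labels:
            self.region_labels = _default_labels(v.shape[1])
        self.values = v
        self.condition = cond

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> np.ndarray:
        return np.unique(self.condition)

    @property
    def subjects(self) -> list[str]:
        first = self.condition == self.conditions[0]
        return [s for s, m in zip(self.subject_ids, first) if m]


def fisher_z_transform(
    r_matrix: np.ndarray,
    region_labels: Sequence[str] | None = None,
    subject_id: str = "",
    timepoint: int = 1,
) -> ConnectomeMatrix:
    """Fisher z-transform a correlation matrix into an FC ConnectomeMatrix.

    Applies arctanh elementwise off-diagonal and forces the diagonal to
    zero.  Off-diagonal entries must lie strictly inside (-1, 1).
    """
    r = np.asarray(r_matrix, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-10, rtol=0.0):
        raise ValueError("correlation matrix must be symmetric")
    off = ~np.eye(r.shape[0], dtype=bool)
    bad = np.abs(r) >= 1.0
    bad &= off
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"|r| >= 1 at entry ({i}, {j}): r = {r[i, j]} is outside arctanh domain"
        )
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    z = (z + z.T) / 2.0  # removes float asymmetry only
    np.fill_diagonal(z, 0.0)
    return ConnectomeMatrix(
        z, list(region_labels) if region_labels else [], "FC", subject_id, timepoint
    )


def normalize_and_symmetrize_sc(
    counts: np.ndarray,
    region_labels: Sequence[str] | None = None,
    subject_id: str = "",
    timepoint: int = 1,
) -> ConnectomeMatrix:
    """Turn a streamline-count matrix into a symmetric proportion matrix.

    Each row is divided by its own row sum (streamlines sent from the seed
    region), then the two directions are averaged and the diagonal zeroed.
    All-zero rows (tractography dropouts) are kept as zero rows and logged.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("counts must be square")
    if np.any(c < 0):
        i, j = np.argwhere(c < 0)[0]
        raise ValueError(f"negative streamline count at ({i}, {j})")
    row_sums = c.sum(axis=1)
    if np.all(row_sums == 0):
        raise ValueError("at least one row must have a positive streamline sum")
    zero_rows = np.flatnonzero(row_sums == 0)
    if zero_rows.size:
        logger.warning(
            "SC normalization: %d region(s) sent no streamlines and remain "
            "disconnected: %s",
            zero_rows.size,
            zero_rows.tolist(),
        )
    w = np.zeros_like(c)
    pos = row_sums > 0
    w[pos] = c[pos] / row_sums[pos, None]
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectomeMatrix(
        w, list(region_labels) if region_labels else [], "SC", subject_id, timepoint
    )


def apply_region_exclusion(
    m: ConnectomeMatrix, excluded: Iterable[str]
) -> ConnectomeMatrix:
    """Remove the rows/columns of the named regions, preserving label order."""
    excluded = list(excluded)
    unknown = [r for r in excluded if r not in m.region_labels]
    if unknown:
        raise KeyError(f"unknown region name(s): {unknown}")
    keep = [i for i, lab in enumerate(m.region_labels) if lab not in set(excluded)]
    idx = np.asarray(keep, dtype=int)
    return ConnectomeMatrix(
        m.weights[np.ix_(idx, idx)],
        [m.region_labels[i] for i in keep],
        m.modality,
        m.subject_id,
        m.timepoint,
    )


def consensus_threshold(
    panel: Sequence[ConnectomeMatrix], fraction: float = 0.75
) -> tuple[np.ndarray, list[ConnectomeMatrix]]:
    """Group-consensus edge mask: keep edges present in >= ``fraction`` of scans.

    "Present" means a strictly positive weight.  Returns the boolean retention
    mask and a new panel with non-consensus edges zeroed.  Per-scan counts of
    zeroed positive edges are logged to support exclusion summaries.
    """
    if not panel:
        raise ValueError("empty panel")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    shape = panel[0].weights.shape
    labels = panel[0].region_labels
    for m in panel:
        if m.weights.shape != shape:
            raise ValueError(
                f"mixed matrix shapes: {m.weights.shape} vs {shape}"
            )
        if m.region_labels != labels:
            raise ValueError("mixed region labels across panel")
    presence = np.mean([m.weights > 0 for m in panel], axis=0)
    mask = presence >= fraction
    mask &= mask.T
    np.fill_diagonal(mask, False)
    out = []
    for m in panel:
        w = np.where(mask, m.weights, 0.0)
        n_zeroed = int(np.sum((m.weights > 0) & ~mask))
        logger.info(
            "consensus threshold (%.0f%%): scan %s/t%d: %d connections set to zero",
            100 * fraction,
            m.subject_id,
            m.timepoint,
            n_zeroed,
        )
        out.append(
            ConnectomeMatrix(w, m.region_labels, m.modality, m.subject_id, m.timepoint)
        )
    return mask, out


def consensus_zeroed_counts(
    panel: Sequence[ConnectomeMatrix], mask: np.ndarray
) -> list[int]:
    """Number of positive connections removed per scan by a consensus mask."""
    return [int(np.sum((m.weights > 0) & ~mask)) for m in panel]


def build_cohort_panel(
    per_scan_vectors: Mapping[tuple[str, int], np.ndarray],
    metric_name: str = "metric",
    region_labels: Sequence[str] | None = None,
) -> CohortPanel:
    """Stack per-scan regional vectors into the canonical PLS layout.

    ``per_scan_vectors`` maps ``(subject_id, timepoint)`` to a length-N metric
    vector (scalar metrics such as modularity Q become N = 1 panels).  Every
    subject must have every timepoint; rows are ordered condition-major with a
    stable subject order shared by the condition blocks.
    """
    keys = list(per_scan_vectors)
    conditions = sorted({tp for _, tp in keys})
    subjects_in_order: list[str] = []
    for s, _ in keys:
        if s not in subjects_in_order:
            subjects_in_order.append(s)
    missing = [
        (s, tp)
        for s in subjects_in_order
        for tp in conditions
        if (s, tp) not in per_scan_vectors
    ]
    if missing:
        raise ValueError(f"unpaired subjects; missing scans: {missing}")
    rows, subj_col, cond_col = [], [], []
    for tp in conditions:
        for s in subjects_in_order:
            rows.append(np.atleast_1d(np.asarray(per_scan_vectors[(s, tp)], float)))
            subj_col.append(s)
            cond_col.append(tp)
    return CohortPanel(
        np.vstack(rows),
        subj_col,
        np.asarray(cond_col),
        metric_name,
        list(region_labels) if region_labels else [],
    )


# ---------------------------------------------------------------------------
# File formats: delimited square matrices, label lists, panel CSVs.
# ---------------------------------------------------------------------------


def read_matrix(
    path: str | Path,
    modality: str = "FC",
    subject_id: str = "",
    timepoint: int = 1,
    region_labels: Sequence[str] | None = None,
) -> ConnectomeMatrix:
    """Read a whitespace- or comma-delimited square matrix file.

    An optional first header row may carry region labels; an explicit
    ``region_labels`` argument overrides any header.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "," if "," in first else r"\s+"
    tokens = first.replace(",", " ").split()

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_is_number(t) for t in tokens)
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    labels = list(region_labels) if region_labels else (
        [str(c) for c in df.columns] if has_header else []
    )
    return ConnectomeMatrix(
        df.to_numpy(dtype=float), labels, modality, subject_id, timepoint
    )


def write_matrix(m: ConnectomeMatrix, path: str | Path, header: bool = True) -> None:
    df = pd.DataFrame(m.weights, columns=m.region_labels)
    df.to_csv(path, index=False, header=header)


def read_region_labels(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_region_labels(labels: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(labels) + "\n")


def write_cohort_panel(panel: CohortPanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.values, columns=panel.region_labels)
    df.insert(0, "timepoint", panel.condition)
    df.insert(0, "subject_id", panel.subject_ids)
    df.to_csv(path, index=False)


def read_cohort_panel(path: str | Path, metric_name: str = "metric") -> CohortPanel:
    df = pd.read_csv(path)
    labels = [c for c in df.columns if c not in ("subject_id", "timepoint")]
    return CohortPanel(
        df[labels].to_numpy(dtype=float),
        df["subject_id"].astype(str).tolist(),
        df["timepoint"].to_numpy(dtype=int),
        metric_name,
        labels,
    )
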