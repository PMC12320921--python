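"""Attention-task scoring and behavior-table harmonization.

Three early-childhood attention measures are scored:

* sustained attention — visual and auditory continuous-performance tasks, each
  scored as correct responses minus errors minus prompts (30 targets per
  modality); the total is the mean of the two modality scores;
* selective attention — a timed visual search with 18 targets, scored as the
  number of correctly identified targets;
* executive attention — a card-sorting adaptation, scored as the number of
  incorrect or incomplete trials multiplied by -1 so that higher is better
  (at most 60 trials: 3 stages x 20 trials).

Harmonization applies the analysis rules for deviant and missing scores: a
modality sustained score more than 3 sample SDs from that modality's mean is
dropped and the total recomputed from the other modality alone; missing
executive scores are imputed with the observed sample mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SUSTAINED_MAX_TARGETS",
    "SELECTIVE_MAX_TARGETS",
    "EXECUTIVE_MAX_TRIALS",
    "score_sustained",
    "score_selective",
    "score_executive",
    "harmonize_behavior",
]

SUSTAINED_MAX_TARGETS = 30
SELECTIVE_MAX_TARGETS = 18
EXECUTIVE_MAX_TRIALS = 60


def _score_modality(correct: float, errors: float, prompts: float, name: str) -> float:
    if min(correct, errors, prompts) < 0:
        raise ValueError(f"{name} counts must be non-negative")
    if correct > SUSTAINED_MAX_TARGETS:
        raise ValueError(
            f"{name}: correct = {correct} exceeds the {SUSTAINED_MAX_TARGETS} targets"
        )
    return float(correct - errors - prompts)


def score_sustained(
    visual: tuple[float, float, float], auditory: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Score the sustained attention tasks.

    Each modality score is correct - errors - prompts; the total sustained
    attention score is the mean of the visual and auditory scores.
    """
    v = _score_modality(*visual, name="visual")
    a = _score_modality(*auditory, name="auditory")
    return v, a, (v + a) / 2.0


def score_selective(found: float) -> float:
    """Selective attention score: the count of correctly identified targets."""
    if not 0 <= found <= SELECTIVE_MAX_TARGETS:
        raise ValueError(
            f"found = {found} outside [0, {SELECTIVE_MAX_TARGETS}] "
            f"({SELECTIVE_MAX_TARGETS} targets on the search sheet)"
        )
    return float(found)


def score_executive(incorrect_or_incomplete: float) -> float:
    """Executive attention score: -1 x incorrect-or-incomplete trial count."""
    if not 0 <= incorrect_or_incomplete <= EXECUTIVE_MAX_TRIALS:
        raise ValueError(
            f"count = {incorrect_or_incomplete} outside [0, {EXECUTIVE_MAX_TRIALS}]"
        )
    return -float(incorrect_or_incomplete)


@dataclass
class HarmonizationLog:
    """Record of every substitution made during harmonization."""

    entries: list[str]

    def __bool__(self) -> bool:
        return bool(self.entries)


def harmonize_behavior(
    table: pd.DataFrame, sd_threshold: float = 3.0
) -> tuple[pd.DataFrame, HarmonizationLog]:
    """Apply outlier and imputation rules to a behavior table.

    Expects columns ``sustained_visual``, ``sustained_auditory``,
    ``sustained`` (total) and ``executive``.  A modality sustained score more
    than ``sd_threshold`` sample SDs (ddof=1) from the modality mean has the
    subject's total recomputed from the other modality alone.  Missing
    executive scores are imputed with the mean of the observed values.
    Returns the harmonized copy and a change log.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to estimate sample SDs")
    out = table.copy()
    log: list[str] = []
    other = {"sustained_visual": "sustained_auditory",
             "sustained_auditory": "sustained_visual"}
    for col, alt in other.items():
        if col not in out.columns:
            continue
        mu = out[col].mean()
        sd = out[col].std(ddof=1)
        if not math.isfinite(sd) or sd == 0:
            continue
        deviant = (out[col] - mu).abs() > sd_threshold * sd
        for idx in out.index[deviant]:
            out.loc[idx, "sustained"] = out.loc[idx, alt]
            log.append(
                f"row {idx}: {col} = {table.loc[idx, col]} is > {sd_threshold} SD "
                f"from mean {mu:.3f}; total recomputed from {alt} alone"
            )
    if "executive" in out.columns:
        missing = out["executive"].isna()
        if missing.all():
            raise ValueError("executive column has no observed values to impute from")
        if missing.any():
            mean_exec = out.loc[~missing, "executive"].mean()
            for idx in out.index[missing]:
                out.loc[idx, "executive"] = mean_exec
                log.append(
                    f"row {idx}: missing executive score imputed with sample "
                    f"mean {mean_exec:.3f}"
                )
    return out, HarmonizationLog(log)


def align_behavior(
    table: pd.DataFrame,
    subject_ids: list[str],
    timepoints: np.ndarray,
    columns: list[str],
) -> np.ndarray:
    """Extract a scans x behaviors matrix aligned to panel row order."""
    indexed = table.set_index(
        [table["subject_id"].astype(str), table["timepoint"].astype(int)]
    )
    rows = []
    for s, tp in zip(subject_ids, timepoints):
        try:
            rows.append(indexed.loc[(str(s), int(tp)), columns].to_numpy(dtype=float))
        except KeyError:
            raise KeyError(f"behavior table has no row for subject {s}, timepoint {tp}")
    return np.vstack(rows)
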