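"""Partial least squares (PLS) correlation for paired two-condition cohorts.

Two analysis modes operate on a scans x regions panel X (condition-major row
order, subjects paired across conditions):

* mean-centered task PLS — the decomposed matrix R holds each condition's
  column means after subtracting the unweighted grand mean of condition
  means, capturing condition (timepoint) differences;
* behavioral PLS — R stacks, condition by condition, the Pearson correlations
  of each behavior column with each region column, capturing brain-behavior
  covariance shared or differing across conditions.

R (regions x columns) is decomposed as R = U S Vᵀ: U holds brain saliences,
V design/behavior saliences, and the singular values the covariance captured
per latent variable (LV).  Inference follows the standard resampling recipe:
permutation tests on the singular values, bootstrap ratios (BSR = salience /
bootstrap SE, with Procrustes alignment of resampled saliences), and two
reproducibility assessments based on split-half resampling with subjects'
timepoints held together — projected test singular values ("test-train") and
cross-half cosine similarity of the brain saliences ("split-half") — each
z-scored and compared to permutation-null z-scores (difference > 2 means
reproducible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .behavior import align_behavior
from .io import CohortPanel

logger = logging.getLogger(__name__)

__all__ = [
    "PLSResult",
    "ReproducibilityReport",
    "BootstrapResult",
    "mean_centered_pls",
    "behavioral_pls",
    "permutation_pvalues",
    "bootstrap_saliences",
    "test_train_reproducibility",
    "split_half_vector_reproducibility",
    "salience_cosine_specificity",
    "cosine_similarity",
]

BSR_THRESHOLD = 2.0
REPRODUCIBILITY_MARGIN = 2.0


# ---------------------------------------------------------------------------
# Decompositions
# ---------------------------------------------------------------------------


def _as_behavior_matrix(panel: CohortPanel, behaviors, behavior_columns) -> np.ndarray:
    if behaviors is None:
        raise ValueError("behavioral mode requires a behavior table")
    if isinstance(behaviors, pd.DataFrame):
        if not behavior_columns:
            raise ValueError("behavior_columns required with a behavior table")
        return align_behavior(
            behaviors, panel.subject_ids, panel.condition, list(behavior_columns)
        )
    y = np.atleast_2d(np.asarray(behaviors, dtype=float))
    if y.shape[0] != panel.n_scans:
        y = y.T
    if y.shape[0] != panel.n_scans:
        raise ValueError("behavior matrix not aligned to panel rows")
    return y


def _mean_centered_matrix(values: np.ndarray, cond: np.ndarray) -> np.ndarray:
    conds = np.unique(cond)
    means = np.vstack([values[cond == c].mean(axis=0) for c in conds])
    dev = means - means.mean(axis=0)
    return dev.T  # regions x conditions


def _behavioral_matrix(
    values: np.ndarray,
    y: np.ndarray,
    cond: np.ndarray,
    column_names: list[str] | None = None,
) -> np.ndarray:
    conds = np.unique(cond)
    rows = []
    for c in conds:
        sel = cond == c
        xc = values[sel] - values[sel].mean(axis=0)
        yc = y[sel] - y[sel].mean(axis=0)
        sy = np.sqrt((yc**2).sum(axis=0))
        sx = np.sqrt((xc**2).sum(axis=0))
        if np.any(sy == 0):
            b = int(np.flatnonzero(sy == 0)[0])
            name = column_names[b] if column_names else f"column {b}"
            raise ValueError(
                f"behavior {name} has zero variance within condition {c}"
            )
        degenerate = sx == 0
        if degenerate.any():
            logger.warning(
                "%d region column(s) constant within condition %s; "
                "their correlations set to 0",
                int(degenerate.sum()),
                c,
            )
            sx = np.where(degenerate, 1.0, sx)
        r = (yc.T @ xc) / np.outer(sy, sx)
        r[:, degenerate] = 0.0
        rows.append(r)
    return np.vstack(rows).T  # regions x (conditions * behaviors)


def _svd(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    v = vt.T
    # sign convention: largest-|u| element of each LV made positive
    for l in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, l])))
        if u[i, l] < 0:
            u[:, l] = -u[:, l]
            v[:, l] = -v[:, l]
    return u, s, v


def _decompose(
    values: np.ndarray,
    cond: np.ndarray,
    y: np.ndarray | None,
    column_names: list[str] | None = None,
):
    if y is None:
        r = _mean_centered_matrix(values, cond)
    else:
        r = _behavioral_matrix(values, y, cond, column_names)
    u, s, v = _svd(r)
    return r, u, s, v


@dataclass
class PLSResult:
    """Result of one PLS decomposition plus any attached resampling output."""

    mode: str
    decomposed_matrix: np.ndarray
    U: np.ndarray
    V: np.ndarray
    s: np.ndarray
    brain_scores: np.ndarray
    column_labels: list[str] = field(default_factory=list)
    perm_p: np.ndarray | None = None
    bsr: np.ndarray | None = None
    behavior_correlations: pd.DataFrame | None = None

    @property
    def n_lv(self) -> int:
        return self.s.shape[0]

    def covariance_explained(self) -> np.ndarray:
        total = (self.s**2).sum()
        return self.s**2 / total if total > 0 else np.zeros_like(self.s)


def mean_centered_pls(panel: CohortPanel) -> PLSResult:
    """Two-condition mean-centered task PLS.

    The decomposed matrix holds per-condition column means minus the
    unweighted grand mean of condition means; for a 2-condition design
    exactly one LV carries signal and its design salience is proportional to
    (1, -1)/sqrt(2).  Brain scores are the panel rows projected onto U.
    """
    conds = panel.conditions
    if len(conds) < 2:
        raise ValueError("mean-centered PLS needs at least 2 conditions")
    r, u, s, v = _decompose(panel.values, panel.condition, None)
    return PLSResult(
        mode="mean_centered",
        decomposed_matrix=r,
        U=u,
        V=v,
        s=s,
        brain_scores=panel.values @ u,
        column_labels=[f"condition{c}" for c in conds],
    )


def _behavior_score_correlations(
    values: np.ndarray,
    y: np.ndarray,
    cond: np.ndarray,
    u: np.ndarray,
    behavior_names: list[str],
) -> pd.DataFrame:
    scores = values @ u
    recs = []
    for c in np.unique(cond):
        sel = cond == c
        for b, name in enumerate(behavior_names):
            for l in range(u.shape[1]):
                r = np.corrcoef(scores[sel, l], y[sel, b])[0, 1]
                recs.append(
                    {"condition": int(c), "behavior": name, "lv": l + 1, "r": r}
                )
    return pd.DataFrame(recs)


def behavioral_pls(
    panel: CohortPanel,
    behaviors,
    behavior_columns: list[str] | None = None,
) -> PLSResult:
    """Behavioral PLS on within-condition brain-behavior correlations.

    ``behaviors`` is either a behavior table (DataFrame with ``subject_id``
    and ``timepoint`` columns, read with ``behavior_columns``) or an aligned
    scans x behaviors array.  Per-condition correlations of each LV's brain
    scores with each behavior are attached for reporting whether the
    brain-behavior relationship is similar across conditions.
    """
    y = _as_behavior_matrix(panel, behaviors, behavior_columns)
    names = list(behavior_columns) if behavior_columns else [
        f"behavior{i + 1}" for i in range(y.shape[1])
    ]
    r, u, s, v = _decompose(panel.values, panel.condition, y, names)
    labels = [
        f"condition{c}:{name}" for c in panel.conditions for name in names
    ]
    res = PLSResult(
        mode="behavioral",
        decomposed_matrix=r,
        U=u,
        V=v,
        s=s,
        brain_scores=panel.values @ u,
        column_labels=labels,
    )
    res.behavior_correlations = _behavior_score_correlations(
        panel.values, y, panel.condition, u, names
    )
    return res


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------


def permutation_pvalues(
    result: PLSResult,
    panel: CohortPanel,
    behaviors=None,
    behavior_columns: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Per-LV permutation p-values for the singular values.

    Each permutation shuffles the panel's scan rows across the whole stack
    (breaking condition assignment in mean-centered mode and the X-Y row
    correspondence in behavioral mode), recomputes the decomposition, and
    p_l is the proportion of permuted singular values >= the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = (
        _as_behavior_matrix(panel, behaviors, behavior_columns)
        if result.mode == "behavioral"
        else None
    )
    rng = np.random.default_rng(seed)
    counts = np.zeros_like(result.s)
    for _ in range(n_perm):
        order = rng.permutation(panel.n_scans)
        xp = panel.values[order]
        if y is None:
            rp = _mean_centered_matrix(xp, panel.condition)
        else:
            rp = _behavioral_matrix(xp, y, panel.condition)
        sp = np.linalg.svd(rp, compute_uv=False)
        counts += sp >= result.s
    p = counts / n_perm
    result.perm_p = p
    return p


# ---------------------------------------------------------------------------
# Bootstrap reliability
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Bootstrap ratios and brain-score-behavior correlation intervals."""

    bsr: np.ndarray
    salience_se: np.ndarray
    behavior_correlation_intervals: pd.DataFrame | None = None


def _subject_row_indices(panel: CohortPanel, subject_idx: np.ndarray) -> np.ndarray:
    """Panel row indices for the given subject indices, both conditions."""
    n_subj = len(panel.subjects)
    blocks = []
    for b in range(len(panel.conditions)):
        blocks.append(b * n_subj + subject_idx)
    return np.concatenate(blocks)


def bootstrap_saliences(
    result: PLSResult,
    panel: CohortPanel,
    behaviors=None,
    behavior_columns: list[str] | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap ratios (BSRs) of the brain saliences.

    Subjects are resampled with replacement with their timepoints held
    together.  Each resample's singular-value-scaled saliences U_b S_b are
    aligned to the original U S by orthogonal Procrustes rotation (weighting
    by the singular values stops noise-level trailing LVs from contaminating
    the alignment); BSR = original scaled salience / bootstrap SD of the
    aligned scaled saliences, the toolbox-standard reliability score.
    Regions with zero bootstrap SE get NaN with a warning.  For behavioral
    mode, 2.5/97.5 percentile intervals of the per-condition
    brain-score-behavior correlations are attached (intervals crossing zero
    flag unstable LVs).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    y = (
        _as_behavior_matrix(panel, behaviors, behavior_columns)
        if result.mode == "behavioral"
        else None
    )
    names = (
        list(behavior_columns)
        if behavior_columns
        else ([f"behavior{i + 1}" for i in range(y.shape[1])] if y is not None else [])
    )
    rng = np.random.default_rng(seed)
    n_subj = len(panel.subjects)
    scaled_orig = result.U * result.s
    u_samples = np.empty((n_boot,) + result.U.shape)
    corr_samples: list[pd.DataFrame] = []
    for b in range(n_boot):
        subj_idx = rng.integers(0, n_subj, size=n_subj)
        rows = _subject_row_indices(panel, subj_idx)
        xb = panel.values[rows]
        yb = y[rows] if y is not None else None
        try:
            _, ub, sb, vb = _decompose(xb, panel.condition, yb)
        except ValueError:
            # degenerate resample (e.g., zero behavior variance); reuse original
            u_samples[b] = scaled_orig
            continue
        rot, _ = orthogonal_procrustes(ub * sb, scaled_orig)
        u_samples[b] = (ub * sb) @ rot
        if y is not None:
            corr_samples.append(
                _behavior_score_correlations(
                    xb, yb, panel.condition, ub @ rot, names
                )
            )
    sd = u_samples.std(axis=0, ddof=1)
    bsr = np.full_like(result.U, np.nan)
    ok = sd > 0
    bsr[ok] = scaled_orig[ok] / sd[ok]
    if not ok.all():
        logger.warning(
            "%d salience entries have zero bootstrap SE; BSR reported as missing",
            int((~ok).sum()),
        )
    intervals = None
    if corr_samples:
        stacked = pd.concat(corr_samples)
        intervals = (
            stacked.groupby(["condition", "behavior", "lv"])["r"]
            .quantile([0.025, 0.975])
            .unstack()
            .rename(columns={0.025: "ci_low", 0.975: "ci_high"})
            .reset_index()
        )
        intervals["crosses_zero"] = (intervals["ci_low"] < 0) & (
            intervals["ci_high"] > 0
        )
    result.bsr = bsr
    return BootstrapResult(bsr, sd, intervals)


# ---------------------------------------------------------------------------
# Reproducibility: test-train singular values and split-half singular vectors
# ---------------------------------------------------------------------------


@dataclass
class ReproducibilityReport:
    """Z-scored reproducibility assessments against permutation nulls.

    An LV is reproducible under an assessment when its z exceeds the
    corresponding null z by more than 2.
    """

    z_test_train: np.ndarray | None = None
    z_null_test_train: np.ndarray | None = None
    z_split_half: np.ndarray | None = None
    z_null_split_half: np.ndarray | None = None

    def reproducible(self, assessment: str = "test_train") -> np.ndarray:
        if assessment == "test_train":
            z, zn = self.z_test_train, self.z_null_test_train
        elif assessment == "split_half":
            z, zn = self.z_split_half, self.z_null_split_half
        else:
            raise ValueError("assessment must be 'test_train' or 'split_half'")
        if z is None or zn is None:
            raise ValueError(f"{assessment} assessment has not been computed")
        return (z - zn) > REPRODUCIBILITY_MARGIN


def _split_subjects(
    n_subj: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint halves; for odd counts the first (train) half is larger."""
    perm = rng.permutation(n_subj)
    cut = (n_subj + 1) // 2
    return perm[:cut], perm[cut:]


def _zscore(samples: np.ndarray) -> np.ndarray:
    mu = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mu / sd, 0.0)
    return z


def _test_train_z(
    values: np.ndarray,
    cond: np.ndarray,
    y: np.ndarray | None,
    panel: CohortPanel,
    n_splits: int,
    n_lv: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n_subj = len(panel.subjects)
    vals = np.empty((n_splits, n_lv))
    for k in range(n_splits):
        train, test = _split_subjects(n_subj, rng)
        rows_tr = _subject_row_indices(panel, train)
        rows_te = _subject_row_indices(panel, test)
        _, u_tr, _, v_tr = _decompose(
            values[rows_tr], cond[rows_tr], y[rows_tr] if y is not None else None
        )
        if y is not None:
            r_te = _behavioral_matrix(values[rows_te], y[rows_te], cond[rows_te])
        else:
            r_te = _mean_centered_matrix(values[rows_te], cond[rows_te])
        for l in range(n_lv):
            vals[k, l] = u_tr[:, l] @ r_te @ v_tr[:, l]
    return _zscore(vals)


def _greedy_match_abs_cosine(ua: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """Per-LV |cosine| between two salience sets, matched greedily by max |cos|."""
    na = np.linalg.norm(ua, axis=0)
    nb = np.linalg.norm(ub, axis=0)
    sim = np.abs(ua.T @ ub) / np.outer(
        np.where(na > 0, na, 1.0), np.where(nb > 0, nb, 1.0)
    )
    out = np.zeros(ua.shape[1])
    sim = sim.copy()
    for _ in range(min(sim.shape)):
        a, b = np.unravel_index(np.argmax(sim), sim.shape)
        out[a] = sim[a, b]
        sim[a, :] = -1.0
        sim[:, b] = -1.0
    return out


def _split_half_z(
    values: np.ndarray,
    cond: np.ndarray,
    y: np.ndarray | None,
    panel: CohortPanel,
    n_splits: int,
    n_lv: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n_subj = len(panel.subjects)
    vals = np.empty((n_splits, n_lv))
    for k in range(n_splits):
        half_a, half_b = _split_subjects(n_subj, rng)
        rows_a = _subject_row_indices(panel, half_a)
        rows_b = _subject_row_indices(panel, half_b)
        _, ua, _, _ = _decompose(
            values[rows_a], cond[rows_a], y[rows_a] if y is not None else None
        )
        _, ub, _, _ = _decompose(
            values[rows_b], cond[rows_b], y[rows_b] if y is not None else None
        )
        vals[k] = _greedy_match_abs_cosine(ua[:, :n_lv], ub[:, :n_lv])
    return _zscore(vals)


def _reproducibility(
    panel: CohortPanel,
    behaviors,
    behavior_columns,
    n_splits: int,
    n_perm: int,
    seed: int,
    stat_fn,
) -> tuple[np.ndarray, np.ndarray]:
    y = (
        _as_behavior_matrix(panel, behaviors, behavior_columns)
        if behaviors is not None
        else None
    )
    if len(panel.subjects) < 4:
        raise ValueError("need at least 4 subjects for split-half resampling")
    _, _, s, _ = _decompose(panel.values, panel.condition, y)
    n_lv = s.shape[0]
    rng = np.random.default_rng(seed)
    z = stat_fn(panel.values, panel.condition, y, panel, n_splits, n_lv, rng)
    z_null_samples = np.empty((n_perm, n_lv))
    for p in range(n_perm):
        order = rng.permutation(panel.n_scans)
        z_null_samples[p] = stat_fn(
            panel.values[order], panel.condition, y, panel, n_splits, n_lv, rng
        )
    return z, z_null_samples.mean(axis=0)


def test_train_reproducibility(
    panel: CohortPanel,
    behaviors=None,
    behavior_columns: list[str] | None = None,
    n_splits: int = 500,
    n_perm: int = 100,
    seed: int = 0,
    report: ReproducibilityReport | None = None,
) -> ReproducibilityReport:
    """Singular-value ("test-train") reproducibility z-scores.

    Subjects are repeatedly split into halves (timepoints held together);
    the training half's singular vectors project the test half's decomposed
    matrix onto per-LV test singular values, whose mean/SD over ``n_splits``
    resamples gives z.  The null z repeats this on row-permuted panels (one
    split schedule per permutation) and averages the per-permutation z.
    """
    z, z_null = _reproducibility(
        panel, behaviors, behavior_columns, n_splits, n_perm, seed, _test_train_z
    )
    report = report or ReproducibilityReport()
    report.z_test_train = z
    report.z_null_test_train = z_null
    return report


def split_half_vector_reproducibility(
    panel: CohortPanel,
    behaviors=None,
    behavior_columns: list[str] | None = None,
    n_splits: int = 500,
    n_perm: int = 100,
    seed: int = 0,
    report: ReproducibilityReport | None = None,
) -> ReproducibilityReport:
    """Singular-vector ("split-half") reproducibility z-scores.

    Each half of every split is decomposed independently; LVs are matched
    across halves by greedy maximal |cosine| of the brain saliences and the
    per-LV |cosine| distribution is z-scored, with the permutation null built
    as in the test-train assessment.
    """
    z, z_null = _reproducibility(
        panel, behaviors, behavior_columns, n_splits, n_perm, seed, _split_half_z
    )
    report = report or ReproducibilityReport()
    report.z_split_half = z
    report.z_null_split_half = z_null
    return report


# ---------------------------------------------------------------------------
# Cosine specificity between analyses
# ---------------------------------------------------------------------------


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def salience_cosine_specificity(
    u_a: np.ndarray,
    panel_b: CohortPanel,
    behaviors_b=None,
    behavior_columns: list[str] | None = None,
    lv: int = 0,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Cosine similarity of a salience to another analysis's salience, with p.

    Analysis B is recomputed on row-permuted panels; the null collects
    |cosine| of its LV ``lv`` brain salience to ``u_a``, and
    p = #(null >= |observed|) / n_perm.
    """
    y = (
        _as_behavior_matrix(panel_b, behaviors_b, behavior_columns)
        if behaviors_b is not None
        else None
    )
    _, u_b, _, _ = _decompose(panel_b.values, panel_b.condition, y)
    observed = cosine_similarity(u_a, u_b[:, lv])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        order = rng.permutation(panel_b.n_scans)
        _, u_p, _, _ = _decompose(panel_b.values[order], panel_b.condition, y)
        if abs(cosine_similarity(u_a, u_p[:, lv])) >= abs(observed):
            count += 1
    return observed, count / n_perm
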