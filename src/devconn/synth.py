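"""Synthetic paired two-timepoint SC/FC cohorts with planted structure.

The generator emulates the statistical features the analysis stages assume in
a paediatric longitudinal connectome study, without any imaging:

* SC — modular block-structured non-negative matrices built from zero-clipped
  normal "streamline counts" (stronger within-module blocks), row-normalised
  to streamline proportions and symmetrised; an age-dependent increase of the
  between-module weights lowers modularity with age;
* FC — an affine (hence monotone) map of the scan's SC plus a subject-specific
  fingerprint component, scan noise, an additive timepoint-2 regional change
  (the planted longitudinal effect), and a per-scan latent factor g loaded on
  a unit-norm region salience u* (the planted brain-behavior pattern);
  negative weights occur by construction;
* behavior — attention scores built from an age trend (slopes in score units
  per year), the latent factor g scaled by the effect size beta (in units of
  the measure's noise SD), and measure noise; ages are uniform on the cohort's
  baseline range with a one-year follow-up offset.

All generators are pure functions of (spec, subject, timepoint): every random
stream is derived from the spec seed, the subject index, the timepoint, and a
fixed stream tag, so repeated calls are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CohortPanel, ConnectomeMatrix, build_cohort_panel, normalize_and_symmetrize_sc
from .metrics import local_clustering_positive, local_clustering_signed, weighted_degree

__all__ = [
    "SyntheticCohortSpec",
    "CohortData",
    "GroundTruth",
    "generate_modular_sc",
    "generate_fc_from_sc",
    "generate_cohort",
    "generate_motion_confound",
    "cohort_metric_panel",
    "default_salience",
]

# stream tags keep the per-purpose random streams disjoint
_TAG_SC, _TAG_FC_SCAN, _TAG_FC_SUBJ, _TAG_LATENT, _TAG_AGE, _TAG_BEHAV, _TAG_MOTION = (
    range(7)
)

AGE_BASELINE_RANGE = (4.14, 6.88)
AGE_REFERENCE = 4.0  # years; age effects are relative to this anchor

# age slopes of the attention measures, in score units per year
ATTENTION_TRENDS = {
    "sustained": (24.0, 2.30, 2.5),  # (intercept at mean age, slope, noise SD)
    "selective": (14.0, 1.78, 2.0),
    "executive": (-31.0, 4.03, 6.0),
}
MEAN_BASELINE_AGE = 5.76


def default_salience(n_regions: int) -> np.ndarray:
    """Default planted brain salience: zero-sum +/- loadings on 20% of regions."""
    k = max(1, n_regions // 10)
    u = np.zeros(n_regions)
    u[:k] = 1.0
    u[k : 2 * k] = -1.0
    return u / np.linalg.norm(u)


@dataclass
class SyntheticCohortSpec:
    """All parameters of the planted-structure cohort generator."""

    n_subjects: int = 39
    n_regions: int = 193
    n_modules: int = 4
    sc_within_mean: float = 4.0
    sc_between_mean: float = 1.0
    sc_weight_cv: float = 0.2  # SD of block weights as a fraction of the mean
    fc_coupling_strength: float = 1.0
    fc_offset: float = 1.0  # shift making weak (between-module) edges negative
    fc_noise_sd: float = 0.35
    fingerprint_icc: float = 0.4
    salience: np.ndarray | None = None  # u*, unit norm; default_salience if None
    salience_loading: float = 0.4  # FC amplitude per unit latent g
    beta: float = 1.5  # behavior effect size, in noise SDs per unit g
    longitudinal_delta: np.ndarray | None = None  # per-region FC change at t2
    modularity_age_slope: float = 0.05  # relative between-module gain per year
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules > self.n_regions:
            raise ValueError("n_modules cannot exceed n_regions")
        if min(self.sc_within_mean, self.sc_between_mean) < 0:
            raise ValueError("SC weight intensities must be non-negative")
        if not 0.0 <= self.fingerprint_icc < 1.0:
            raise ValueError("fingerprint_icc must lie in [0, 1)")
        if self.salience is None:
            self.salience = default_salience(self.n_regions)
        else:
            self.salience = np.asarray(self.salience, dtype=float)
            norm = np.linalg.norm(self.salience)
            if not np.isclose(norm, 1.0, atol=1e-8):
                raise ValueError("planted salience u* must have unit norm")
        if self.longitudinal_delta is not None:
            self.longitudinal_delta = np.asarray(self.longitudinal_delta, dtype=float)
            if self.longitudinal_delta.shape != (self.n_regions,):
                raise ValueError("longitudinal_delta must be a per-region vector")

    def with_defaults_planted(self) -> "SyntheticCohortSpec":
        """Copy with the default longitudinal change planted (last 10% of regions)."""
        delta = np.zeros(self.n_regions)
        k = max(1, self.n_regions // 10)
        delta[-k:] = -0.08
        return replace(self, longitudinal_delta=delta)

    def module_membership(self) -> np.ndarray:
        """Contiguous planted module assignment of the regions."""
        return (
            np.arange(self.n_regions) * self.n_modules // self.n_regions
        ).astype(int)


def _rng(spec: SyntheticCohortSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed) % (2**31), *key]))


def subject_ages(spec: SyntheticCohortSpec, subject: int) -> tuple[float, float]:
    """Deterministic (baseline, follow-up) ages for a subject."""
    rng = _rng(spec, _TAG_AGE, subject)
    lo, hi = AGE_BASELINE_RANGE
    age1 = rng.uniform(lo, hi)
    age2 = age1 + 1.0 + rng.normal(0.0, 0.05)
    return float(age1), float(age2)


def latent_factor(spec: SyntheticCohortSpec, subject: int, timepoint: int) -> float:
    """Per-scan latent brain factor g shared by FC structure and behavior."""
    return float(_rng(spec, _TAG_LATENT, subject, timepoint).normal())


def generate_modular_sc(
    spec: SyntheticCohortSpec, subject: int, timepoint: int
) -> ConnectomeMatrix:
    """Block-modular SC matrix for one scan.

    Directed "streamline counts" are drawn around the within/between block
    means (zero-clipped normals with coefficient of variation
    ``sc_weight_cv``), then row-normalised to proportions and symmetrised.
    Older age scales the between-module mean up by ``modularity_age_slope``
    per year above the age anchor, lowering modularity with age.
    """
    if timepoint not in (1, 2):
        raise ValueError("timepoint must be 1 or 2")
    age = subject_ages(spec, subject)[timepoint - 1]
    mem = spec.module_membership()
    same = mem[:, None] == mem[None, :]
    between = spec.sc_between_mean * (
        1.0 + spec.modularity_age_slope * (age - AGE_REFERENCE)
    )
    mean_mat = np.where(same, spec.sc_within_mean, max(between, 0.0))
    rng = _rng(spec, _TAG_SC, subject, timepoint)
    counts = rng.normal(mean_mat, spec.sc_weight_cv * mean_mat)
    counts = np.clip(counts, 0.0, None)
    np.fill_diagonal(counts, 0.0)
    return normalize_and_symmetrize_sc(
        counts, subject_id=f"S{subject + 1:03d}", timepoint=timepoint
    )


def _symmetric_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    e = rng.normal(0.0, 1.0, size=(n, n))
    e = (e + e.T) / np.sqrt(2.0)
    np.fill_diagonal(e, 0.0)
    return e


def generate_fc_from_sc(
    sc: ConnectomeMatrix, spec: SyntheticCohortSpec, subject: int, timepoint: int
) -> ConnectomeMatrix:
    """FC matrix for one scan, coupled to its SC matrix.

    FC = coupling * (N * SC - offset)                            (monotone map)
         + noise_sd * (sqrt(icc) * E_subject + sqrt(1-icc) * E_scan)
         + planted longitudinal change at timepoint 2
         + loading * g_scan * (u*_i + u*_j) / 2                 (planted LV)

    Streamline proportions are of order 1/N, so N * SC is of order one; the
    fixed offset pushes weak (between-module) edges negative, so Fisher-z-like
    negative weights always occur.  The subject matrix E_subject is shared by
    the subject's two scans (the fingerprint component).
    """
    n = spec.n_regions
    if sc.n_regions != n:
        raise ValueError("SC matrix does not match spec n_regions")
    base = sc.weights * n
    fc = spec.fc_coupling_strength * (base - spec.fc_offset)
    e_subj = _symmetric_noise(_rng(spec, _TAG_FC_SUBJ, subject), n)
    e_scan = _symmetric_noise(_rng(spec, _TAG_FC_SCAN, subject, timepoint), n)
    icc = spec.fingerprint_icc
    fc = fc + spec.fc_noise_sd * (np.sqrt(icc) * e_subj + np.sqrt(1 - icc) * e_scan)
    if timepoint == 2 and spec.longitudinal_delta is not None:
        d = spec.longitudinal_delta
        fc = fc + (d[:, None] + d[None, :]) / 2.0
    g = latent_factor(spec, subject, timepoint)
    u = spec.salience
    fc = fc + spec.salience_loading * g * (u[:, None] + u[None, :]) / 2.0
    np.fill_diagonal(fc, 0.0)
    return ConnectomeMatrix(fc, sc.region_labels, "FC", sc.subject_id, timepoint)


@dataclass
class GroundTruth:
    """Planted quantities stored for assertion in tests."""

    salience: np.ndarray
    beta: float
    module_membership: np.ndarray
    longitudinal_delta: np.ndarray | None
    latent: dict[tuple[int, int], float]
    ages: dict[tuple[int, int], float]


@dataclass
class CohortData:
    """A full paired synthetic cohort."""

    spec: SyntheticCohortSpec
    sc: dict[tuple[str, int], ConnectomeMatrix]
    fc: dict[tuple[str, int], ConnectomeMatrix]
    behavior: pd.DataFrame
    truth: GroundTruth

    @property
    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.spec.n_subjects)]


def generate_cohort(spec: SyntheticCohortSpec) -> CohortData:
    """Generate the full paired cohort: SC, FC, behavior, and ground truth.

    Attention scores are an age trend plus ``beta`` noise-SDs of the latent
    factor g (the same factor loaded on u* in the FC matrices) plus noise, so
    behavioral PLS has a recoverable target whenever beta > 0.
    """
    sc: dict[tuple[str, int], ConnectomeMatrix] = {}
    fc: dict[tuple[str, int], ConnectomeMatrix] = {}
    latent: dict[tuple[int, int], float] = {}
    ages: dict[tuple[int, int], float] = {}
    rows = []
    for subject in range(spec.n_subjects):
        sid = f"S{subject + 1:03d}"
        age_pair = subject_ages(spec, subject)
        for timepoint in (1, 2):
            m_sc = generate_modular_sc(spec, subject, timepoint)
            m_fc = generate_fc_from_sc(m_sc, spec, subject, timepoint)
            sc[(sid, timepoint)] = m_sc
            fc[(sid, timepoint)] = m_fc
            age = age_pair[timepoint - 1]
            g = latent_factor(spec, subject, timepoint)
            latent[(subject, timepoint)] = g
            ages[(subject, timepoint)] = age
            rng = _rng(spec, _TAG_BEHAV, subject, timepoint)
            row = {"subject_id": sid, "timepoint": timepoint, "age": age}
            for name, (intercept, slope, noise_sd) in ATTENTION_TRENDS.items():
                score = (
                    intercept
                    + slope * (age - MEAN_BASELINE_AGE)
                    + spec.beta * noise_sd * g
                    + noise_sd * rng.normal()
                )
                row[name] = score
            rows.append(row)
    behavior = pd.DataFrame(rows)
    truth = GroundTruth(
        salience=spec.salience.copy(),
        beta=spec.beta,
        module_membership=spec.module_membership(),
        longitudinal_delta=(
            None
            if spec.longitudinal_delta is None
            else spec.longitudinal_delta.copy()
        ),
        latent=latent,
        ages=ages,
    )
    return CohortData(spec, sc, fc, behavior, truth)


_METRICS = {
    "fc_degree": ("fc", weighted_degree),
    "sc_degree": ("sc", weighted_degree),
    "fc_clustering": ("fc", local_clustering_signed),
    "sc_clustering": ("sc", local_clustering_positive),
}


def cohort_metric_panel(cohort: CohortData, metric: str = "fc_degree") -> CohortPanel:
    """Compute one regional metric for every scan and stack it into a panel."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    which, fn = _METRICS[metric]
    mats = cohort.fc if which == "fc" else cohort.sc
    vectors = {key: fn(m) for key, m in mats.items()}
    labels = next(iter(mats.values())).region_labels
    return build_cohort_panel(vectors, metric_name=metric, region_labels=labels)


def generate_motion_confound(
    spec: SyntheticCohortSpec,
    contaminated_edges: float = 0.2,
    strength: float = 0.5,
    cohort: CohortData | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-scan motion values and a motion-contaminated FC edge panel.

    Mean framewise displacement is drawn per scan (gamma-distributed around
    ~0.2 mm); a random ``contaminated_edges`` fraction of the vectorised FC
    edges receives additive contamination proportional to centred motion.
    Returns (motion, edge_panel, contaminated_edge_indices).
    """
    if not 0.0 <= contaminated_edges <= 1.0:
        raise ValueError("contaminated_edges must be in [0, 1]")
    if cohort is None:
        cohort = generate_cohort(spec)
    keys = [
        (sid, tp) for tp in (1, 2) for sid in cohort.subject_ids
    ]
    panel = np.vstack([cohort.fc[k].upper_triangle() for k in keys])
    rng = _rng(spec, _TAG_MOTION)
    motion = 0.1 + rng.gamma(2.0, 0.05, size=len(keys))
    n_edges = panel.shape[1]
    n_bad = int(round(contaminated_edges * n_edges))
    bad = rng.choice(n_edges, size=n_bad, replace=False)
    panel = panel.copy()
    panel[:, bad] += strength * (motion - motion.mean())[:, None]
    return motion, panel, np.sort(bad)
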