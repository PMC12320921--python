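# Methods

This note documents the models and procedures devconn implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter when comparing
against other implementations.

## Connectivity matrices

A `ConnectomeMatrix` is square, symmetric to 1e-12, zero-diagonal, and
label-indexed. SC weights are streamline proportions: each row of the raw
count matrix is divided by its own row sum (the total streamlines sent from
the seed region) before the two directions are averaged; probabilistic
tractography gives no directional information, so symmetrisation is the
honest summary. Rows with a zero sum (tractography dropouts) are kept as
zero rows with a warning rather than rejected — downstream metrics are
defined for disconnected nodes, and erroring would make real dropout data
unusable. FC weights are Fisher z-transformed correlations; negative weights
are retained because anticorrelation is informative for the signed metrics.

Consensus thresholding treats an edge as "present" when its weight is
strictly positive — proportions are non-negative, so zero encodes absence —
and keeps it only if present in at least the given fraction of scans
(default 0.75). The mask is symmetric and monotone: raising the fraction
never adds edges.

Matrix files are plain delimited text (comma or whitespace), optionally with
a label header row; panels are CSVs with `subject_id`, `timepoint`, then one
column per region. `CohortPanel` enforces the canonical PLS layout — equal
scans per condition, each subject exactly once per condition, condition-1
block stacked above condition-2 with the same subject order.

## Signed graph metrics

**Modularity.** The quality function is the asymmetric signed form
`Q* = Q⁺ − [v⁻/(v⁺+v⁻)]·Q⁻`, equivalently the sum over within-community
pairs of the matrix `B = B⁺/v⁺ − B⁻/(v⁺+v⁻)` with `B± = W± − γ k±k±ᵀ/v±`.
Positive weights contribute at full strength; the negative-weight penalty is
scaled by the negative share, which keeps the statistic dominated by the
positive structure of FC networks. For non-negative input it reduces exactly
to Newman's weighted modularity. Optimisation is Louvain operating directly
on `B` (local moves, then aggregation of `B` by community, repeated to a
fixed point). Louvain is stochastic, so the implementation takes a mandatory
seed and runs `n_restarts` random-order restarts (default 100), returning
the best partition; on small graphs this reliably attains the exhaustive
optimum (checked against a full partition enumeration in the tests). The
resolution parameter γ defaults to 1 and is exposed.

**Clustering.** The non-negative variant normalises weights by the network
maximum and computes the geometric-mean triangle intensity over the binary
number of neighbour pairs, with `C_i = 0` for degree < 2. The signed variant
is `C_i = Σ_{j≠h} w_ij w_ih w_jh / Σ_{j≠h} |w_ij w_ih|` (numerator
`diag(W³)`, denominator `(Σ|w|)² − Σw²` per row), lying in [−1, 1]; a zero
denominator (isolated node) yields 0 by convention, matching the behaviour
of the standard toolbox implementations.

**Weighted degree** is `Σ_{j≠i} w_ij / (N−1)` — the off-diagonal mean, since
self-connections are structurally zero.

## Null models

Null networks preserve, per sign class, the exact binary degree sequence and
the exact multiset of edge weights, and approximate the strength sequence:

1. *Topology*: double-edge swaps within each sign class, default 10 swap
   attempts per edge. A proposed swap is accepted only if both target slots
   have the same occupancy status — both empty, or both held by the opposite
   sign class. In the latter case the displaced opposite-sign edges take the
   vacated slots; this exchange preserves the degree sequences of both
   classes simultaneously and is what makes the scheme work on dense signed
   FC matrices, where the two classes tile the complete graph and no empty
   slots exist.
2. *Weights*: the class's original weights, sorted descending, are assigned
   to the rewired edges ranked by the product of residual node strengths;
   residuals are decremented as weights are placed and the ranking is
   recomputed every 10% of assignments (both knobs exposed). On planted
   modular networks the resulting node strengths correlate with the
   originals at r ≈ 0.97.

Empirical p-values are tail proportions with ties counted as extreme and
denominator n (not n+1), so the smallest resolvable nonzero p is 1/n and a
zero count is reported in text as p < 1/n.

## SC–FC coupling

Per region: Spearman correlation (average ranks for ties) between the SC and
FC profiles over the N−1 off-diagonal entries. Zero SC entries stay in the
profile — indirect structural paths can support functional connections, so
pre-thresholding the ranked profile would discard signal. Constant profiles
make the correlation undefined; these are returned as NaN and logged rather
than silently zeroed.

## PLS

**Decompositions.** Mean-centered task PLS builds the k×p matrix of
per-condition column means, subtracts the unweighted grand mean of condition
means, and decomposes the transpose; with two conditions the deviation rows
are mirror images, so exactly one LV carries signal and its design salience
is ±(1,−1)/√2. Behavioral PLS computes, within each condition, the Pearson
correlation of each behavior column with each region column, stacks the
condition-by-behavior rows, and decomposes the transpose. Sign convention:
each U column's largest-magnitude element is made positive, V adjusted to
match; every reported quantity is invariant to this choice. The energy
identity `Σ s_l² = ‖R‖²_F` holds to 1e-9 and is asserted in the tests.
Region columns that are constant within a condition would make a
correlation undefined; they are set to 0 with a warning, while a
zero-variance *behavior* column is an error naming the condition and column.

**Permutation test.** Scan rows of X are shuffled without restriction
across the whole stack (breaking condition assignment in mean-centered mode
and X–Y correspondence in behavioral mode), the decomposition is recomputed,
and `p_l = #(s_perm,l ≥ s_obs,l)/n_perm` per LV with raw (unrotated)
singular values. An alternative within-subject condition-swap scheme was
considered and not adopted: unrestricted shuffling is the classic default
for this family of analyses, and the calibration test shows the nominal
5% level holds under it. Default 1,000 permutations.

**Bootstrap.** Subjects are resampled with replacement with both timepoints
held together (consistent with the split-half rule; resampling rows
independently would break the pairing the design assumes). Each resample's
singular-value-scaled saliences `U_b S_b` are aligned to the original `U S`
by orthogonal Procrustes; weighting by the singular values keeps noise-level
trailing LVs from rotating variance into the leading LV. The bootstrap ratio
is the original scaled salience over the bootstrap SD of the aligned scaled
saliences — the toolbox-standard "salience / SE" reliability score, read
like a z-score with |BSR| > 2 ≈ 95% confidence. Regions with zero bootstrap
SE get NaN with a warning. For behavioral mode, per-condition correlations
between LV brain scores and each behavior are collected per resample and
summarised as 2.5/97.5 percentile intervals; intervals crossing zero flag
unstable LVs. Default 500 resamples.

**Reproducibility.** Both assessments run over random split-halves of the
subjects (timepoints together; odd counts put the extra subject in the
train/first half deterministically), default 500 splits. *Test-train*: the
training half's singular vectors project the test half's decomposed matrix,
`s_test,l = u_lᵀ R_test v_l`; the distribution's mean/SD gives z (values can
be negative; they are not rectified). *Split-half*: each half is decomposed
independently, LVs are matched across halves by greedy maximal |cosine| of
the brain saliences (axis order can swap between halves), and the |cosine|
distribution is z-scored. Absolute cosine is used because singular vectors
carry an arbitrary sign. Null z-scores repeat the procedure on row-permuted
panels — one split schedule per permutation — and average the
per-permutation z (the aggregation is a package choice; default 100
permutations, reduced in the heavier simulations). An LV is reproducible
when z exceeds its null z by more than 2.

**Cosine specificity.** The observed cosine between a salience and another
analysis's salience is tested against the null |cosine| distribution
obtained by re-running the second analysis on row-permuted data,
`p = #(|null| ≥ |observed|)/n_perm`.

## QC statistics

Fingerprinting correlates vectorised upper triangles (Pearson, diagonal
excluded) and counts a match when a scan's argmax partner shares its
subject; the denominator is all scans, so scans without a same-subject
partner can only lower the rate — they serve as potential false matches.
QC-FC tests each edge's Pearson correlation with mean framewise displacement
two-sided and uncorrected at α = 0.05 (matching the convention the metric is
defined by); zero-variance edges are excluded from the fraction and counted
separately. The exclusion ledger is sequential subtraction with per-stage
validation. Panel PCA column-centers the panel and reports squared singular
values over their total, truncating (with a warning) at the numerical rank.

## Synthetic cohort generator

The generator's job is to produce cohorts in which every quantity the
pipeline estimates has a known planted value. Defaults describe a
39-subject, 193-region, 4-module paired cohort with baseline ages uniform on
4.14–6.88 years and follow-up one year later (small jitter).

* **SC** — directed "streamline counts" drawn as zero-clipped normals around
  block means (within-module 4.0, between-module 1.0, coefficient of
  variation 0.2), then row-normalised and symmetrised by the same code path
  real data would use. Age scales the between-module mean up by
  `modularity_age_slope` (default 0.05/year above the 4.0-year anchor), so
  modularity falls with age.
* **FC** — `coupling · (N·SC − 1) + noise + planted terms`. Proportions are
  of order 1/N, so N·SC is of order one and the fixed offset makes weak
  between-module edges negative (Fisher-z-like signed weights). The noise
  term is `fc_noise_sd · (√icc · E_subj + √(1−icc) · E_scan)` with symmetric
  standard-normal matrices: `E_subj` is shared by a subject's two scans and
  carries the fingerprint; `fingerprint_icc` is its variance share (default
  0.4). The fixed N·SC scaling matters: normalising by a per-scan maximum
  would leak age into every region's FC degree and contaminate the planted
  brain–behavior pattern. Timepoint 2 optionally adds `(δ_i + δ_j)/2` for a
  per-region change vector δ (`with_defaults_planted()` sets −0.08 on the
  last 10% of regions). A per-scan latent `g ~ N(0,1)` adds
  `loading · g · (u*_i + u*_j)/2` with `u*` the unit-norm, zero-sum planted
  salience (default ±loadings on two 10% region blocks) and loading 0.4.
* **Behavior** — each attention score is an intercept plus an age slope
  (2.30, 1.78, 4.03 score units/year for sustained, selective, executive —
  values typical of this age range), plus `beta` noise-SDs of the same
  latent g (default beta 1.5), plus noise. With beta = 0 the cohort is an
  exact global null for behavioral PLS.
* **Motion** — per-scan mean framewise displacement from a gamma
  distribution around ~0.2 mm; a chosen fraction of FC edges receives
  additive contamination proportional to centred motion.

All generators are pure functions of (spec, subject, timepoint): streams are
derived from the spec seed plus subject, timepoint and a fixed stream tag,
so repeated calls are bitwise identical and subject-level components are
consistent across that subject's scans.

The noise and effect-size defaults were chosen together so that, at the
default cohort size, the planted pattern is recoverable to the documented
contracts (LV1 salience cosine ≥ 0.9 with u*; |BSR| > 2 sensitivity ≥ 0.8
with false-positive rate ≤ 0.1; fingerprint rate ≥ 0.95 at icc 0.8 and
chance-level at 0) while the beta = 0 null remains exactly calibrated —
these are the study conditions the generator defines, not tuning targets
revisited per analysis.

**What the generator does not emulate.** Edge weights are conditionally
Gaussian, not the heavy-tailed distributions of real streamline counts;
spatial autocorrelation, distance effects and hemispheric structure are
absent; FC is a static monotone map of SC plus noise rather than emergent
dynamics; behavior has a single latent factor. Tests passing on these
cohorts therefore validate the statistical machinery — estimator
definitions, resampling schemes, calibration, recovery at a known SNR — not
claims about real developmental data.

## Problem sizes in the simulations

The acceptance-style simulations use deliberately scaled resampling depths
chosen as sensible desk-scale defaults: permutation calibration uses 200
cohorts at 200 permutations; BSR classification uses 200 bootstraps over 5
cohorts; reproducibility separation uses 100 splits and 10 null permutations
over 50 cohort pairs; the null-model comparison uses a 60-node planted
network with 1,000 nulls. The package defaults remain 1,000 permutations /
500 bootstraps / 500 splits.

## Known limitations

* The Louvain implementation aggregates the dense modularity matrix, which
  is quadratic in regions — appropriate for parcellation-scale networks
  (hundreds of regions), not voxel-level graphs.
* Strength preservation in the null model is approximate by construction;
  only degrees and weight multisets are exact. Annealing-based
  strength-exact nulls and spatially constrained nulls are out of scope.
* Reproducibility z-scores assume the split-half distributions are roughly
  Gaussian; with very few subjects (< ~8) the z is noisy and the permutation
  null correspondingly wide.
* Multi-group designs (> 2 conditions) run through the same code paths for
  the decompositions, but the planted-structure generator and the worked
  contracts cover the two-condition paired design only.
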