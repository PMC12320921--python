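import numpy as np
import pandas as pd
import pytest

from devconn.io import CohortPanel, build_cohort_panel
from devconn.pls import (
    ReproducibilityReport,
    _zscore,
    behavioral_pls,
    bootstrap_saliences,
    cosine_similarity,
    mean_centered_pls,
    permutation_pvalues,
    salience_cosine_specificity,
    split_half_vector_reproducibility,
)
from devconn.pls import test_train_reproducibility as reproducibility_test_train


def make_panel(cond1_rows, cond2_rows, region_labels=None):
    cond1_rows = np.atleast_2d(np.asarray(cond1_rows, float))
    cond2_rows = np.atleast_2d(np.asarray(cond2_rows, float))
    n = cond1_rows.shape[0]
    subjects = [f"s{i}" for i in range(n)]
    return CohortPanel(
        np.vstack([cond1_rows, cond2_rows]),
        subjects + subjects,
        np.array([1] * n + [2] * n),
        "metric",
        region_labels or [],
    )


class TestMeanCenteredPLS:
    def test_closed_form_two_region_example(self):
        # condition means (1, 0) and (0, 0): deviation matrix has s1 = 1/sqrt(2)
        panel = make_panel([[1, 0], [1, 0]], [[0, 0], [0, 0]])
        res = mean_centered_pls(panel)
        assert res.s[0] == pytest.approx(0.707107, abs=1e-6)
        assert np.allclose(np.abs(res.U[:, 0]), [1.0, 0.0], atol=1e-9)
        assert np.allclose(np.abs(res.V[:, 0]), [0.707107, 0.707107], atol=1e-6)
        assert res.V[0, 0] * res.V[1, 0] < 0  # condition contrast

    def test_identical_condition_means_give_zero(self, rng):
        x = rng.normal(size=(3, 4))
        panel = make_panel(x, x)
        res = mean_centered_pls(panel)
        assert np.allclose(res.s, 0.0, atol=1e-12)

    def test_homogeneity_in_scale(self, rng):
        x1, x2 = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        r1 = mean_centered_pls(make_panel(x1, x2))
        r2 = mean_centered_pls(make_panel(2 * x1, 2 * x2))
        assert r2.s[0] == pytest.approx(2 * r1.s[0])
        assert abs(cosine_similarity(r1.U[:, 0], r2.U[:, 0])) == pytest.approx(1.0)

    def test_two_condition_design_salience_is_contrast(self, rng):
        x1, x2 = rng.normal(size=(6, 8)), rng.normal(size=(6, 8))
        res = mean_centered_pls(make_panel(x1, x2))
        assert np.allclose(np.abs(res.V[:, 0]), 1 / np.sqrt(2), atol=1e-9)

    def test_energy_conservation(self, rng):
        x1, x2 = rng.normal(size=(5, 7)), rng.normal(size=(5, 7))
        res = mean_centered_pls(make_panel(x1, x2))
        assert np.sum(res.s**2) == pytest.approx(
            np.sum(res.decomposed_matrix**2), abs=1e-9
        )

    def test_single_condition_rejected(self):
        panel = CohortPanel(np.zeros((2, 3)), ["a", "b"], np.array([1, 1]))
        with pytest.raises(ValueError, match="2 conditions"):
            mean_centered_pls(panel)


def exact_correlation_panel():
    """Panel and behavior whose within-condition correlation matrix is exactly
    [[1, 0], [1, 0]]: behavior equals region 1, region 2 orthogonal to it."""
    r1 = np.array([1.0, 2.0, 3.0, 4.0])
    r2 = np.array([1.0, -1.0, -1.0, 1.0])  # exactly uncorrelated with r1
    x = np.column_stack([r1, r2])
    panel = make_panel(x, x)
    y = np.concatenate([r1, r1])[:, None]
    return panel, y


class TestBehavioralPLS:
    def test_closed_form_correlation_example(self):
        panel, y = exact_correlation_panel()
        res = behavioral_pls(panel, y)
        assert res.s[0] == pytest.approx(np.sqrt(2), abs=1e-9)
        assert np.allclose(np.abs(res.U[:, 0]), [1.0, 0.0], atol=1e-9)
        assert np.allclose(np.abs(res.V[:, 0]), 1 / np.sqrt(2), atol=1e-9)

    def test_energy_conservation(self, rng):
        x = rng.normal(size=(12, 6))
        panel = make_panel(x[:6], x[6:])
        y = rng.normal(size=(12, 2))
        res = behavioral_pls(panel, y)
        assert np.sum(res.s**2) == pytest.approx(
            np.sum(res.decomposed_matrix**2), abs=1e-9
        )
        # singular vectors orthonormal, singular values sorted
        assert np.allclose(res.U.T @ res.U, np.eye(res.n_lv), atol=1e-9)
        assert np.all(np.diff(res.s) <= 1e-12)

    def test_duplicated_behavior_scales_singular_value(self, rng):
        x = rng.normal(size=(12, 5))
        panel = make_panel(x[:6], x[6:])
        y = rng.normal(size=(12, 1))
        res1 = behavioral_pls(panel, y)
        res2 = behavioral_pls(panel, np.hstack([y, y]))
        assert res2.s[0] == pytest.approx(np.sqrt(2) * res1.s[0], abs=1e-9)

    def test_zero_variance_behavior_rejected(self):
        panel = make_panel(np.eye(3), np.eye(3))
        y = np.ones((6, 1))
        with pytest.raises(ValueError, match="zero variance"):
            behavioral_pls(panel, y)

    def test_behavior_table_alignment(self):
        panel = build_cohort_panel(
            {("a", 1): [1.0, 0.0], ("b", 1): [2.0, 1.0], ("a", 2): [3.0, 0.5],
             ("b", 2): [0.0, 2.0]}
        )
        table = pd.DataFrame(
            {
                "subject_id": ["b", "a", "b", "a"],
                "timepoint": [2, 2, 1, 1],
                "age": [6.5, 6.1, 5.5, 5.1],
            }
        )
        res = behavioral_pls(panel, table, ["age"])
        assert res.mode == "behavioral"
        assert res.behavior_correlations is not None


class TestPermutation:
    def test_pvalues_bounded_and_attached(self, rng):
        x = rng.normal(size=(16, 6))
        panel = make_panel(x[:8], x[8:])
        res = mean_centered_pls(panel)
        p = permutation_pvalues(res, panel, n_perm=99, seed=1)
        assert np.all((p >= 0) & (p <= 1))
        assert res.perm_p is p

    def test_strong_effect_never_beaten(self, rng):
        base = rng.normal(size=(10, 5))
        panel = make_panel(base, base + 5.0)  # huge uniform condition shift
        res = mean_centered_pls(panel)
        p = permutation_pvalues(res, panel, n_perm=200, seed=2)
        assert p[0] == 0.0

    def test_invariant_to_region_reordering(self, rng):
        x = rng.normal(size=(12, 6))
        y = rng.normal(size=(12, 1))
        panel = make_panel(x[:6], x[6:])
        res = behavioral_pls(panel, y)
        p1 = permutation_pvalues(res, panel, y, n_perm=50, seed=3)
        order = rng.permutation(6)
        panel2 = make_panel(x[:6][:, order], x[6:][:, order])
        res2 = behavioral_pls(panel2, y)
        p2 = permutation_pvalues(res2, panel2, y, n_perm=50, seed=3)
        assert np.allclose(p1, p2)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(8, 4))
        panel = make_panel(x[:4], x[4:])
        res = mean_centered_pls(panel)
        p1 = permutation_pvalues(res, panel, n_perm=50, seed=9)
        p2 = permutation_pvalues(res, panel, n_perm=50, seed=9)
        assert np.array_equal(p1, p2)


class TestBootstrap:
    def test_deterministic_and_finite(self, rng):
        x = rng.normal(size=(20, 6))
        panel = make_panel(x[:10], x[10:] + 1.0)
        res = mean_centered_pls(panel)
        b1 = bootstrap_saliences(res, panel, n_boot=50, seed=4)
        b2 = bootstrap_saliences(res, panel, n_boot=50, seed=4)
        assert np.allclose(b1.bsr, b2.bsr, equal_nan=True)

    def test_bsr_is_salience_over_se(self, rng):
        x = rng.normal(size=(20, 4))
        panel = make_panel(x[:10], x[10:] + 2.0)
        res = mean_centered_pls(panel)
        b = bootstrap_saliences(res, panel, n_boot=80, seed=5)
        scaled = res.U * res.s
        ok = b.salience_se > 0
        assert np.allclose(b.bsr[ok], scaled[ok] / b.salience_se[ok])

    def test_constant_region_gets_missing_bsr(self, caplog, rng):
        x = rng.normal(size=(16, 3))
        x[:, 2] = 0.0  # a dead region: zero salience and zero bootstrap spread
        panel = make_panel(x[:8], x[8:])
        res = mean_centered_pls(panel)
        with caplog.at_level("WARNING"):
            b = bootstrap_saliences(res, panel, n_boot=30, seed=6)
        assert np.isnan(b.bsr[2]).all()
        assert "zero bootstrap SE" in caplog.text

    def test_behavior_correlation_intervals_reported(self, rng):
        x = rng.normal(size=(24, 5))
        y = x[:, :1] + 0.5 * rng.normal(size=(24, 1))
        panel = make_panel(x[:12], x[12:])
        res = behavioral_pls(panel, y)
        b = bootstrap_saliences(res, panel, y, n_boot=60, seed=7)
        ci = b.behavior_correlation_intervals
        assert ci is not None
        assert {"ci_low", "ci_high", "crosses_zero"} <= set(ci.columns)
        assert np.all(ci["ci_low"] <= ci["ci_high"])


class TestReproducibility:
    def test_zscore_formula(self):
        samples = np.array([[10.0], [14.0], [6.0]])  # mean 10, sd 4
        assert _zscore(samples)[0] == pytest.approx(2.5)

    def test_reproducible_flag_rule(self):
        rep = ReproducibilityReport(
            z_test_train=np.array([2.5, 1.0]),
            z_null_test_train=np.array([0.1, 0.5]),
        )
        assert rep.reproducible("test_train").tolist() == [True, False]
        with pytest.raises(ValueError, match="split_half"):
            rep.reproducible("split_half")

    def test_planted_effect_detected_and_noise_not(self, rng):
        base = rng.normal(size=(16, 12))
        shift = np.zeros(12)
        shift[:4] = 2.0
        planted = make_panel(base, base + shift + 0.3 * rng.normal(size=(16, 12)))
        rep = reproducibility_test_train(planted, n_splits=60, n_perm=10, seed=8)
        assert rep.reproducible("test_train")[0]
        noise = make_panel(
            rng.normal(size=(16, 12)), rng.normal(size=(16, 12))
        )
        rep_n = reproducibility_test_train(noise, n_splits=60, n_perm=10, seed=8)
        assert (rep_n.z_test_train[0] - rep_n.z_null_test_train[0]) < 2

    def test_split_half_detects_planted_vector(self, rng):
        base = rng.normal(size=(16, 12))
        shift = np.zeros(12)
        shift[:4] = 2.0
        planted = make_panel(base, base + shift + 0.3 * rng.normal(size=(16, 12)))
        rep = split_half_vector_reproducibility(
            planted, n_splits=60, n_perm=10, seed=9
        )
        assert rep.reproducible("split_half")[0]

    def test_too_few_subjects_rejected(self, rng):
        panel = make_panel(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        with pytest.raises(ValueError, match="4 subjects"):
            reproducibility_test_train(panel, n_splits=5, n_perm=2, seed=0)


class TestCosineSpecificity:
    def test_identical_and_orthogonal_vectors(self):
        assert cosine_similarity([1, 0], [2, 0]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 3]) == pytest.approx(0.0)
        with pytest.raises(ValueError, match="zero vector"):
            cosine_similarity([0, 0], [1, 0])

    def test_self_similarity_is_significant(self, rng):
        base = rng.normal(size=(10, 6))
        panel = make_panel(base, base + 3.0)
        res = mean_centered_pls(panel)
        cos, p = salience_cosine_specificity(
            res.U[:, 0], panel, n_perm=99, seed=10
        )
        assert cos == pytest.approx(1.0)
        assert p < 0.05
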