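import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from devconn.coupling import regional_scfc_coupling
from devconn.metrics import modularity_signed
from devconn.qc import fingerprint_match_rate, qcfc_summary
from devconn.synth import (
    SyntheticCohortSpec,
    cohort_metric_panel,
    generate_cohort,
    generate_fc_from_sc,
    generate_modular_sc,
    generate_motion_confound,
)


class TestSpecValidation:
    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError, match="n_modules"):
            SyntheticCohortSpec(n_regions=4, n_modules=8)
        with pytest.raises(ValueError, match="icc"):
            SyntheticCohortSpec(fingerprint_icc=1.0)
        with pytest.raises(ValueError, match="unit norm"):
            SyntheticCohortSpec(n_regions=10, salience=np.ones(10))

    def test_default_salience_is_unit_zero_sum(self):
        spec = SyntheticCohortSpec(n_regions=50)
        assert np.linalg.norm(spec.salience) == pytest.approx(1.0)
        assert spec.salience.sum() == pytest.approx(0.0)


class TestGenerators:
    def test_matrix_invariants(self):
        spec = SyntheticCohortSpec(n_subjects=2, n_regions=30, seed=1)
        sc = generate_modular_sc(spec, 0, 1)
        fc = generate_fc_from_sc(sc, spec, 0, 1)
        assert np.allclose(sc.weights, sc.weights.T)
        assert np.all(np.diag(sc.weights) == 0)
        assert np.all(sc.weights >= 0)
        assert np.allclose(fc.weights, fc.weights.T)
        assert np.all(np.diag(fc.weights) == 0)
        assert np.any(fc.weights < 0)  # Fisher-z-like negative weights occur

    def test_bitwise_determinism(self):
        spec = SyntheticCohortSpec(n_subjects=2, n_regions=25, seed=9)
        a = generate_modular_sc(spec, 1, 2)
        b = generate_modular_sc(spec, 1, 2)
        assert np.array_equal(a.weights, b.weights)
        fa = generate_fc_from_sc(a, spec, 1, 2)
        fb = generate_fc_from_sc(b, spec, 1, 2)
        assert np.array_equal(fa.weights, fb.weights)

    def test_pure_block_structure_recovered_by_louvain(self):
        spec = SyntheticCohortSpec(
            n_subjects=1, n_regions=36, n_modules=3, sc_between_mean=0.0, seed=3
        )
        sc = generate_modular_sc(spec, 0, 1)
        res = modularity_signed(sc, n_restarts=20, seed=0)
        mem = res.membership(sc.region_labels)
        assert adjusted_rand_score(spec.module_membership(), mem) == pytest.approx(1.0)

    def test_age_slope_lowers_modularity(self):
        mean_q = []
        for slope in (0.0, 0.1, 0.3):
            spec = SyntheticCohortSpec(
                n_subjects=6, n_regions=40, modularity_age_slope=slope, seed=17
            )
            qs = [
                modularity_signed(
                    generate_modular_sc(spec, s, tp), n_restarts=5, seed=0
                ).Q
                for s in range(6)
                for tp in (1, 2)
            ]
            mean_q.append(np.mean(qs))
        assert mean_q[0] > mean_q[1] > mean_q[2]

    def test_noiseless_limit_gives_perfect_coupling(self):
        spec = SyntheticCohortSpec(
            n_subjects=1,
            n_regions=30,
            fc_noise_sd=0.0,
            fingerprint_icc=0.0,
            salience_loading=0.0,
            seed=5,
        )
        sc = generate_modular_sc(spec, 0, 1)
        fc = generate_fc_from_sc(sc, spec, 0, 1)
        c = regional_scfc_coupling(sc, fc)
        assert np.allclose(c[~np.isnan(c)], 1.0)


class TestCohort:
    def test_default_cohort_dimensions(self):
        spec = SyntheticCohortSpec(seed=2)
        cohort = generate_cohort(spec)
        panel = cohort_metric_panel(cohort, "fc_degree")
        assert panel.values.shape == (78, 193)
        assert len(cohort.behavior) == 78
        assert set(cohort.behavior.columns) >= {
            "subject_id",
            "timepoint",
            "age",
            "sustained",
            "selective",
            "executive",
        }

    def test_ages_within_study_ranges(self):
        spec = SyntheticCohortSpec(n_subjects=30, n_regions=10, seed=4)
        cohort = generate_cohort(spec)
        b = cohort.behavior
        t1 = b[b.timepoint == 1]["age"]
        t2 = b[b.timepoint == 2]["age"]
        assert t1.between(4.14, 6.88).all()
        assert ((t2.to_numpy() - t1.to_numpy()) > 0.7).all()

    def test_strong_fingerprint_component_identifies_subjects(self):
        spec = SyntheticCohortSpec(
            n_subjects=8, n_regions=40, fingerprint_icc=0.9, seed=6
        )
        cohort = generate_cohort(spec)
        assert fingerprint_match_rate(list(cohort.fc.values())) >= 0.9

    def test_ground_truth_latents_drive_behavior(self):
        spec = SyntheticCohortSpec(n_subjects=30, n_regions=10, beta=2.0, seed=8)
        cohort = generate_cohort(spec)
        g = [
            cohort.truth.latent[(s, tp)]
            for tp in (1, 2)
            for s in range(30)
        ]
        sustained = cohort.behavior.sort_values(["timepoint", "subject_id"])[
            "sustained"
        ]
        r = np.corrcoef(g, sustained)[0, 1]
        assert r > 0.5


class TestMotionConfound:
    def test_deterministic_and_clean_at_zero_fraction(self):
        spec = SyntheticCohortSpec(n_subjects=10, n_regions=30, seed=12)
        m1, p1, bad1 = generate_motion_confound(spec, 0.0)
        m2, p2, bad2 = generate_motion_confound(spec, 0.0)
        assert np.array_equal(m1, m2) and np.array_equal(p1, p2)
        assert bad1.size == 0

    def test_strong_contamination_detected_by_qcfc(self):
        spec = SyntheticCohortSpec(n_subjects=20, n_regions=40, seed=13)
        motion, panel, bad = generate_motion_confound(spec, 0.5, strength=4.0)
        res = qcfc_summary(panel, motion)
        assert res.fraction_significant >= 0.4
        assert bad.size == int(round(0.5 * panel.shape[1]))
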