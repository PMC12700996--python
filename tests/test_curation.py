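"""Unit and property tests for curation: trajectories, filters, scaling, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amldyn.curation import (
    BLAST_SCALE,
    ClinicalCohort,
    FeatureEntry,
    FeatureManifest,
    FeatureTrajectory,
    PatientRecord,
    apply_scaling,
    auc_over_duration,
    denormalize_cohort,
    filter_features,
    filter_patients,
    interpolate_feature,
    normalize_cohort,
    read_cohort,
    split_cohort,
    treatment_to_signal,
    write_cohort,
)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

class TestManifest:
    def test_accessors(self, small_manifest):
        assert small_manifest.names() == ["age", "flt3_itd", "chemo"]
        assert small_manifest.dtype_of("age") == "continuous"
        assert small_manifest.category_of("chemo") == "disease_management"
        assert small_manifest.by_dtype("interval") == ["chemo"]
        assert small_manifest.by_category("leukemia_parameter") == ["flt3_itd"]

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            FeatureManifest([
                FeatureEntry("a", "patient_info", "continuous"),
                FeatureEntry("a", "patient_info", "binary"),
            ])

    def test_bad_dtype_rejected(self):
        with pytest.raises(ValueError):
            FeatureManifest([FeatureEntry("a", "patient_info", "ordinal")])

    def test_yaml_round_trip(self, small_manifest, tmp_path):
        path = tmp_path / "manifest.yaml"
        small_manifest.to_yaml(path)
        back = FeatureManifest.from_yaml(path)
        assert back.entries == small_manifest.entries

    def test_subset_preserves_order(self, small_manifest):
        sub = small_manifest.subset(["chemo", "age"])
        assert sub.names() == ["age", "chemo"]


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

class TestInterpolation:
    def test_continuous_passes_through_observations(self):
        obs = [(0.0, 1.0), (10.0, 3.0), (25.0, 2.0)]
        traj = interpolate_feature(obs, "continuous")
        for t, v in obs:
            assert traj.evaluate(t) == pytest.approx(v)

    def test_continuous_linear_between_knots(self):
        traj = interpolate_feature([(0.0, 0.0), (10.0, 10.0)], "continuous")
        assert traj.evaluate(4.0) == pytest.approx(4.0)

    def test_binary_zero_order_hold(self):
        traj = interpolate_feature([(0.0, 0.0), (10.0, 1.0)], "binary")
        assert traj.evaluate(9.999) == 0.0
        assert traj.evaluate(10.0) == 1.0
        assert traj.evaluate(50.0) == 1.0

    def test_constant_extension_outside_domain(self):
        traj = interpolate_feature([(5.0, 2.0), (10.0, 4.0)], "continuous")
        assert traj.evaluate(0.0) == pytest.approx(2.0)
        assert traj.evaluate(100.0) == pytest.approx(4.0)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            interpolate_feature([(5.0, 1.0), (2.0, 2.0)], "continuous")

    def test_interval_dtype_rejected(self):
        with pytest.raises(ValueError):
            interpolate_feature([(0.0, 1.0)], "interval")

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(-10, 10)),
                    min_size=1, max_size=10,
                    unique_by=lambda o: round(o[0], 6)))
    @settings(max_examples=100, derandomize=True)
    def test_exactness_property(self, obs):
        obs = sorted(obs)
        if len({t for t, _ in obs}) < len(obs):
            return
        for dtype in ("continuous", "binary"):
            traj = interpolate_feature(obs, dtype)
            for t, v in obs:
                assert traj.evaluate(t) == pytest.approx(v, abs=1e-9)


class TestTreatmentSignal:
    def test_basic_indicator(self):
        traj = treatment_to_signal([(10.0, 20.0)], (0.0, 30.0))
        assert traj.evaluate(5.0) == 0.0
        assert traj.evaluate(10.0) == 1.0
        assert traj.evaluate(15.0) == 1.0
        assert traj.evaluate(20.0) == 1.0  # closed interval
        assert traj.evaluate(20.5) == 0.0

    def test_overlapping_intervals_merged(self):
        traj = treatment_to_signal([(5.0, 15.0), (10.0, 20.0)], (0.0, 30.0))
        assert traj.evaluate(12.0) == 1.0
        assert np.count_nonzero(np.diff(traj.values)) <= 2

    def test_empty_is_zero(self):
        traj = treatment_to_signal([], (0.0, 30.0))
        assert traj.evaluate(15.0) == 0.0

    def test_inconsistent_interval_raises(self):
        with pytest.raises(ValueError):
            treatment_to_signal([(20.0, 10.0)], (0.0, 30.0))

    def test_integral_matches_covered_time(self):
        traj = treatment_to_signal([(2.0, 6.0), (10.0, 12.0)], (0.0, 20.0))
        assert traj.integral() == pytest.approx(4.0 + 2.0, abs=1e-9)


class TestAuc:
    def test_ramp(self):
        ramp = FeatureTrajectory("piecewise_linear",
                                 np.array([0.0, 10.0]), np.array([0.0, 10.0]),
                                 (0.0, 10.0))
        assert auc_over_duration(ramp) == pytest.approx(5.0)

    def test_step(self):
        step = FeatureTrajectory("step", np.array([0.0, 5.0]),
                                 np.array([0.0, 2.0]), (0.0, 10.0))
        # 0 on [0,5), 2 on [5,10] -> integral 10, mean 1
        assert auc_over_duration(step) == pytest.approx(1.0)

    def test_zero_length_domain_raises(self):
        flat = FeatureTrajectory("step", np.array([0.0]), np.array([1.0]),
                                 (0.0, 0.0))
        with pytest.raises(ValueError):
            auc_over_duration(flat)


# ---------------------------------------------------------------------------
# Patient filtration
# ---------------------------------------------------------------------------

def _complete_patient(pid: str) -> PatientRecord:
    return PatientRecord(
        pid,
        feature_obs={"age": [(0.0, 0.5)], "flt3_itd": [(0.0, 1.0)]},
        treatments=[("chemo", 5.0, 10.0)],
        blast_obs=[(0.0, 30.0), (30.0, 40.0)],
    )


class TestFilterPatients:
    def test_complete_patients_kept(self, small_manifest):
        cohort = ClinicalCohort([_complete_patient("a"), _complete_patient("b")],
                                small_manifest)
        out, log = filter_patients(cohort)
        assert len(out) == 2 and len(log) == 0

    def test_each_rule_triggers(self, small_manifest):
        p1 = _complete_patient("no_treat"); p1.treatments = []
        p2 = _complete_patient("bad_dates"); p2.treatments = [("chemo", 10.0, 5.0)]
        p3 = _complete_patient("no_mut"); p3.feature_obs.pop("flt3_itd")
        p4 = _complete_patient("few_blasts"); p4.blast_obs = [(0.0, 30.0)]
        cohort = ClinicalCohort([p1, p2, p3, p4, _complete_patient("ok")],
                                small_manifest)
        out, log = filter_patients(cohort)
        assert [p.patient_id for p in out.patients] == ["ok"]
        assert dict(zip(log.subjects(), log.rules())) == {
            "no_treat": "missing_treatments",
            "bad_dates": "inconsistent_treatment_dates",
            "no_mut": "missing_mutations",
            "few_blasts": "insufficient_blasts",
        }

    def test_first_matching_rule_wins(self, small_manifest):
        p = _complete_patient("multi")
        p.treatments = []          # rule 1
        p.blast_obs = [(0.0, 1.0)]  # also rule 4
        cohort = ClinicalCohort([p, _complete_patient("ok")], small_manifest)
        _, log = filter_patients(cohort)
        assert log.rules() == ["missing_treatments"]

    def test_min_blast_obs_validated(self, small_manifest):
        cohort = ClinicalCohort([_complete_patient("a")], small_manifest)
        with pytest.raises(ValueError):
            filter_patients(cohort, min_blast_obs=1)


class TestFilterFeatures:
    def _cohort(self, small_manifest, n=20, positives=1, variance=True):
        patients = []
        for i in range(n):
            p = _complete_patient(f"p{i}")
            p.feature_obs["flt3_itd"] = [(0.0, 1.0 if i < positives else 0.0)]
            p.feature_obs["age"] = [(0.0, 0.5 + (0.01 * i if variance else 0.0))]
            patients.append(p)
        return ClinicalCohort(patients, small_manifest)

    def test_low_prevalence_binary_dropped(self, small_manifest):
        cohort = self._cohort(small_manifest, n=40, positives=1)
        out, log = filter_features(cohort, min_prevalence=0.05)
        assert "flt3_itd" not in out.manifest.names()
        assert log.rules() == ["low_prevalence"]

    def test_prevalent_binary_kept(self, small_manifest):
        cohort = self._cohort(small_manifest, n=40, positives=10)
        out, _ = filter_features(cohort, min_prevalence=0.05)
        assert "flt3_itd" in out.manifest.names()

    def test_constant_continuous_dropped(self, small_manifest):
        cohort = self._cohort(small_manifest, positives=10, variance=False)
        out, log = filter_features(cohort)
        assert "age" not in out.manifest.names()
        assert "low_variance" in log.rules()

    def test_interval_features_always_kept(self, small_manifest):
        cohort = self._cohort(small_manifest, positives=10)
        out, _ = filter_features(cohort)
        assert "chemo" in out.manifest.names()

    def test_observations_of_dropped_features_removed(self, small_manifest):
        cohort = self._cohort(small_manifest, n=40, positives=1)
        out, _ = filter_features(cohort)
        assert all("flt3_itd" not in p.feature_obs for p in out.patients)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class TestNormalization:
    def test_continuous_to_unit_interval(self, small_cohort):
        out, scaling = normalize_cohort(small_cohort)
        vals = [v for p in out.patients for _, v in p.feature_obs["age"]]
        assert min(vals) == pytest.approx(0.0)
        assert max(vals) == pytest.approx(1.0)
        assert out.normalized

    def test_blasts_divided_by_100(self, small_cohort):
        out, _ = normalize_cohort(small_cohort)
        for p, q in zip(small_cohort.patients, out.patients):
            for (t0, v0), (t1, v1) in zip(p.blast_obs, q.blast_obs):
                assert t1 == t0
                assert v1 == pytest.approx(v0 / BLAST_SCALE)

    def test_binary_untouched(self, small_cohort):
        out, _ = normalize_cohort(small_cohort)
        for p, q in zip(small_cohort.patients, out.patients):
            assert q.feature_obs["flt3_itd"] == p.feature_obs["flt3_itd"]

    def test_round_trip(self, small_cohort):
        normed, scaling = normalize_cohort(small_cohort)
        back = denormalize_cohort(normed, scaling)
        assert not back.normalized
        for p, q in zip(small_cohort.patients, back.patients):
            for (t0, v0), (t1, v1) in zip(p.feature_obs["age"],
                                          q.feature_obs["age"]):
                assert v1 == pytest.approx(v0, abs=1e-12)
            for (_, v0), (_, v1) in zip(p.blast_obs, q.blast_obs):
                assert v1 == pytest.approx(v0, abs=1e-10)

    def test_double_normalization_rejected(self, small_cohort):
        normed, _ = normalize_cohort(small_cohort)
        with pytest.raises(ValueError):
            normalize_cohort(normed)

    def test_apply_scaling_matches_normalize(self, small_cohort):
        normed, scaling = normalize_cohort(small_cohort)
        again = apply_scaling(small_cohort, scaling)
        for p, q in zip(normed.patients, again.patients):
            assert p.feature_obs == q.feature_obs
            assert p.blast_obs == q.blast_obs
        assert again.normalized

    def test_apply_scaling_foreign_extremes(self, small_cohort):
        # held-out values outside the training extremes map outside [0, 1]
        _, scaling = normalize_cohort(small_cohort)
        lo, hi = scaling.ranges["age"]
        outlier = small_cohort.patients[0].copy()
        outlier.feature_obs["age"] = [(0.0, hi + (hi - lo))]
        foreign = ClinicalCohort([outlier], small_cohort.manifest)
        scaled = apply_scaling(foreign, scaling)
        assert scaled.patients[0].feature_obs["age"][0][1] == pytest.approx(2.0)
        with pytest.raises(ValueError):
            apply_scaling(scaled, scaling)


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------

class TestSplit:
    def _cohort(self, small_manifest, n):
        return ClinicalCohort([_complete_patient(f"p{i}") for i in range(n)],
                              small_manifest)

    def test_sizes(self, small_manifest):
        for n, expected_test in ((245, 25), (20, 2), (5, 1), (9, 1), (15, 2)):
            cohort = self._cohort(small_manifest, n)
            train, test = split_cohort(cohort, 0.10, seed=0)
            assert len(test) == expected_test, n
            assert len(train) == n - expected_test

    def test_disjoint_and_exhaustive(self, small_manifest):
        cohort = self._cohort(small_manifest, 30)
        train, test = split_cohort(cohort, 0.2, seed=3)
        ids_train = {p.patient_id for p in train.patients}
        ids_test = {p.patient_id for p in test.patients}
        assert not (ids_train & ids_test)
        assert ids_train | ids_test == {p.patient_id for p in cohort.patients}

    def test_deterministic(self, small_manifest):
        cohort = self._cohort(small_manifest, 30)
        a = split_cohort(cohort, 0.2, seed=7)
        b = split_cohort(cohort, 0.2, seed=7)
        assert [p.patient_id for p in a[1].patients] == \
               [p.patient_id for p in b[1].patients]

    def test_too_small_raises(self, small_manifest):
        with pytest.raises(ValueError):
            split_cohort(self._cohort(small_manifest, 1))


# ---------------------------------------------------------------------------
# Tidy I/O
# ---------------------------------------------------------------------------

class TestIO:
    def test_round_trip(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        assert len(back) == len(small_cohort)
        for p, q in zip(small_cohort.patients, back.patients):
            assert q.patient_id == p.patient_id
            assert q.blast_obs == p.blast_obs
            assert q.treatments == p.treatments
            assert q.feature_obs == p.feature_obs
        assert back.manifest.entries == small_cohort.manifest.entries
        assert back.provenance == small_cohort.provenance
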