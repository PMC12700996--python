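"""Shared fixtures: small manifests, hand-built models, tiny cohorts."""

import numpy as np
import pytest

from amldyn.curation import (
    ClinicalCohort,
    FeatureEntry,
    FeatureManifest,
    PatientRecord,
)
from amldyn.model_core import (
    GROUP_NECESSARY,
    GROUP_SUFFICIENT,
    Node,
    RegulatoryLink,
    RegulatoryModel,
)


@pytest.fixture
def small_manifest() -> FeatureManifest:
    """Three features covering all dtypes."""
    return FeatureManifest([
        FeatureEntry("age", "patient_info", "continuous"),
        FeatureEntry("flt3_itd", "leukemia_parameter", "binary"),
        FeatureEntry("chemo", "disease_management", "interval"),
    ])


@pytest.fixture
def decay_model() -> RegulatoryModel:
    """Single output node, no regulators: pure exponential decay."""
    return RegulatoryModel(
        nodes=[Node("blast", "output", m=0.1, d=0.05, initial_value=0.8)],
        links=[],
        feature_bindings={},
    )


@pytest.fixture
def activator_model(small_manifest) -> RegulatoryModel:
    """One constant-input activator driving the output."""
    return RegulatoryModel(
        nodes=[
            Node("age", "input"),
            Node("flt3_itd", "input"),
            Node("chemo", "input"),
            Node("blast", "output", m=0.12, d=0.08, initial_value=0.1),
        ],
        links=[
            RegulatoryLink("age", "blast", sign=1, group=GROUP_SUFFICIENT,
                           K=0.4, n=2),
        ],
        feature_bindings={"age": "age", "flt3_itd": "flt3_itd", "chemo": "chemo"},
    )


@pytest.fixture
def two_node_model(small_manifest) -> RegulatoryModel:
    """Input -> hidden -> output chain with mixed groups and signs."""
    return RegulatoryModel(
        nodes=[
            Node("age", "input"),
            Node("flt3_itd", "input"),
            Node("chemo", "input"),
            Node("h1", "hidden", m=0.3, d=0.1, initial_value=0.2),
            Node("blast", "output", m=0.2, d=0.07, initial_value=0.15),
        ],
        links=[
            RegulatoryLink("flt3_itd", "h1", sign=1, group=GROUP_SUFFICIENT,
                           K=0.5, n=1),
            RegulatoryLink("chemo", "blast", sign=-1, group=GROUP_NECESSARY,
                           K=0.3, n=2),
            RegulatoryLink("h1", "blast", sign=1, group=GROUP_SUFFICIENT,
                           K=0.6, n=3),
        ],
        feature_bindings={"age": "age", "flt3_itd": "flt3_itd", "chemo": "chemo"},
    )


def make_patient(pid: str = "p0", t_end: float = 60.0) -> PatientRecord:
    """A simple complete patient over [0, t_end]."""
    return PatientRecord(
        patient_id=pid,
        feature_obs={
            "age": [(0.0, 0.5), (t_end, 0.6)],
            "flt3_itd": [(0.0, 1.0)],
        },
        treatments=[("chemo", 10.0, 20.0)],
        blast_obs=[(0.0, 30.0), (t_end / 2, 40.0), (t_end, 50.0)],
    )


@pytest.fixture
def small_patient() -> PatientRecord:
    return make_patient()


@pytest.fixture
def small_cohort(small_manifest) -> ClinicalCohort:
    patients = [make_patient(f"p{i}") for i in range(3)]
    # vary the records a little so normalization has a nontrivial range
    patients[1].feature_obs["age"] = [(0.0, 0.3), (60.0, 0.4)]
    patients[1].blast_obs = [(0.0, 10.0), (30.0, 20.0), (60.0, 15.0)]
    patients[2].feature_obs["age"] = [(0.0, 0.9)]
    patients[2].blast_obs = [(0.0, 60.0), (60.0, 80.0)]
    return ClinicalCohort(patients, small_manifest, provenance=["test fixture"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
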