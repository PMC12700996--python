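"""Synthetic longitudinal cohorts from known ground-truth regulatory models.

The generator emulates the structure of a curated AML clinical dataset:
mixed continuous/binary clinical features, treatment exposure windows,
and irregular blast-percentage observations produced by simulating a known
ground-truth ODE network plus observation noise.  Because the true model is
known, every downstream stage (curation, simulation, inference, evaluation)
can be tested for recovery against ground truth without any external data.

Conventions:

* All event times (feature knots, treatment window edges, blast observation
  days) are whole days, mirroring dated clinical records.
* Feature values are in natural units (age in years, BMI in kg/m^2, ...).
  Before the ground-truth model is simulated, the cohort is min-max
  normalized exactly as :func:`amldyn.curation.normalize_cohort` does, so
  the documented curate -> normalize -> infer pipeline sees the same signals
  that generated the data, and the zero-noise cohort fitness of the ground
  truth model vanishes.
* Feature observations are emitted at the trajectory knot times, so linear
  interpolation of the observations reconstructs the generating trajectory
  exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .curation import (
    ClinicalCohort,
    FeatureEntry,
    FeatureManifest,
    FeatureTrajectory,
    PatientRecord,
    interpolate_feature,
    normalize_cohort,
    treatment_to_signal,
)
from .model_core import (
    Node,
    RegulatoryLink,
    RegulatoryModel,
    validate_model,
)
from . import simulator

__all__ = [
    "FeatureManifest",
    "FeatureEntry",
    "GroundTruthSpec",
    "default_manifest",
    "make_ground_truth_model",
    "generate_patient_inputs",
    "generate_cohort",
    "inject_defects",
    "DEFECT_KINDS",
]

#: natural-unit value ranges for continuous features, keyed by name fragment
FEATURE_RANGES = {
    "age": (20.0, 85.0),   # years
    "bmi": (15.0, 45.0),   # kg/m^2
    "ecog": (0.0, 4.0),    # performance-status scale
}
DEFAULT_CONTINUOUS_RANGE = (0.0, 1.0)

#: ground-truth parameter priors (normalized units, rates per day): chosen to
#: put the dynamics on the weeks-to-months scale of clinical follow-up.
#: Production is sampled as gain * degradation with gain = m/d <= 1, so every
#: node's steady state stays inside [0, 1] and the simulated blast fraction
#: never leaves the measurable range.
K_RANGE = (0.1, 0.9)
D_RANGE = (0.01, 0.2)
GAIN_RANGE = (0.4, 1.0)  # m / d

OUTPUT_NODE_ID = "blast"


@dataclass
class GroundTruthSpec:
    """Study conditions for one synthetic cohort.

    ``n_drivers`` inputs are truly wired to the output; ``n_decoys`` inputs
    exist but have no path to it; ``n_hidden`` intermediate nodes sit between
    drivers and output.  ``noise_sd`` is the observation noise on blast
    percentages (percentage points); blast observations are spaced as a
    renewal process with mean ``obs_interval_days`` (minimum 7 days).
    """

    n_drivers: int = 1
    n_decoys: int = 9
    n_hidden: int = 0
    noise_sd: float = 2.0
    duration_days: float = 365.0
    obs_interval_days: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_drivers < 1:
            raise ValueError("n_drivers must be >= 1")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        if self.n_hidden < 0:
            raise ValueError("n_hidden must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be > 0")


def default_manifest() -> FeatureManifest:
    """A small manifest mirroring the three clinical feature categories."""
    entries = [
        FeatureEntry("age", "patient_info", "continuous"),
        FeatureEntry("bmi", "patient_info", "continuous"),
        FeatureEntry("ecog", "patient_info", "continuous"),
        FeatureEntry("flt3_itd", "leukemia_parameter", "binary"),
        FeatureEntry("npm1", "leukemia_parameter", "binary"),
        FeatureEntry("dnmt3a", "leukemia_parameter", "binary"),
        FeatureEntry("tp53", "leukemia_parameter", "binary"),
        FeatureEntry("cytogenetic_abnormality", "leukemia_parameter", "binary"),
        FeatureEntry("ara_c", "disease_management", "interval"),
        FeatureEntry("hma", "disease_management", "interval"),
        FeatureEntry("consolidation", "disease_management", "interval"),
    ]
    return FeatureManifest(entries)


def _continuous_range(name: str) -> tuple[float, float]:
    for frag, rng in FEATURE_RANGES.items():
        if frag in name.lower():
            return rng
    return DEFAULT_CONTINUOUS_RANGE


def _ordered_candidates(manifest: FeatureManifest) -> list[str]:
    """Driver/decoy assignment order: interval, then continuous, then binary.

    Treatment-exposure signals switch on and off within each patient's
    history, so they make the most informative drivers; the order is
    deterministic given the manifest.
    """
    order = []
    for dtype in ("interval", "continuous", "binary"):
        order.extend(e.name for e in manifest.entries if e.dtype == dtype)
    return order


# ---------------------------------------------------------------------------
# Ground-truth model construction
# ---------------------------------------------------------------------------

def make_ground_truth_model(
    manifest: FeatureManifest, spec: GroundTruthSpec
) -> RegulatoryModel:
    """Build a valid ground-truth model with known drivers and decoys.

    Exactly ``spec.n_drivers`` input nodes have a directed path to the
    output (through a chain of ``spec.n_hidden`` intermediate nodes when
    present); ``spec.n_decoys`` inputs are left unwired.  Parameters are
    drawn from the documented priors using ``spec.seed``.
    """
    n_inputs = spec.n_drivers + spec.n_decoys
    candidates = _ordered_candidates(manifest)
    if len(candidates) < n_inputs:
        raise ValueError(
            f"manifest has {len(candidates)} features, need {n_inputs} "
            "(n_drivers + n_decoys)"
        )
    rng = np.random.default_rng(spec.seed)
    drivers = candidates[: spec.n_drivers]
    decoys = candidates[spec.n_drivers : n_inputs]

    nodes: list[Node] = []
    bindings: dict[str, str] = {}
    for feat in drivers + decoys:
        nodes.append(Node(feat, "input"))
        bindings[feat] = feat
    def sample_kinetics() -> tuple[float, float]:
        d = float(rng.uniform(*D_RANGE))
        m = d * float(rng.uniform(*GAIN_RANGE))
        return m, d

    hidden_ids = [f"h{i + 1}" for i in range(spec.n_hidden)]
    for hid in hidden_ids:
        m, d = sample_kinetics()
        nodes.append(Node(hid, "hidden", m=m, d=d,
                          initial_value=float(rng.uniform(0.0, 1.0))))
    m, d = sample_kinetics()
    nodes.append(Node(OUTPUT_NODE_ID, "output", m=m, d=d,
                      initial_value=float(rng.uniform(0.1, 0.6))))

    def sample_link(source: str, target: str) -> RegulatoryLink:
        return RegulatoryLink(
            source, target,
            sign=int(rng.choice([1, -1])),
            group=str(rng.choice(["necessary", "sufficient"])),
            K=float(rng.uniform(*K_RANGE)),
            n=int(rng.choice([1, 2, 3, 4])),
        )

    links: list[RegulatoryLink] = []
    chain = hidden_ids + [OUTPUT_NODE_ID]
    for a, b in zip(chain[:-1], chain[1:]):
        links.append(sample_link(a, b))
    for j, feat in enumerate(drivers):
        target = hidden_ids[j % len(hidden_ids)] if hidden_ids else OUTPUT_NODE_ID
        links.append(sample_link(feat, target))

    model = RegulatoryModel(nodes, links, bindings)
    violations = validate_model(model, manifest)
    if violations:  # pragma: no cover - construction guarantees validity
        raise AssertionError("ground-truth model invalid: " + "; ".join(violations))
    return model


# ---------------------------------------------------------------------------
# Patient input sampling
# ---------------------------------------------------------------------------

def _sample_patient_data(
    manifest: FeatureManifest, duration_days: float, rng: np.random.Generator
) -> tuple[dict[str, list[tuple[float, float]]], list[tuple[str, float, float]]]:
    """Sample raw feature observations (at knot days) and treatment windows."""
    duration = float(math.floor(duration_days))
    feature_obs: dict[str, list[tuple[float, float]]] = {}
    treatments: list[tuple[str, float, float]] = []
    interval_features = manifest.by_dtype("interval")
    for entry in manifest.entries:
        if entry.dtype == "continuous":
            lo, hi = _continuous_range(entry.name)
            if "age" in entry.name.lower():
                start = float(rng.uniform(lo, hi - duration / 365.25))
                feature_obs[entry.name] = [
                    (0.0, start), (duration, start + duration / 365.25)
                ]
            else:
                n_knots = int(rng.integers(3, 7))
                inner = np.sort(rng.choice(
                    np.arange(1, int(duration)), size=n_knots - 2, replace=False
                )).astype(float) if duration > n_knots else np.array([])
                times = np.concatenate(([0.0], inner, [duration]))
                values = rng.uniform(lo, hi, size=times.size)
                feature_obs[entry.name] = list(zip(times.tolist(), values.tolist()))
        elif entry.dtype == "binary":
            obs = [(0.0, 0.0)]
            if rng.random() < 0.4:
                onset = float(rng.integers(1, int(duration)))
                obs.append((onset, 1.0))
            feature_obs[entry.name] = obs
        else:  # interval
            n_win = int(rng.choice([0, 1, 2], p=[0.4, 0.45, 0.15]))
            start_free = 0.0
            for _ in range(n_win):
                s = float(rng.integers(int(start_free), max(int(start_free) + 1,
                                                            int(0.7 * duration))))
                length = float(rng.integers(14, 121))
                e = min(s + length, duration)
                if e > s:
                    treatments.append((entry.name, s, e))
                    start_free = e + 14
                if start_free >= 0.7 * duration:
                    break
    # every synthetic patient is treated at least once (AML patients in a
    # clean cohort all carry treatment records)
    if interval_features and not treatments:
        name = interval_features[0]
        s = float(rng.integers(0, max(1, int(0.5 * duration))))
        e = min(s + float(rng.integers(14, 121)), duration)
        treatments.append((name, s, max(e, s + 7.0)))
    return feature_obs, treatments


def generate_patient_inputs(
    manifest: FeatureManifest, duration_days: float, rng: np.random.Generator
) -> dict[str, FeatureTrajectory]:
    """Sample one patient's continuous-time input signals.

    Continuous features are piecewise linear (age strictly increasing),
    binary features are 0/1 steps with a sampled (or absent) onset day, and
    interval features are treatment-window indicators.
    """
    if duration_days <= 0:
        raise ValueError("duration_days must be > 0")
    feature_obs, treatments = _sample_patient_data(manifest, duration_days, rng)
    trajs: dict[str, FeatureTrajectory] = {}
    for entry in manifest.entries:
        if entry.dtype == "interval":
            ivs = [(s, e) for name, s, e in treatments if name == entry.name]
            trajs[entry.name] = treatment_to_signal(ivs, (0.0, float(duration_days)))
        else:
            trajs[entry.name] = interpolate_feature(feature_obs[entry.name], entry.dtype)
    return trajs


def _blast_obs_times(
    duration: float, mean_interval: float, rng: np.random.Generator
) -> np.ndarray:
    """Renewal observation schedule: exponential spacing, >= 7 days, day 0 first.

    The end of follow-up is always observed, so every patient has at least
    two blast observations (a trajectory needs two points, and curation
    would otherwise exclude the patient).
    """
    times = [0.0]
    t = 0.0
    while True:
        gap = max(7.0, round(rng.exponential(mean_interval)))
        t += gap
        if t > duration - 1.0:
            break
        times.append(t)
    times.append(float(math.floor(duration)))
    return np.array(times)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    gt_model: RegulatoryModel,
    manifest: FeatureManifest,
    spec: GroundTruthSpec,
    n_patients: int,
    dt: float = simulator.DEFAULT_DT,
) -> ClinicalCohort:
    """Sample a full synthetic cohort from a ground-truth model.

    For each patient, input signals are sampled, the ground-truth model is
    simulated on the min-max-normalized signals, and blast observations are
    taken at irregular times with additive Gaussian noise (sd =
    ``spec.noise_sd`` percentage points) clipped to [0, 100].  The noiseless
    latent blast trajectory is kept on each record in the test-only
    ``latent_blast`` field.
    """
    violations = validate_model(gt_model, manifest)
    if violations:
        raise ValueError("ground-truth model invalid for manifest: "
                         + "; ".join(violations))
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(spec.seed)
    duration = float(math.floor(spec.duration_days))

    # pass 1: sample all inputs and observation schedules
    patients: list[PatientRecord] = []
    schedules: list[np.ndarray] = []
    for i in range(n_patients):
        feature_obs, treatments = _sample_patient_data(manifest, duration, rng)
        patients.append(PatientRecord(f"P{i:04d}", feature_obs, treatments, []))
        schedules.append(_blast_obs_times(duration, spec.obs_interval_days, rng))

    raw = ClinicalCohort(patients, FeatureManifest(list(manifest.entries)),
                         provenance=[f"generate_cohort: n={n_patients}, seed={spec.seed}"])
    normalized, _scaling = normalize_cohort(raw)

    # pass 2: simulate the ground truth on the normalized signals
    for i, (norm_p, raw_p) in enumerate(zip(normalized.patients, raw.patients)):
        try:
            result = simulator.simulate_patient(
                gt_model, norm_p, manifest, dt=dt,
                init_output_from_obs=False, t_end=duration, normalized=True,
            )
        except simulator.SimulationError as exc:
            raise simulator.SimulationError(
                f"ground-truth simulation failed for patient index {i}: {exc}"
            ) from exc
        latent_pct = result.output * 100.0
        obs_t = schedules[i]
        latent_at_obs = np.interp(obs_t, result.time_grid, latent_pct)
        noise = rng.normal(0.0, spec.noise_sd, size=obs_t.size) if spec.noise_sd > 0 \
            else np.zeros(obs_t.size)
        values = np.clip(latent_at_obs + noise, 0.0, 100.0)
        raw_p.blast_obs = list(zip(obs_t.tolist(), values.tolist()))
        raw_p.latent_blast = FeatureTrajectory(
            "piecewise_linear", result.time_grid, latent_pct, (0.0, duration)
        )
    return raw


# ---------------------------------------------------------------------------
# Defect injection
# ---------------------------------------------------------------------------

DEFECT_KINDS = (
    "missing_treatments",
    "inconsistent_treatment_dates",
    "missing_mutations",
    "insufficient_blasts",
)


def inject_defects(
    cohort: ClinicalCohort,
    defect_spec: dict[str, int],
    rng: np.random.Generator,
) -> ClinicalCohort:
    """Corrupt exactly the requested numbers of distinct patients per defect.

    Defects mirror the curation exclusion rules: empty treatment table,
    a treatment interval with end < start, no mutation-category
    observations, fewer than two blast observations.  No patient receives
    more than one defect; requesting more defects than patients raises.
    """
    unknown = set(defect_spec) - set(DEFECT_KINDS)
    if unknown:
        raise ValueError(f"unknown defect kinds: {sorted(unknown)}")
    total = sum(defect_spec.values())
    if total > len(cohort.patients):
        raise ValueError(
            f"requested {total} defective patients but cohort has {len(cohort.patients)}"
        )
    out = cohort.copy()
    order = rng.permutation(len(out.patients))
    pos = 0
    mutation_features = [
        f for f in out.manifest.by_category("leukemia_parameter")
        if out.manifest.dtype_of(f) != "interval"
    ]
    interval_features = out.manifest.by_dtype("interval")
    log_lines = []
    for kind in DEFECT_KINDS:  # deterministic order
        count = defect_spec.get(kind, 0)
        for _ in range(count):
            p = out.patients[int(order[pos])]
            pos += 1
            if kind == "missing_treatments":
                p.treatments = []
            elif kind == "inconsistent_treatment_dates":
                if p.treatments:
                    name, s, e = p.treatments[0]
                    p.treatments[0] = (name, max(s, e) + 10.0, min(s, e))
                else:
                    name = interval_features[0]
                    p.treatments = [(name, 20.0, 5.0)]
            elif kind == "missing_mutations":
                for f in mutation_features:
                    p.feature_obs.pop(f, None)
            else:  # insufficient_blasts
                p.blast_obs = p.blast_obs[:1]
            log_lines.append(f"inject_defects: {kind} -> {p.patient_id}")
    out.provenance.extend(log_lines)
    return out
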