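"""Clinical-cohort data types, filtration, interpolation and splitting.

Longitudinal cohorts are tidy collections of per-patient time-stamped
feature observations (continuous and binary), treatment intervals, and
blast-percentage observations.  This module implements the curation stages
that precede model inference: rule-based patient/feature filtration with an
exclusion log, conversion of discrete observations into continuous-time
trajectories (linear interpolation for continuous features, zero-order hold
for binary ones, interval indicators for treatments), min-max normalization,
time-averaged (AUC/duration) summaries, and the random train/test split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureManifest",
    "FeatureEntry",
    "FeatureTrajectory",
    "PatientRecord",
    "ClinicalCohort",
    "ExclusionLog",
    "ScalingMap",
    "filter_patients",
    "filter_features",
    "interpolate_feature",
    "treatment_to_signal",
    "normalize_cohort",
    "denormalize_cohort",
    "auc_over_duration",
    "split_cohort",
    "write_cohort",
    "read_cohort",
]

CATEGORIES = ("patient_info", "leukemia_parameter", "disease_management")
DTYPES = ("continuous", "binary", "interval")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureEntry:
    name: str
    category: str
    dtype: str


@dataclass
class FeatureManifest:
    """Declares every clinical feature: its category and data type.

    Categories follow the three groups of the curated AML dataset (patient
    information, leukemia parameters, disease management); ``interval``
    features (treatment exposure windows) are only allowed in the
    disease-management category.
    """

    entries: list[FeatureEntry]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        for e in self.entries:
            if e.category not in CATEGORIES:
                raise ValueError(f"feature {e.name}: unknown category {e.category!r}")
            if e.dtype not in DTYPES:
                raise ValueError(f"feature {e.name}: unknown dtype {e.dtype!r}")
            if e.dtype == "interval" and e.category != "disease_management":
                raise ValueError(
                    f"feature {e.name}: interval dtype is only allowed for "
                    "disease_management features"
                )

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def entry(self, name: str) -> FeatureEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def dtype_of(self, name: str) -> str:
        return self.entry(name).dtype

    def category_of(self, name: str) -> str:
        return self.entry(name).category

    def by_dtype(self, dtype: str) -> list[str]:
        return [e.name for e in self.entries if e.dtype == dtype]

    def by_category(self, category: str) -> list[str]:
        return [e.name for e in self.entries if e.category == category]

    @property
    def observed_features(self) -> list[str]:
        """Features recorded as time-stamped observations (not intervals)."""
        return [e.name for e in self.entries if e.dtype != "interval"]

    def subset(self, keep: Iterable[str]) -> "FeatureManifest":
        keep = set(keep)
        return FeatureManifest([e for e in self.entries if e.name in keep])

    # -- I/O ---------------------------------------------------------------
    def to_yaml(self, path) -> None:
        data = {"features": [{"name": e.name, "category": e.category, "dtype": e.dtype}
                             for e in self.entries]}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureManifest":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls([FeatureEntry(d["name"], d["category"], d["dtype"])
                    for d in data["features"]])


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class FeatureTrajectory:
    """Continuous-time signal built from discrete observations.

    ``piecewise_linear`` interpolates linearly between knots;
    ``step`` holds the last observed value (zero-order hold).
    Outside ``domain`` the first/last value is extended as a constant.
    """

    kind: str  # "piecewise_linear" | "step"
    times: np.ndarray
    values: np.ndarray
    domain: tuple[float, float]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("piecewise_linear", "step"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.times.size == 0:
            raise ValueError("trajectory needs at least one knot")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("knot times must be strictly increasing")
        if self.domain[1] < self.domain[0]:
            raise ValueError("empty trajectory domain")

    @property
    def knots(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.values.tolist()))

    def evaluate(self, t) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        if self.kind == "piecewise_linear":
            out = np.interp(t_arr, self.times, self.values)
        else:
            # zero-order hold: value of the last knot at or before t
            idx = np.searchsorted(self.times, t_arr, side="right") - 1
            idx = np.clip(idx, 0, self.times.size - 1)
            out = self.values[idx]
        return float(out) if np.isscalar(t) else out

    __call__ = evaluate

    def integral(self) -> float:
        """Exact integral over the trajectory's domain."""
        t0, t1 = self.domain
        # breakpoints: domain ends plus knots inside the domain
        inside = self.times[(self.times > t0) & (self.times < t1)]
        pts = np.concatenate(([t0], inside, [t1]))
        if self.kind == "piecewise_linear":
            vals = self.evaluate(pts)
            return float(np.trapezoid(vals, pts))
        total = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            total += float(self.evaluate(a)) * (b - a)
        return total


def interpolate_feature(
    obs: Sequence[tuple[float, float]], dtype: str
) -> FeatureTrajectory:
    """Turn discrete observations into a continuous trajectory.

    Continuous features are linearly interpolated; binary features (mutation
    or cytogenetic statuses, which are not fractionally present between
    tests) use a zero-order hold.  The trajectory passes exactly through
    every observation.
    """
    if len(obs) == 0:
        raise ValueError("cannot interpolate an empty observation list")
    times = np.array([t for t, _ in obs], dtype=float)
    values = np.array([v for _, v in obs], dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("observation times must be strictly increasing")
    if dtype == "continuous":
        kind = "piecewise_linear"
    elif dtype == "binary":
        kind = "step"
    else:
        raise ValueError(f"cannot interpolate dtype {dtype!r}")
    return FeatureTrajectory(kind, times, values, (float(times[0]), float(times[-1])))


def treatment_to_signal(
    intervals: Sequence[tuple[float, float]], domain: tuple[float, float]
) -> FeatureTrajectory:
    """Indicator signal: 1 inside any (closed) treatment interval, else 0.

    Overlapping intervals are merged.  An inconsistent interval
    (end < start) raises, naming the interval — the same condition is a
    patient-exclusion rule in :func:`filter_patients`.
    """
    for iv in intervals:
        if iv[1] < iv[0]:
            raise ValueError(f"inconsistent treatment interval (end < start): {iv}")
    t0, t1 = float(domain[0]), float(domain[1])
    if not intervals:
        return FeatureTrajectory("step", np.array([t0]), np.array([0.0]), (t0, t1))
    merged: list[list[float]] = []
    for s, e in sorted((float(s), float(e)) for s, e in intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    times: list[float] = []
    values: list[float] = []

    def add(t: float, v: float) -> None:
        if times and t <= times[-1]:
            # closed-interval edge collision: keep "on" at the shared instant
            values[-1] = max(values[-1], v)
            return
        times.append(t)
        values.append(v)

    if merged[0][0] > t0:
        add(t0, 0.0)
    for s, e in merged:
        add(s, 1.0)
        # switch off just after the closed right endpoint
        add(np.nextafter(e, np.inf), 0.0)
    traj = FeatureTrajectory("step", np.array(times), np.array(values), (t0, t1))
    return traj


def auc_over_duration(traj: FeatureTrajectory) -> float:
    """Time-averaged trajectory value: integral over domain / domain length."""
    length = traj.domain[1] - traj.domain[0]
    if length <= 0:
        raise ValueError("auc_over_duration requires a domain of positive length")
    return traj.integral() / length


# ---------------------------------------------------------------------------
# Patient records and cohorts
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """One patient's longitudinal record.

    ``feature_obs`` maps feature name -> [(time_days, value), ...];
    ``treatments`` is [(treatment_name, start_day, end_day), ...];
    ``blast_obs`` is [(time_days, blast_pct), ...].

    ``latent_blast`` is a TEST-ONLY field: the noiseless simulated blast
    trajectory (in percent) a synthetic generator produced this patient
    from.  It is never read by curation, inference, or evaluation.
    """

    patient_id: str
    feature_obs: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    treatments: list[tuple[str, float, float]] = field(default_factory=list)
    blast_obs: list[tuple[float, float]] = field(default_factory=list)
    latent_blast: FeatureTrajectory | None = None

    def last_blast_time(self) -> float:
        if not self.blast_obs:
            raise ValueError(f"patient {self.patient_id} has no blast observations")
        return max(t for t, _ in self.blast_obs)

    def copy(self) -> "PatientRecord":
        return PatientRecord(
            self.patient_id,
            {k: list(v) for k, v in self.feature_obs.items()},
            list(self.treatments),
            list(self.blast_obs),
            self.latent_blast,
        )


@dataclass
class ClinicalCohort:
    """A set of patients plus the feature manifest and a provenance log."""

    patients: list[PatientRecord]
    manifest: FeatureManifest
    provenance: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")
        names = set(self.manifest.names())
        treatment_features = set(self.manifest.by_dtype("interval"))
        for p in self.patients:
            unknown = set(p.feature_obs) - names
            if unknown:
                raise ValueError(
                    f"patient {p.patient_id} references features not in manifest: "
                    f"{sorted(unknown)}"
                )
            unknown_t = {t for t, _, _ in p.treatments} - treatment_features
            if unknown_t:
                raise ValueError(
                    f"patient {p.patient_id} references treatments not in manifest: "
                    f"{sorted(unknown_t)}"
                )

    def __len__(self) -> int:
        return len(self.patients)

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def copy(self) -> "ClinicalCohort":
        return ClinicalCohort(
            [p.copy() for p in self.patients],
            FeatureManifest(list(self.manifest.entries)),
            list(self.provenance),
            self.normalized,
        )


@dataclass
class ExclusionLog:
    """Audit log of removed patients/features: (subject, rule, detail)."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, subject: str, rule: str, detail: str) -> None:
        self.entries.append((subject, rule, detail))

    def subjects(self) -> list[str]:
        return [s for s, _, _ in self.entries]

    def rules(self) -> list[str]:
        return [r for _, r, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["id", "rule", "detail"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtration
# ---------------------------------------------------------------------------

#: patient exclusion rules, applied in this order; a patient is logged under
#: the first rule it matches
PATIENT_RULES = (
    "missing_treatments",
    "inconsistent_treatment_dates",
    "missing_mutations",
    "insufficient_blasts",
)


def _first_matching_rule(
    patient: PatientRecord, mutation_features: set[str], min_blast_obs: int
) -> tuple[str, str] | None:
    if not patient.treatments:
        return "missing_treatments", "empty treatment table"
    bad = [(n, s, e) for n, s, e in patient.treatments if e < s]
    if bad:
        n, s, e = bad[0]
        return "inconsistent_treatment_dates", f"{n}: end {e} < start {s}"
    has_mutation_obs = any(
        patient.feature_obs.get(f) for f in mutation_features
    )
    if mutation_features and not has_mutation_obs:
        return "missing_mutations", "no mutation-category observations"
    if len(patient.blast_obs) < min_blast_obs:
        return "insufficient_blasts", (
            f"{len(patient.blast_obs)} blast observations < {min_blast_obs}"
        )
    return None


def filter_patients(
    cohort: ClinicalCohort, min_blast_obs: int = 2
) -> tuple[ClinicalCohort, ExclusionLog]:
    """Remove patients with missing/inconsistent records.

    Rules, in order: empty treatment table; any treatment end day before its
    start day; no observations for any leukemia-parameter (mutation/
    cytogenetic) feature; fewer than ``min_blast_obs`` blast observations.
    Each removed patient is logged once, under the first matching rule.
    """
    if min_blast_obs < 2:
        raise ValueError("min_blast_obs must be >= 2 (a trajectory needs two points)")
    mutation_features = set(cohort.manifest.by_category("leukemia_parameter")) & set(
        cohort.manifest.observed_features
    )
    log = ExclusionLog()
    kept: list[PatientRecord] = []
    for p in cohort.patients:
        match = _first_matching_rule(p, mutation_features, min_blast_obs)
        if match is None:
            kept.append(p.copy())
        else:
            rule, detail = match
            log.add(p.patient_id, rule, detail)
    out = ClinicalCohort(
        kept,
        FeatureManifest(list(cohort.manifest.entries)),
        cohort.provenance + [
            f"filter_patients: kept {len(kept)}/{len(cohort.patients)} "
            f"(min_blast_obs={min_blast_obs})"
        ],
        cohort.normalized,
    )
    return out, log


def filter_features(
    cohort: ClinicalCohort,
    min_prevalence: float = 0.05,
    min_variance: float = 1e-12,
) -> tuple[ClinicalCohort, ExclusionLog]:
    """Remove uninformative features.

    Binary features positive in fewer than ``min_prevalence`` of patients
    are dropped; continuous features whose per-patient means have variance
    below ``min_variance`` are dropped.  Interval (treatment) features are
    kept.  Removing every feature raises (inference would have no inputs).
    """
    if not (0.0 <= min_prevalence < 1.0):
        raise ValueError("min_prevalence must be in [0, 1)")
    if min_variance < 0:
        raise ValueError("min_variance must be >= 0")
    n_pat = len(cohort.patients)
    log = ExclusionLog()
    removed: set[str] = set()
    for entry in cohort.manifest.entries:
        if entry.dtype == "binary":
            n_pos = sum(
                1 for p in cohort.patients
                if any(v > 0 for _, v in p.feature_obs.get(entry.name, []))
            )
            prev = n_pos / n_pat if n_pat else 0.0
            if prev < min_prevalence:
                removed.add(entry.name)
                log.add(entry.name, "low_prevalence",
                        f"positive in {n_pos}/{n_pat} patients")
        elif entry.dtype == "continuous":
            means = [
                float(np.mean([v for _, v in p.feature_obs[entry.name]]))
                for p in cohort.patients
                if p.feature_obs.get(entry.name)
            ]
            var = float(np.var(means)) if len(means) > 1 else 0.0
            if var < min_variance:
                removed.add(entry.name)
                log.add(entry.name, "low_variance",
                        f"variance of per-patient means {var:.3g}")
    keep = [n for n in cohort.manifest.names() if n not in removed]
    if not keep:
        raise ValueError("feature filtration removed every feature")
    new_manifest = cohort.manifest.subset(keep)
    patients = []
    for p in cohort.patients:
        q = p.copy()
        q.feature_obs = {k: v for k, v in q.feature_obs.items() if k not in removed}
        patients.append(q)
    out = ClinicalCohort(
        patients, new_manifest,
        cohort.provenance + [
            f"filter_features: kept {len(keep)}/{len(cohort.manifest.entries)} features"
        ],
        cohort.normalized,
    )
    return out, log


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

BLAST_SCALE = 100.0


@dataclass
class ScalingMap:
    """Invertible per-feature min-max scaling (continuous features only)."""

    ranges: dict[str, tuple[float, float]]
    blast_scale: float = BLAST_SCALE

    def normalize_value(self, feature: str, value: float) -> float:
        lo, hi = self.ranges[feature]
        return (value - lo) / (hi - lo)

    def denormalize_value(self, feature: str, value: float) -> float:
        lo, hi = self.ranges[feature]
        return lo + value * (hi - lo)


def normalize_cohort(cohort: ClinicalCohort) -> tuple[ClinicalCohort, ScalingMap]:
    """Min-max scale continuous features to [0, 1] and blasts to [0, 1].

    Scaling uses cohort-wide extremes; binary and interval features are
    untouched.  A continuous feature with zero range raises (it should have
    been removed by :func:`filter_features`).
    """
    if cohort.normalized:
        raise ValueError("cohort is already normalized")
    ranges: dict[str, tuple[float, float]] = {}
    for name in cohort.manifest.by_dtype("continuous"):
        values = [
            v for p in cohort.patients for _, v in p.feature_obs.get(name, [])
        ]
        if not values:
            continue
        lo, hi = float(min(values)), float(max(values))
        if hi <= lo:
            raise ValueError(
                f"continuous feature {name!r} has zero range; run filter_features first"
            )
        ranges[name] = (lo, hi)
    scaling = ScalingMap(ranges)
    return apply_scaling(cohort, scaling), scaling


def apply_scaling(cohort: ClinicalCohort, scaling: ScalingMap) -> ClinicalCohort:
    """Normalize a raw cohort with a pre-computed scaling map.

    This is how held-out patients must be scored: their features are scaled
    by the *training* cohort's extremes, so normalized values can fall
    slightly outside [0, 1] (negative values are clipped to 0 during
    simulation).
    """
    if cohort.normalized:
        raise ValueError("cohort is already normalized")
    patients = []
    for p in cohort.patients:
        q = p.copy()
        for name, obs in q.feature_obs.items():
            if name in scaling.ranges:
                q.feature_obs[name] = [
                    (t, scaling.normalize_value(name, v)) for t, v in obs
                ]
        q.blast_obs = [(t, v / scaling.blast_scale) for t, v in q.blast_obs]
        patients.append(q)
    return ClinicalCohort(
        patients, FeatureManifest(list(cohort.manifest.entries)),
        cohort.provenance + ["apply_scaling: min-max features, blasts / 100"],
        normalized=True,
    )


def denormalize_cohort(cohort: ClinicalCohort, scaling: ScalingMap) -> ClinicalCohort:
    """Inverse of :func:`normalize_cohort`."""
    if not cohort.normalized:
        raise ValueError("cohort is not normalized")
    patients = []
    for p in cohort.patients:
        q = p.copy()
        for name, obs in q.feature_obs.items():
            if name in scaling.ranges:
                q.feature_obs[name] = [
                    (t, scaling.denormalize_value(name, v)) for t, v in obs
                ]
        q.blast_obs = [(t, v * scaling.blast_scale) for t, v in q.blast_obs]
        patients.append(q)
    return ClinicalCohort(
        patients, FeatureManifest(list(cohort.manifest.entries)),
        cohort.provenance + ["denormalize_cohort"], normalized=False,
    )


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def split_cohort(
    cohort: ClinicalCohort, test_fraction: float = 0.10, seed: int = 0
) -> tuple[ClinicalCohort, ClinicalCohort]:
    """Random disjoint, exhaustive train/test partition.

    |test| = max(1, floor(test_fraction * N + 0.5)); deterministic given
    the seed.
    """
    n = len(cohort.patients)
    if n < 2:
        raise ValueError("split_cohort requires at least 2 patients")
    n_test = max(1, math.floor(test_fraction * n + 0.5))
    if n_test >= n:
        raise ValueError("test split would contain the whole cohort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [cohort.patients[i].copy() for i in range(n) if i not in test_idx]
    test = [cohort.patients[i].copy() for i in range(n) if i in test_idx]
    mk = lambda pats, tag: ClinicalCohort(
        pats, FeatureManifest(list(cohort.manifest.entries)),
        cohort.provenance + [f"split_cohort({test_fraction}, seed={seed}): {tag}"],
        cohort.normalized,
    )
    return mk(train, "train"), mk(test, "test")


# ---------------------------------------------------------------------------
# Tidy CSV I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: ClinicalCohort, directory) -> None:
    """Write the cohort as tidy CSV tables plus a YAML manifest.

    Files: observations.csv (patient_id, feature, time_days, value),
    treatments.csv (patient_id, treatment, start_day, end_day),
    blasts.csv (patient_id, time_days, blast_pct), manifest.yaml,
    provenance.txt.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    obs_rows, treat_rows, blast_rows = [], [], []
    for p in cohort.patients:
        for feat, obs in p.feature_obs.items():
            for t, v in obs:
                obs_rows.append((p.patient_id, feat, t, v))
        for name, s, e in p.treatments:
            treat_rows.append((p.patient_id, name, s, e))
        for t, v in p.blast_obs:
            blast_rows.append((p.patient_id, t, v))
    pd.DataFrame(obs_rows, columns=["patient_id", "feature", "time_days", "value"]) \
        .to_csv(directory / "observations.csv", index=False)
    pd.DataFrame(treat_rows, columns=["patient_id", "treatment", "start_day", "end_day"]) \
        .to_csv(directory / "treatments.csv", index=False)
    pd.DataFrame(blast_rows, columns=["patient_id", "time_days", "blast_pct"]) \
        .to_csv(directory / "blasts.csv", index=False)
    cohort.manifest.to_yaml(directory / "manifest.yaml")
    (directory / "provenance.txt").write_text(
        "".join(line + "\n" for line in cohort.provenance)
    )


def read_cohort(directory) -> ClinicalCohort:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = FeatureManifest.from_yaml(directory / "manifest.yaml")
    obs = pd.read_csv(directory / "observations.csv")
    treats = pd.read_csv(directory / "treatments.csv")
    blasts = pd.read_csv(directory / "blasts.csv")
    prov_path = directory / "provenance.txt"
    provenance = (
        [l for l in prov_path.read_text().splitlines() if l] if prov_path.exists() else []
    )
    ids: list[str] = []
    for frame in (obs, treats, blasts):
        for pid in frame["patient_id"].astype(str):
            if pid not in ids:
                ids.append(pid)
    patients = []
    for pid in ids:
        feature_obs: dict[str, list[tuple[float, float]]] = {}
        sub = obs[obs["patient_id"].astype(str) == pid]
        for feat, grp in sub.groupby("feature", sort=False):
            grp = grp.sort_values("time_days")
            feature_obs[str(feat)] = list(
                zip(grp["time_days"].astype(float), grp["value"].astype(float))
            )
        sub_t = treats[treats["patient_id"].astype(str) == pid]
        treatments = [
            (str(r.treatment), float(r.start_day), float(r.end_day))
            for r in sub_t.itertuples()
        ]
        sub_b = blasts[blasts["patient_id"].astype(str) == pid].sort_values("time_days")
        blast_obs = list(
            zip(sub_b["time_days"].astype(float), sub_b["blast_pct"].astype(float))
        )
        patients.append(PatientRecord(pid, feature_obs, treatments, blast_obs))
    return ClinicalCohort(patients, manifest, provenance)
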