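"""Model-evaluation metrics and per-patient / cohort reports.

Predictions and observations are compared in blast-percentage units with
five standard longitudinal-fit metrics: RMSE and MAE (percentage points),
R^2 (variance explained about the observation mean), normalized RMSE
(RMSE over the observed range), and MAPE (with a 1-percentage-point floor
on the denominator so remission observations near 0% do not blow up the
ratio).  Cohort-level reports pool all (prediction, observation) pairs
rather than averaging per-patient metrics, so every observation carries
equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curation import ClinicalCohort, apply_scaling, normalize_cohort
from .model_core import RegulatoryModel
from .simulator import DEFAULT_DT, SimulationError, simulate_patient

__all__ = ["MetricsReport", "compute_metrics", "evaluate_model", "evaluate_split"]

MAPE_FLOOR = 1.0  # blast-percentage points


@dataclass
class MetricsReport:
    rmse: float
    mae: float
    r2: float
    rmse_n: float
    mape: float
    n_points: int
    scope: str = "patient"
    r2_defined: bool = True
    rmse_n_defined: bool = True
    failed: bool = False
    n_failed_patients: int = 0


def compute_metrics(pred, obs, scope: str = "patient") -> MetricsReport:
    """Standard fit metrics between prediction and observation vectors.

    RMSE = sqrt(mean squared error); MAE = mean absolute error;
    R^2 = 1 - SSE/SStot (flagged undefined when the observations are
    constant); RMSEn = RMSE / (max(obs) - min(obs)) (flagged undefined on a
    zero range); MAPE = mean(|error| / max(|obs|, 1)) with the 1-point
    floor guarding division by near-zero observations.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-D vectors of equal length")
    if pred.size == 0:
        raise ValueError("cannot compute metrics on empty vectors")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot > 0:
        r2 = 1.0 - float(np.sum(err**2)) / sstot
        r2_defined = True
    else:
        r2, r2_defined = float("nan"), False
    obs_range = float(obs.max() - obs.min())
    if obs_range > 0:
        rmse_n = rmse / obs_range
        rmse_n_defined = True
    else:
        rmse_n, rmse_n_defined = float("nan"), False
    mape = float(np.mean(np.abs(err) / np.maximum(np.abs(obs), MAPE_FLOOR)))
    return MetricsReport(rmse, mae, r2, rmse_n, mape, int(pred.size), scope,
                         r2_defined, rmse_n_defined)


def evaluate_model(
    model: RegulatoryModel,
    cohort: ClinicalCohort,
    scope: str = "cohort-train",
    dt: float = DEFAULT_DT,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Per-patient metric reports plus a pooled aggregate, in blast-% units.

    Each patient is simulated over their observation span, the output is
    read off at the observation times, and all (pred, obs) pairs are pooled
    for the aggregate report.  A failed simulation marks that patient's
    report as failed; the aggregate excludes it and records the count.

    Models are defined over normalized feature values; a raw cohort is
    min-max normalized (over its own extremes) before simulation.  To score
    held-out patients with the training cohort's scaling, normalize with
    :func:`amldyn.curation.apply_scaling` first (or use
    :func:`evaluate_split`).
    """
    if not cohort.normalized:
        cohort, _ = normalize_cohort(cohort)
    per_patient: list[MetricsReport] = []
    all_pred: list[np.ndarray] = []
    all_obs: list[np.ndarray] = []
    n_failed = 0
    for patient in cohort.patients:
        obs = sorted(patient.blast_obs)
        t = np.array([o[0] for o in obs])
        v_pct = np.array([o[1] for o in obs]) * (100.0 if cohort.normalized else 1.0)
        try:
            result = simulate_patient(model, patient, cohort.manifest, dt=dt,
                                      normalized=cohort.normalized)
        except SimulationError:
            n_failed += 1
            report = MetricsReport(float("nan"), float("nan"), float("nan"),
                                   float("nan"), float("nan"), len(obs),
                                   scope="patient", r2_defined=False,
                                   rmse_n_defined=False, failed=True)
            per_patient.append(report)
            continue
        pred_pct = np.interp(t, result.time_grid, result.output) * 100.0
        per_patient.append(compute_metrics(pred_pct, v_pct, scope="patient"))
        all_pred.append(pred_pct)
        all_obs.append(v_pct)
    if not all_pred:
        raise SimulationError("every patient simulation failed")
    aggregate = compute_metrics(np.concatenate(all_pred), np.concatenate(all_obs),
                                scope=scope)
    aggregate.n_failed_patients = n_failed
    return per_patient, aggregate


def evaluate_split(
    model: RegulatoryModel,
    train: ClinicalCohort,
    test: ClinicalCohort,
    dt: float = DEFAULT_DT,
) -> dict[str, MetricsReport]:
    """Aggregate reports on the training and held-out test cohorts.

    When given raw cohorts, the test features are scaled by the *training*
    extremes (no information leaks from the held-out set into the scaling).
    """
    if not train.normalized:
        train, scaling = normalize_cohort(train)
        if not test.normalized:
            test = apply_scaling(test, scaling)
    _, train_report = evaluate_model(model, train, scope="cohort-train", dt=dt)
    _, test_report = evaluate_model(model, test, scope="cohort-test", dt=dt)
    return {"train": train_report, "test": test_report}
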