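"""Patient-level simulation and trajectory-fit scoring of regulatory models.

A model is integrated with fixed-step RK4 (default dt = 0.25 day) from
diagnosis (t = 0) to the patient's last blast observation, driven by the
patient's interpolated input trajectories.  The output node is initialized
at the first observed blast value (normalized); hidden nodes start at their
own initial values.  Fit is scored as the RMSE, in normalized [0, 1] blast
units, between observed blasts and the simulated output interpolated to the
observation times; cohort fitness is the unweighted mean over patients,
with a +inf sentinel when any simulation diverges (the candidate is culled
by selection rather than crashing the search).

Step-kind input signals (treatment indicators, mutation statuses) are
sampled right-continuously on the integration grid, so a switch taking
effect at day ``t`` drives the step starting at ``t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import curation
from ._kernel import simulate_batch
from .curation import ClinicalCohort, FeatureManifest, FeatureTrajectory, PatientRecord
from .model_core import (
    ROLE_INPUT,
    GROUP_NECESSARY,
    GROUP_SUFFICIENT,
    RegulatoryModel,
    model_rhs,
    validate_model,
)

__all__ = [
    "SimulationResult",
    "CohortSimData",
    "patient_trajectories",
    "simulate_patient",
    "patient_error",
    "cohort_fitness",
    "reference_simulate",
]

DEFAULT_DT = 0.25  # days


@dataclass
class SimulationResult:
    """Time grid plus per-node trajectories for one patient under one model."""

    patient_id: str
    time_grid: np.ndarray
    states: dict[str, np.ndarray]
    output_id: str

    @property
    def output(self) -> np.ndarray:
        return self.states[self.output_id]


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Trajectory assembly
# ---------------------------------------------------------------------------

def patient_trajectories(
    patient: PatientRecord, manifest: FeatureManifest, t_end: float
) -> dict[str, FeatureTrajectory]:
    """Continuous-time input signals for every manifest feature.

    Continuous/binary features are interpolated from their observations;
    interval features become treatment indicator signals.  A feature with
    no observations for this patient yields a constant-zero signal.
    """
    trajs: dict[str, FeatureTrajectory] = {}
    for entry in manifest.entries:
        if entry.dtype == "interval":
            ivs = [(s, e) for name, s, e in patient.treatments if name == entry.name]
            trajs[entry.name] = curation.treatment_to_signal(ivs, (0.0, t_end))
        else:
            obs = patient.feature_obs.get(entry.name)
            if obs:
                trajs[entry.name] = curation.interpolate_feature(obs, entry.dtype)
            else:
                trajs[entry.name] = FeatureTrajectory(
                    "step", np.array([0.0]), np.array([0.0]), (0.0, t_end)
                )
    return trajs


def _sample_on_half_grid(
    traj: FeatureTrajectory, t_half: np.ndarray
) -> np.ndarray:
    if traj.kind == "step":
        # right-continuous sampling: a switch at t drives the step starting at t
        return traj.evaluate(np.nextafter(t_half, np.inf))
    return traj.evaluate(t_half)


def _sample_left_limits(
    traj: FeatureTrajectory, t_half: np.ndarray
) -> np.ndarray:
    """Left limits, fed to the end-of-step RK4 stage (k4): a switch at t
    must not contaminate the step ending at t."""
    if traj.kind == "step":
        return traj.evaluate(np.nextafter(t_half, -np.inf))
    return traj.evaluate(t_half)


# ---------------------------------------------------------------------------
# Model encoding for the compiled kernel
# ---------------------------------------------------------------------------

@dataclass
class _ModelArrays:
    dyn_ids: list[str]
    out_pos: int
    m: np.ndarray
    d: np.ndarray
    x0: np.ndarray
    link_from_input: np.ndarray
    link_src: np.ndarray
    link_tgt: np.ndarray
    link_sign: np.ndarray
    link_nec: np.ndarray
    link_Kn: np.ndarray
    link_n: np.ndarray
    n_suff: np.ndarray
    n_reg: np.ndarray


def _encode_model(model: RegulatoryModel, feature_index: dict[str, int]) -> _ModelArrays:
    dyn = model.dynamic_nodes
    dyn_ids = [n.node_id for n in dyn]
    dyn_pos = {nid: i for i, nid in enumerate(dyn_ids)}
    out_pos = dyn_pos[model.output_node.node_id]
    roles = {n.node_id: n.role for n in model.nodes}

    n_links = len(model.links)
    from_input = np.zeros(n_links, dtype=np.int8)
    src = np.zeros(n_links, dtype=np.int64)
    tgt = np.zeros(n_links, dtype=np.int64)
    sign = np.zeros(n_links, dtype=np.int8)
    nec = np.zeros(n_links, dtype=np.int8)
    Kn = np.zeros(n_links)
    n_exp = np.zeros(n_links, dtype=np.int64)
    n_suff = np.zeros(len(dyn), dtype=np.int64)
    n_reg = np.zeros(len(dyn), dtype=np.int64)
    for i, link in enumerate(model.links):
        if roles[link.source] == ROLE_INPUT:
            from_input[i] = 1
            src[i] = feature_index[model.feature_bindings[link.source]]
        else:
            src[i] = dyn_pos[link.source]
        tgt[i] = dyn_pos[link.target]
        sign[i] = link.sign
        nec[i] = 1 if link.group == GROUP_NECESSARY else 0
        Kn[i] = link.K ** link.n
        n_exp[i] = int(link.n)
        n_reg[tgt[i]] += 1
        if link.group == GROUP_SUFFICIENT:
            n_suff[tgt[i]] += 1
    return _ModelArrays(
        dyn_ids, out_pos,
        np.array([n.m for n in dyn], dtype=float),
        np.array([n.d for n in dyn], dtype=float),
        np.array([n.initial_value for n in dyn], dtype=float),
        from_input, src, tgt, sign, nec, Kn, n_exp, n_suff, n_reg,
    )


# ---------------------------------------------------------------------------
# Cohort simulation data
# ---------------------------------------------------------------------------

@dataclass
class CohortSimData:
    """Cohort pre-sampled on the RK4 grid, ready for repeated model scoring.

    Built once per cohort; every candidate model evaluated against it reuses
    the sampled input signals and normalized blast observations.
    """

    manifest: FeatureManifest
    patient_ids: list[str]
    feature_index: dict[str, int]
    inputs_half: np.ndarray  # right limits, (n_patients, n_features, 2*max_steps+1)
    inputs_left: np.ndarray  # left limits, same shape
    n_steps: np.ndarray
    dt: float
    obs_times: list[np.ndarray]
    obs_values: list[np.ndarray]  # normalized [0, 1]
    first_obs: np.ndarray

    @classmethod
    def from_cohort(cls, cohort: ClinicalCohort, dt: float = DEFAULT_DT) -> "CohortSimData":
        if dt <= 0:
            raise ValueError("dt must be positive")
        if not cohort.patients:
            raise ValueError("empty cohort")
        blast_scale = 1.0 if cohort.normalized else curation.BLAST_SCALE
        feature_names = cohort.manifest.names()
        feature_index = {name: i for i, name in enumerate(feature_names)}
        n_steps = np.zeros(len(cohort.patients), dtype=np.int64)
        obs_times, obs_values = [], []
        for i, p in enumerate(cohort.patients):
            if not p.blast_obs:
                raise ValueError(f"patient {p.patient_id} has no blast observations")
            obs = sorted(p.blast_obs)
            t = np.array([o[0] for o in obs])
            v = np.array([o[1] for o in obs]) / blast_scale
            obs_times.append(t)
            obs_values.append(v)
            n_steps[i] = max(1, math.ceil(t[-1] / dt - 1e-9))
        max_steps = int(n_steps.max())
        t_half = np.arange(2 * max_steps + 1) * (dt / 2.0)
        inputs_half = np.zeros((len(cohort.patients), len(feature_names), t_half.size))
        inputs_left = np.zeros_like(inputs_half)
        for i, p in enumerate(cohort.patients):
            trajs = patient_trajectories(p, cohort.manifest, float(n_steps[i] * dt))
            for name, j in feature_index.items():
                inputs_half[i, j] = _sample_on_half_grid(trajs[name], t_half)
                inputs_left[i, j] = _sample_left_limits(trajs[name], t_half)
        first_obs = np.array([v[0] for v in obs_values])
        return cls(cohort.manifest, [p.patient_id for p in cohort.patients],
                   feature_index, inputs_half, inputs_left, n_steps, dt,
                   obs_times, obs_values, first_obs)

    def __len__(self) -> int:
        return len(self.patient_ids)


def _run_kernel(arrays: _ModelArrays, sim: CohortSimData, init_states: np.ndarray):
    return simulate_batch(
        arrays.m, arrays.d, init_states,
        arrays.link_from_input, arrays.link_src, arrays.link_tgt,
        arrays.link_sign, arrays.link_nec, arrays.link_Kn, arrays.link_n,
        arrays.n_suff, arrays.n_reg,
        sim.inputs_half, sim.inputs_left, sim.n_steps, sim.dt,
    )


def _init_states(
    arrays: _ModelArrays, sim: CohortSimData, init_output_from_obs: bool
) -> np.ndarray:
    init = np.tile(arrays.x0, (len(sim), 1))
    if init_output_from_obs:
        init[:, arrays.out_pos] = sim.first_obs
    return init


# ---------------------------------------------------------------------------
# Public simulation / scoring API
# ---------------------------------------------------------------------------

def simulate_patient(
    model: RegulatoryModel,
    patient: PatientRecord,
    manifest: FeatureManifest,
    dt: float = DEFAULT_DT,
    init_output_from_obs: bool = True,
    t_end: float | None = None,
    normalized: bool = False,
) -> SimulationResult:
    """Fixed-step RK4 simulation of one model for one patient.

    ``t_end`` defaults to the last blast observation; the output node starts
    at the first observed blast (normalized; set ``normalized=True`` when the
    patient's blasts are already in [0, 1]) unless ``init_output_from_obs``
    is False, in which case the model's own initial value is used.
    States are clipped at 0 if numerically negative.
    """
    violations = validate_model(model)
    if violations:
        raise ValueError("invalid model: " + "; ".join(violations))
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end is None:
        t_end = patient.last_blast_time()
    n = max(1, math.ceil(t_end / dt - 1e-9))
    t_half = np.arange(2 * n + 1) * (dt / 2.0)
    trajs = patient_trajectories(patient, manifest, float(n * dt))
    feature_index = {name: i for i, name in enumerate(manifest.names())}
    inputs_half = np.zeros((1, len(feature_index), t_half.size))
    inputs_left = np.zeros_like(inputs_half)
    for name, j in feature_index.items():
        inputs_half[0, j] = _sample_on_half_grid(trajs[name], t_half)
        inputs_left[0, j] = _sample_left_limits(trajs[name], t_half)
    arrays = _encode_model(model, feature_index)
    init = arrays.x0[None, :].copy()
    if init_output_from_obs and patient.blast_obs:
        scale = 1.0 if normalized else curation.BLAST_SCALE
        init[0, arrays.out_pos] = sorted(patient.blast_obs)[0][1] / scale
    states, status = simulate_batch(
        arrays.m, arrays.d, init,
        arrays.link_from_input, arrays.link_src, arrays.link_tgt,
        arrays.link_sign, arrays.link_nec, arrays.link_Kn, arrays.link_n,
        arrays.n_suff, arrays.n_reg,
        inputs_half, inputs_left, np.array([n], dtype=np.int64), dt,
    )
    if status[0] != 0:
        step = int(status[0]) - 1
        raise SimulationError(
            f"non-finite state at t={step * dt:.3f} days for patient {patient.patient_id}"
        )
    grid = np.arange(n + 1) * dt
    out_states = {nid: states[0, : n + 1, i] for i, nid in enumerate(arrays.dyn_ids)}
    # attach input signals on the same grid for inspection/plotting
    for node in model.input_nodes:
        feat = model.feature_bindings[node.node_id]
        out_states[node.node_id] = _sample_on_half_grid(trajs[feat], grid)
    return SimulationResult(patient.patient_id, grid, out_states,
                            model.output_node.node_id)


def patient_error(result: SimulationResult, blast_obs) -> float:
    """RMSE between observed (normalized) blasts and the simulated output.

    The simulated output is linearly interpolated to the observation times,
    which must lie inside the simulated time span.
    """
    if len(blast_obs) == 0:
        raise ValueError("empty blast observation list")
    obs = sorted(blast_obs)
    t = np.array([o[0] for o in obs], dtype=float)
    v = np.array([o[1] for o in obs], dtype=float)
    if t[0] < result.time_grid[0] - 1e-9 or t[-1] > result.time_grid[-1] + 1e-9:
        raise ValueError("observation times outside the simulated span")
    pred = np.interp(t, result.time_grid, result.output)
    return float(np.sqrt(np.mean((pred - v) ** 2)))


def cohort_fitness(
    model: RegulatoryModel,
    cohort: ClinicalCohort | CohortSimData,
    dt: float = DEFAULT_DT,
) -> float:
    """Mean per-patient RMSE of the model over a cohort (lower is better).

    Returns +inf when any patient's simulation produces a non-finite state,
    so a divergent candidate is eliminated by selection instead of raising.
    """
    sim = cohort if isinstance(cohort, CohortSimData) else CohortSimData.from_cohort(cohort, dt)
    if len(sim) == 0:
        raise ValueError("empty cohort")
    arrays = _encode_model(model, sim.feature_index)
    init = _init_states(arrays, sim, init_output_from_obs=True)
    states, status = _run_kernel(arrays, sim, init)
    if np.any(status != 0):
        return float("inf")
    total = 0.0
    for i in range(len(sim)):
        n = int(sim.n_steps[i])
        grid = np.arange(n + 1) * sim.dt
        pred = np.interp(sim.obs_times[i], grid, states[i, : n + 1, arrays.out_pos])
        err = float(np.sqrt(np.mean((pred - sim.obs_values[i]) ** 2)))
        if not np.isfinite(err):
            return float("inf")
        total += err
    return total / len(sim)


# ---------------------------------------------------------------------------
# Adaptive reference integrator (cross-validation oracle)
# ---------------------------------------------------------------------------

def reference_simulate(
    model: RegulatoryModel,
    patient: PatientRecord,
    manifest: FeatureManifest,
    t_eval: np.ndarray,
    init_output_from_obs: bool = True,
    normalized: bool = False,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> dict[str, np.ndarray]:
    """High-accuracy adaptive integration using the plain-Python RHS.

    Integrates piecewise between input-signal knot times (where the signals
    are discontinuous or kinked) with scipy's DOP853 at tight tolerances.
    This is a cross-check for the fixed-step production kernel, not a
    replacement for it.
    """
    from scipy.integrate import solve_ivp

    t_eval = np.asarray(t_eval, dtype=float)
    t_end = float(t_eval[-1])
    trajs = patient_trajectories(patient, manifest, t_end)
    bound = {nid: trajs[feat] for nid, feat in model.feature_bindings.items()}
    dyn = model.dynamic_nodes
    dyn_ids = [n.node_id for n in dyn]

    def rhs(t, y):
        state = dict(zip(dyn_ids, y))
        inputs = {
            nid: float(traj.evaluate(np.nextafter(t, np.inf)))
            if traj.kind == "step" else float(traj.evaluate(t))
            for nid, traj in bound.items()
        }
        deriv = model_rhs(model, state, inputs)
        return [deriv[nid] for nid in dyn_ids]

    y0 = []
    scale = 1.0 if normalized else curation.BLAST_SCALE
    for node in dyn:
        if (node.role == "output" and init_output_from_obs and patient.blast_obs):
            y0.append(sorted(patient.blast_obs)[0][1] / scale)
        else:
            y0.append(node.initial_value)
    # break the integration at every input knot inside the span
    breaks = {0.0, t_end}
    for traj in bound.values():
        breaks.update(float(t) for t in traj.times if 0.0 < t < t_end)
    breaks = sorted(breaks)
    out = np.empty((len(dyn_ids), t_eval.size))
    y = np.array(y0, dtype=float)
    for k, (a, b) in enumerate(zip(breaks[:-1], breaks[1:])):
        sol = solve_ivp(rhs, (a, b), y, method="DOP853",
                        rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            raise SimulationError(f"reference integration failed on [{a}, {b}]: {sol.message}")
        last = k == len(breaks) - 2
        mask = (t_eval >= a) & ((t_eval <= b) if last else (t_eval < b))
        if mask.any():
            out[:, mask] = sol.sol(t_eval[mask])
        y = sol.y[:, -1]
    return dict(zip(dyn_ids, out))
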