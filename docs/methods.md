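# Methods

This note documents the mathematical model, the numerical choices, the
synthetic-cohort generator, and the known limitations of `amldyn`.

## 1. Problem statement

Acute myeloid leukemia (AML) progression is tracked clinically through the
bone-marrow **blast percentage** measured at irregular visits, alongside
baseline demographics, mutation panels, and treatment episodes.  `amldyn`
infers, *de novo*, a small mechanistic regulatory-network model — both its
**topology** (which clinical features regulate disease burden, possibly
through hidden intermediate states) and its **parameters** — such that the
network's ordinary-differential-equation (ODE) dynamics reproduce each
patient's blast trajectory.  Inference is by an evolutionary algorithm (EA)
over model structures; an ensemble of independent runs yields feature-level
selection frequencies that separate genuine drivers from decoys.

## 2. Model

### 2.1 State variables and inputs

A model is a directed network over three node roles:

* **input nodes** — bound one-to-one to clinical features; their values are
  patient-specific *known time courses* (no ODE), normalized to `[0, 1]`.
* **hidden nodes** — optional latent dynamic states (e.g. an unobserved
  clone or marrow-niche signal), dimensionless in `[0, ∞)`.
* **output node** `blast` — normalized blast fraction (observed blast % / 100).

### 2.2 Regulation

Each link `j → i` carries a sign (activation/repression), a Hill threshold
`K ∈ (0, 1]`, an integer Hill exponent `n ∈ {1, 2, 3, 4}`, and a logic group.
The single-link response to regulator value `x_j ≥ 0` is

```
h(x_j) = x_j^n / (x_j^n + K^n)        (activator)
h(x_j) = 1 − x_j^n / (x_j^n + K^n)    (repressor)
```

Links into a node combine in two groups:

* **sufficient** (OR-like, noisy-OR): `S = 1 − Π (1 − h_k)`
* **necessary** (AND-like): `N = Π h_k`

and the total regulation is `R = S · N` (with `S = 0` if a node has no
sufficient links and regulators exist only in the necessary group,
`R = N`; a node with no incoming links has `R = 0`).  Each dynamic node
then obeys

```
dx_i/dt = m_i · R_i(x, u(t)) − d_i · x_i
```

with production capacity `m_i` (1/day) and first-order decay `d_i` (1/day).
`R ∈ [0, 1]`, so trajectories stay in `[0, m_i / d_i]`; states are clipped
at 0 after each step to guard against rounding.

### 2.3 Parameter ranges

| Parameter | Search range | Clamp after mutation | Units / rationale |
|---|---|---|---|
| Hill `K` | 0.05 – 0.95 | [1e-3, 1] | normalized regulator units; thresholds inside the observable range |
| Hill `n` | {1, 2, 3, 4} | — | integer cooperativity; bounded for identifiability |
| `m` | 0.02 – 0.8 /day | [1e-4, 2] | production over days-to-months clinical timescales |
| `d` | 0.005 – 0.4 /day | [1e-3, 2] | turnover half-lives ≈ 1.7 – 140 days |

## 3. Numerical integration

* **Fixed-step classical RK4**, `dt = 0.25` day, compiled with numba
  (`amldyn._kernel.simulate_batch`) and vectorized over patients.
* Input trajectories are **pre-sampled on the half-step grid**.  Because
  treatment signals are step functions, a switch at a grid point would make
  the right-hand side discontinuous *at* a stage evaluation; the kernel
  therefore takes two samplings — right limits for RK4 stages 1–3 and left
  limits for stage 4 — so every step integrates a smooth piece and retains
  4th-order accuracy.  Measured error vs. an adaptive reference is
  ~2 × 10⁻⁷ in normalized units.
* **Independent reference**: `reference_simulate` integrates the pure-Python
  right-hand side with `scipy.integrate.solve_ivp` (DOP853, rtol 1e-10,
  atol 1e-12), restarted piecewise at every input knot.  It shares no code
  with the kernel beyond the model definition and serves as the oracle in
  the test suite.
* Non-finite states abort a patient's simulation; fitness assigns `+inf`
  so divergent models are selected against, never crash the EA.
* A note on the kernel's shape: the regulation function is written inline
  in the integrator loop rather than as a separate compiled function,
  because the outlined form compiled ~30× slower under LLVM.  The readable
  definition lives in `model_core.model_rhs` and the two are tested to
  agree to ~1e-9.

## 4. Data curation

* **Exclusion rules**, applied in order with first-match logging:
  no treatment records; treatment end before start; missing mutation
  features; fewer than 2 blast observations.  `filter_patients` returns the
  retained cohort plus a per-patient `ExclusionLog`.
* **Feature interpolation**: continuous features use piecewise-linear
  interpolation (exact at every observation, constant extrapolation);
  binary features use zero-order hold; treatments become closed-interval
  0/1 signals with overlapping episodes merged.
* **Normalization**: features are min-max scaled to `[0, 1]` over the
  cohort; blast % divides by 100.  The scaling map is returned so held-out
  patients can be scaled by the *training* extremes (`apply_scaling`) —
  evaluation functions do this automatically, and models are always
  simulated against normalized features (metrics are still reported in
  blast-% units).
* `auc_over_duration` is the exact trapezoidal integral of a trajectory
  divided by its time span (e.g. a (0,0)→(10,10) ramp gives 5).

## 5. Evolutionary inference

* Generational EA: tournament selection (size 3), elitism (top 10%),
  link-wise uniform crossover keyed on `(source, target)` pairs
  (probability 0.5), then mutation.
* Mutation kinds and default per-offspring rates: parameter perturbation
  0.9 (two-scale lognormal, σ = 0.3 or 0.03 — coarse exploration plus fine
  polishing), add link 0.15, delete link 0.20, add hidden 0.05, delete
  hidden 0.07, flip sign 0.15, flip logic group 0.10.  Structural edits
  that would violate model constraints (e.g. a link into an input node)
  are skipped and logged, never repaired into invalid states.
* **Memetic local search**: every `local_search_interval` generations (and
  at the final one) the best individuals of the top `local_search_top_k`
  structurally distinct topologies get a short Nelder-Mead polish of their
  continuous parameters (log m, log d, log K, hidden initial values;
  topology and integer exponents untouched), Lamarckian-style.  Two starts
  are used — the current parameters and a mid-range restart — because the
  landscape contains a fast-equilibrium valley (m, d large with the right
  ratio) whose minimum lies outside the search clamps.  Polishing several
  distinct topologies keeps simpler candidate structures competitive with
  the polished incumbent; pure mutation-based parameter search crawls
  along the correlated (m, d, K) valleys and stalls 2–4 orders of
  magnitude above what a few hundred simplex steps achieve.
* **Fitness** = mean over patients of the RMSE between simulated and
  observed normalized blast values; lower is better.  No complexity
  penalty is applied; parsimony pressure comes from delete mutations and
  from ensemble frequency analysis.
* Determinism: every stochastic draw comes from a `numpy.random.Generator`
  seeded from the config; fitness evaluation is pure, and parallel
  evaluation (joblib, order-preserving) gives bit-identical results for
  any worker count.  Ranking ties break on population index, so results
  are reproducible run-to-run.
* `run_ensemble` performs independent runs with seeds `seed + i`;
  `feature_frequency` reports the fraction of best models whose simplified
  structure actually uses each feature (links that cannot influence the
  output are ignored).

## 6. Evaluation metrics

Computed in blast-% units, per patient and pooled over all
prediction/observation pairs: RMSE, MAE, R² (flagged undefined when the
observations are constant), range-normalized RMSE (same flag), and MAPE
with a 1-blast-point denominator floor to avoid division blow-up near
zero.  RMSE ≥ MAE always (Cauchy–Schwarz), and R² = 1 exactly on perfect
predictions; both facts are enforced in tests.

## 7. Synthetic-cohort generator

The generator emulates a longitudinal AML registry:

* Baseline features: age, BMI, ECOG (continuous); FLT3-ITD, NPM1, DNMT3A,
  TP53, cytogenetic abnormality (binary); cytarabine, hypomethylating
  agent, consolidation (treatment intervals).  Continuous features drift
  over follow-up via smoothed random walks; binaries may switch once
  (clonal acquisition); treatments are 2-to-17-week episodes.
* Ground truth: a random regulatory model with a configurable number of
  drivers, inert decoys, and hidden nodes.  Kinetics use `d ∈ [0.01, 0.2]`
  /day and `m = d · gain` with gain ∈ [0.4, 1.0] so steady states stay in
  the normalized range (an independent `m` would saturate blast at 100%
  for many draws and destroy the zero-noise consistency used for testing).
* Blast observations are taken at irregular visits (≥ 7-day gaps, mean 30
  days, always including day 0 and end of follow-up) by simulating the
  ground truth with the same kernel and adding Gaussian noise (sd in
  blast-% points, clipped to [0, 100]).  At zero noise the generator and
  the fitness pipeline agree to ~1e-16, so "fitness ≈ 0" is achievable and
  meaningful.
* Defect injection adds curation-violating defects (missing treatments,
  inconsistent dates, missing mutations, too-few blasts) to distinct
  patients for testing the curation pipeline.

**What the generator does not emulate:** survival/censoring, relapse–
remission treatment feedback (treatments are exogenous, not
response-driven), measurement heteroscedasticity, batch effects between
centers, pharmacokinetics (drug exposure is a 0/1 signal), and clonal
competition between multiple leukemic populations.

## 8. Identifiability

A binary (0/1) activator exposes only `h(1) = 1/(1 + K^n)`, which the
production rate `m` can absorb — `K` and `n` are then structurally
unidentifiable even from noiseless data.  Identifiable `K` requires a
regulator whose value varies across the cohort interior of `(0, 1)`
(e.g. a continuous demographic driver) or a repressor acting on a decaying
state.  Parameter-recovery experiments therefore use continuous drivers;
topology-recovery (driver vs. decoy) experiments work with any driver
type, since selection frequency does not depend on `K` being pinned down.

## 9. Limitations

* Fixed-step integration assumes dynamics are resolved at dt = 0.25 day;
  extremely stiff parameter combinations (d ≫ 1/day) are excluded by the
  search clamps rather than handled adaptively.
* The fitness has no explicit complexity penalty; on noisy data the best
  models can carry spurious decoy links whose net effect is small.  Driver
  identification relies on ensemble frequency, not on single-run sparsity.
* Hill exponents are restricted to integers 1–4; real dose–response curves
  need not be Hill-shaped at all.
* Normalization is cohort-relative; transferring a fitted model to a new
  cohort requires reusing the original normalization parameters.
* All empirical statements above (kernel accuracy, zero-noise consistency,
  runtime) are reproduced by the test suite and `scripts/acceptance.py`;
  no claims are made beyond what those compute.
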