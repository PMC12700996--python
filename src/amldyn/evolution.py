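"""De novo evolutionary inference of regulatory-network ODE models.

The search explores both topology (which inputs and intermediate nodes are
wired, and how) and parameters (Hill half-responses and exponents, kinetic
rates) of :class:`~amldyn.model_core.RegulatoryModel`, minimising the mean
per-patient trajectory RMSE (:func:`amldyn.simulator.cohort_fitness`) over a
training cohort.  Selection is tournament-based with elitism; variation is
stochastic crossover (link-wise recombination of two parents) plus seven
independent mutation kinds.  Because a model's inputs are only *selected*
when a directed path to the output survives, the search performs feature
selection automatically: decoy inputs end up unwired.

Every stochastic choice flows through one seeded generator, and fitness
evaluation is a pure function of (model, cohort), so a run is reproducible
bit-for-bit regardless of the worker count used for evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .curation import ClinicalCohort, FeatureManifest, PatientRecord
from .model_core import (
    GROUP_NECESSARY,
    GROUP_SUFFICIENT,
    HILL_EXPONENTS,
    ROLE_INPUT,
    Node,
    RegulatoryLink,
    RegulatoryModel,
    complexity,
    selected_features,
    validate_model,
)
from .simulator import DEFAULT_DT, CohortSimData, SimulationError, cohort_fitness, simulate_patient

__all__ = [
    "EvolutionConfig",
    "GenerationRecord",
    "EvolutionResult",
    "RunEnsemble",
    "init_population",
    "mutate_model",
    "crossover_models",
    "evolve",
    "run_ensemble",
    "feature_frequency",
    "link_strength_summary",
    "ensemble_prediction",
]

#: search priors (slightly wider than typical ground-truth ranges so the
#: truth is interior to the searched region)
SEARCH_K_RANGE = (0.05, 0.95)
SEARCH_M_RANGE = (0.02, 0.8)
SEARCH_D_RANGE = (0.005, 0.4)

#: hard clamps applied after parameter perturbation
K_CLAMP = (1e-3, 1.0)
M_CLAMP = (1e-4, 2.0)
D_CLAMP = (1e-3, 2.0)

DEFAULT_MUTATION_RATES = {
    "param_perturb": 0.9,
    "add_link": 0.15,
    "delete_link": 0.20,
    "add_hidden": 0.05,
    "delete_hidden": 0.07,
    "flip_sign": 0.15,
    "flip_group": 0.10,
}

OUTPUT_NODE_ID = "blast"


@dataclass
class EvolutionConfig:
    """Hyperparameters of one evolutionary run."""

    population_size: int = 100
    max_generations: int = 200
    elite_fraction: float = 0.1
    tournament_size: int = 3
    crossover_prob: float = 0.5
    mutation_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_RATES)
    )
    max_hidden_nodes: int = 3
    zero_error_epsilon: float = 1e-6
    seed: int = 0
    n_workers: int = 1
    dt: float = DEFAULT_DT
    #: when set, every link uses this Hill exponent and exponent mutation is off
    fixed_hill_exponent: int | None = None
    #: polish the best individual's continuous parameters (Nelder-Mead,
    #: Lamarckian) every this many generations and at the final generation;
    #: 0 disables local search
    local_search_interval: int = 10
    #: fitness-evaluation budget of each local polish
    local_search_maxfev: int = 300
    #: at each polish event, refine the best individuals of this many
    #: structurally distinct topologies, so simpler candidate structures can
    #: compete with the polished incumbent on equal footing
    local_search_top_k: int = 3

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if not (0.0 < self.elite_fraction < 1.0):
            raise ValueError("elite_fraction must be in (0, 1)")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        for name, rate in self.mutation_rates.items():
            if name not in DEFAULT_MUTATION_RATES:
                raise ValueError(f"unknown mutation kind {name!r}")
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"mutation rate {name} must be in [0, 1]")
        if self.zero_error_epsilon < 0:
            raise ValueError("zero_error_epsilon must be >= 0")
        if self.local_search_interval < 0:
            raise ValueError("local_search_interval must be >= 0")
        if self.local_search_maxfev < 0:
            raise ValueError("local_search_maxfev must be >= 0")
        if self.local_search_top_k < 1:
            raise ValueError("local_search_top_k must be >= 1")


# ---------------------------------------------------------------------------
# Random model construction
# ---------------------------------------------------------------------------

def _sample_exponent(config: EvolutionConfig, rng: np.random.Generator) -> int:
    if config.fixed_hill_exponent is not None:
        return int(config.fixed_hill_exponent)
    return int(rng.choice(HILL_EXPONENTS))


def _sample_link(
    source: str, target: str, config: EvolutionConfig, rng: np.random.Generator
) -> RegulatoryLink:
    return RegulatoryLink(
        source, target,
        sign=int(rng.choice([1, -1])),
        group=str(rng.choice([GROUP_NECESSARY, GROUP_SUFFICIENT])),
        K=float(rng.uniform(*SEARCH_K_RANGE)),
        n=_sample_exponent(config, rng),
    )


def _sample_dynamic_node(
    node_id: str, role: str, rng: np.random.Generator
) -> Node:
    return Node(node_id, role,
                m=float(rng.uniform(*SEARCH_M_RANGE)),
                d=float(rng.uniform(*SEARCH_D_RANGE)),
                initial_value=float(rng.uniform(0.0, 1.0)))


def _fresh_hidden_id(rng: np.random.Generator) -> str:
    # creation-stamped id: hidden nodes only match across models when they
    # share an ancestor, which crossover relies on
    return f"z{int(rng.integers(0, 10**12)):012d}"


def init_population(
    config: EvolutionConfig, manifest: FeatureManifest, rng: np.random.Generator
) -> list[RegulatoryModel]:
    """Random initial population of valid models.

    Every model carries an input node per manifest feature (wired or not),
    the output node, a uniform-random number of hidden nodes up to
    ``max_hidden_nodes``, and 1-3 random incoming links per dynamic node.
    """
    if not manifest.entries:
        raise ValueError("empty manifest")
    population = []
    feature_names = manifest.names()
    for _ in range(config.population_size):
        nodes = [Node(f, ROLE_INPUT) for f in feature_names]
        bindings = {f: f for f in feature_names}
        n_hidden = int(rng.integers(0, config.max_hidden_nodes + 1))
        hidden_ids = [_fresh_hidden_id(rng) for _ in range(n_hidden)]
        for hid in hidden_ids:
            nodes.append(_sample_dynamic_node(hid, "hidden", rng))
        nodes.append(_sample_dynamic_node(OUTPUT_NODE_ID, "output", rng))
        all_ids = feature_names + hidden_ids + [OUTPUT_NODE_ID]
        links: list[RegulatoryLink] = []
        used: set[tuple[str, str]] = set()
        for target in hidden_ids + [OUTPUT_NODE_ID]:
            n_in = int(rng.integers(1, 4))
            for _ in range(n_in):
                source = all_ids[int(rng.integers(0, len(all_ids)))]
                if (source, target) in used:
                    continue
                used.add((source, target))
                links.append(_sample_link(source, target, config, rng))
        model = RegulatoryModel(nodes, links, bindings)
        population.append(model)
    return population


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _perturb(value: float, clamp: tuple[float, float], rng: np.random.Generator) -> float:
    # two-scale log-normal step: coarse exploration or fine refinement
    sigma = 0.3 if rng.random() < 0.5 else 0.03
    out = value * float(np.exp(sigma * rng.standard_normal()))
    return float(min(max(out, clamp[0]), clamp[1]))


def _perturb_parameters(
    model: RegulatoryModel, config: EvolutionConfig, rng: np.random.Generator
) -> RegulatoryModel:
    p_each = 0.3
    nodes = []
    for node in model.nodes:
        if not node.is_dynamic:
            nodes.append(node)
            continue
        m, d, x0 = node.m, node.d, node.initial_value
        if rng.random() < p_each:
            m = _perturb(m, M_CLAMP, rng)
        if rng.random() < p_each:
            d = _perturb(d, D_CLAMP, rng)
        if node.role == "hidden" and rng.random() < p_each:
            x0 = float(min(max(x0 + 0.1 * rng.standard_normal(), 0.0), 1.0))
        nodes.append(Node(node.node_id, node.role, m, d, x0))
    links = []
    for link in model.links:
        K, n = link.K, link.n
        if rng.random() < p_each:
            K = _perturb(K, K_CLAMP, rng)
        if config.fixed_hill_exponent is None and rng.random() < 0.15:
            n = int(min(max(n + rng.choice([-1, 1]), HILL_EXPONENTS[0]),
                        HILL_EXPONENTS[-1]))
        links.append(replace(link, K=K, n=n))
    return RegulatoryModel(nodes, links, dict(model.feature_bindings))


def mutate_model(
    model: RegulatoryModel,
    config: EvolutionConfig,
    rng: np.random.Generator,
    events: list[str] | None = None,
) -> RegulatoryModel:
    """Apply each mutation kind independently with its configured rate.

    Kinds: parameter perturbation (log-normal on K/m/d, integer step on the
    Hill exponent), add/delete link, add/delete hidden node, flip a link's
    sign, flip a link's group.  Inapplicable mutations are skipped (and
    recorded in ``events`` when provided).  The result is always valid: no
    mutation can make a link target an input node.
    """
    rates = config.mutation_rates

    def log(msg: str) -> None:
        if events is not None:
            events.append(msg)

    out = model.copy()
    if rng.random() < rates.get("param_perturb", 0.0):
        out = _perturb_parameters(out, config, rng)

    dyn_ids = [n.node_id for n in out.dynamic_nodes]
    all_ids = [n.node_id for n in out.nodes]

    if rng.random() < rates.get("add_link", 0.0):
        used = {(l.source, l.target) for l in out.links}
        candidates = [
            (s, t) for s in all_ids for t in dyn_ids if (s, t) not in used
        ]
        if candidates:
            s, t = candidates[int(rng.integers(0, len(candidates)))]
            out.links.append(_sample_link(s, t, config, rng))
        else:
            log("add_link skipped: model fully connected")

    if rng.random() < rates.get("delete_link", 0.0):
        if out.links:
            out.links.pop(int(rng.integers(0, len(out.links))))
        else:
            log("delete_link skipped: no links")

    if rng.random() < rates.get("add_hidden", 0.0):
        if len(out.hidden_nodes) < config.max_hidden_nodes:
            hid = _fresh_hidden_id(rng)
            src = all_ids[int(rng.integers(0, len(all_ids)))]
            tgt = dyn_ids[int(rng.integers(0, len(dyn_ids)))]
            out.nodes.append(_sample_dynamic_node(hid, "hidden", rng))
            out.links.append(_sample_link(src, hid, config, rng))
            out.links.append(_sample_link(hid, tgt, config, rng))
        else:
            log("add_hidden skipped: at max_hidden_nodes")

    if rng.random() < rates.get("delete_hidden", 0.0):
        hidden = out.hidden_nodes
        if hidden:
            victim = hidden[int(rng.integers(0, len(hidden)))]
            out.nodes = [n for n in out.nodes if n.node_id != victim.node_id]
            out.links = [
                l for l in out.links
                if l.source != victim.node_id and l.target != victim.node_id
            ]
        else:
            log("delete_hidden skipped: no hidden nodes")

    if rng.random() < rates.get("flip_sign", 0.0):
        if out.links:
            i = int(rng.integers(0, len(out.links)))
            out.links[i] = replace(out.links[i], sign=-out.links[i].sign)
        else:
            log("flip_sign skipped: no links")

    if rng.random() < rates.get("flip_group", 0.0):
        if out.links:
            i = int(rng.integers(0, len(out.links)))
            new_group = (GROUP_NECESSARY
                         if out.links[i].group == GROUP_SUFFICIENT
                         else GROUP_SUFFICIENT)
            out.links[i] = replace(out.links[i], group=new_group)
        else:
            log("flip_group skipped: no links")

    return out


def crossover_models(
    parent_a: RegulatoryModel,
    parent_b: RegulatoryModel,
    rng: np.random.Generator,
) -> RegulatoryModel:
    """Link-wise recombination of two parents sharing a manifest.

    The offspring inherits each link in the union of the parents' link sets
    (matched by (source, target) node ids) from a uniformly chosen parent
    possessing it, with that parent's parameters.  Hidden nodes referenced
    by inherited links are copied from the contributing parent; when both
    parents carry a hidden node of the same id, a coin flip picks whose
    kinetic parameters survive.  The output node's kinetics are likewise
    taken from a randomly chosen parent.
    """
    if parent_a.feature_bindings != parent_b.feature_bindings:
        raise ValueError("parents are bound to different manifests")
    links_a = {(l.source, l.target): l for l in parent_a.links}
    links_b = {(l.source, l.target): l for l in parent_b.links}
    keys = sorted(set(links_a) | set(links_b))
    chosen: list[RegulatoryLink] = []
    link_owner: dict[tuple[str, str], RegulatoryModel] = {}
    for key in keys:
        if key in links_a and key in links_b:
            owner = parent_a if rng.random() < 0.5 else parent_b
        elif key in links_a:
            owner = parent_a
        else:
            owner = parent_b
        chosen.append(links_a[key] if owner is parent_a else links_b[key])
        link_owner[key] = owner

    hidden_a = {n.node_id: n for n in parent_a.hidden_nodes}
    hidden_b = {n.node_id: n for n in parent_b.hidden_nodes}
    referenced: list[str] = []
    for link in chosen:
        for nid in (link.source, link.target):
            if (nid in hidden_a or nid in hidden_b) and nid not in referenced:
                referenced.append(nid)
    # preserve parent-a hidden ordering first, then parent-b extras
    ordering = [n.node_id for n in parent_a.hidden_nodes] + [
        n.node_id for n in parent_b.hidden_nodes if n.node_id not in hidden_a
    ]
    referenced.sort(key=ordering.index)
    hidden_nodes: list[Node] = []
    for nid in referenced:
        if nid in hidden_a and nid in hidden_b:
            hidden_nodes.append(hidden_a[nid] if rng.random() < 0.5 else hidden_b[nid])
        else:
            hidden_nodes.append(hidden_a.get(nid) or hidden_b[nid])

    output = parent_a.output_node if rng.random() < 0.5 else parent_b.output_node
    nodes = list(parent_a.input_nodes) + hidden_nodes + [output]
    child = RegulatoryModel(nodes, chosen, dict(parent_a.feature_bindings))
    # repair: drop links that reference hidden nodes not copied (cannot occur
    # by construction, but keep the offspring contract absolute)
    node_ids = {n.node_id for n in child.nodes}
    child.links = [l for l in child.links
                   if l.source in node_ids and l.target in node_ids]
    return child


# ---------------------------------------------------------------------------
# The generational loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_complexity: int


@dataclass
class EvolutionResult:
    """Outcome of one evolutionary run."""

    best_model: RegulatoryModel
    best_fitness: float
    history: list[GenerationRecord]
    config: EvolutionConfig
    seed: int
    terminated_by: str  # "epsilon" | "budget"

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(r.generation, r.best_fitness, r.mean_fitness, r.best_complexity)
             for r in self.history],
            columns=["generation", "best_fitness", "mean_fitness", "best_complexity"],
        )


@dataclass
class RunEnsemble:
    """Results of independent runs (distinct seeds) on a shared manifest."""

    results: list[EvolutionResult]
    manifest: FeatureManifest

    def __post_init__(self):
        seeds = [r.seed for r in self.results]
        if len(set(seeds)) != len(seeds):
            raise ValueError("ensemble runs must have distinct seeds")

    def __len__(self) -> int:
        return len(self.results)

    def best_models(self) -> list[RegulatoryModel]:
        return [r.best_model for r in self.results]


def _evaluate(
    models: Sequence[RegulatoryModel], sim: CohortSimData, n_workers: int
) -> list[float]:
    if n_workers <= 1 or len(models) < 2:
        return [cohort_fitness(m, sim) for m in models]
    from joblib import Parallel, delayed

    return list(
        Parallel(n_jobs=n_workers)(delayed(cohort_fitness)(m, sim) for m in models)
    )


def _structure_signature(model: RegulatoryModel):
    """Hashable topology key: node set plus links up to continuous params."""
    return (
        frozenset((n.node_id, n.role) for n in model.nodes),
        frozenset((l.source, l.target, l.sign, l.group, l.n) for l in model.links),
    )


def _polish_parameters(
    model: RegulatoryModel, sim: CohortSimData, maxfev: int
) -> tuple[RegulatoryModel, float]:
    """Nelder-Mead refinement of the continuous parameters, structure fixed.

    Optimizes log m, log d (and initial value for hidden nodes) of every
    dynamic node plus log K of every link; integer Hill exponents, signs,
    groups, and topology are untouched.  The mutation operator's random
    multiplicative steps explore well but crawl along the correlated
    (m, d, K) valleys of the fitness landscape; a short deterministic
    simplex descent finishes the job in a few hundred evaluations.
    """
    from scipy.optimize import minimize

    theta0: list[float] = []
    for node in model.dynamic_nodes:
        theta0 += [float(np.log(node.m)), float(np.log(node.d))]
        if node.role == "hidden":
            theta0.append(float(node.initial_value))
    for link in model.links:
        theta0.append(float(np.log(link.K)))

    def rebuild(theta: np.ndarray) -> RegulatoryModel:
        it = iter(theta)

        def clamp(v, lo_hi):
            return float(min(max(v, lo_hi[0]), lo_hi[1]))

        nodes = []
        for node in model.nodes:
            if not node.is_dynamic:
                nodes.append(node)
                continue
            m = clamp(np.exp(next(it)), M_CLAMP)
            d = clamp(np.exp(next(it)), D_CLAMP)
            x0 = node.initial_value
            if node.role == "hidden":
                x0 = clamp(next(it), (0.0, 1.0))
            nodes.append(Node(node.node_id, node.role, m, d, x0))
        links = [replace(l, K=clamp(np.exp(next(it)), K_CLAMP))
                 for l in model.links]
        return RegulatoryModel(nodes, links, dict(model.feature_bindings))

    # second start: kinetic rates reset to the geometric mean of the search
    # ranges (K and hidden initial values kept).  The landscape has a
    # fast-equilibrium valley (m, d large with the right ratio) whose
    # minimum lies outside the clamps; a descent started there stalls on
    # the clamp boundary, so a mid-range restart offers an escape route.
    theta1 = list(theta0)
    pos = 0
    m_mid = float(np.sqrt(SEARCH_M_RANGE[0] * SEARCH_M_RANGE[1]))
    d_mid = float(np.sqrt(SEARCH_D_RANGE[0] * SEARCH_D_RANGE[1]))
    for node in model.dynamic_nodes:
        theta1[pos] = float(np.log(m_mid))
        theta1[pos + 1] = float(np.log(d_mid))
        pos += 3 if node.role == "hidden" else 2

    best_model, best_fit = model, float("inf")
    for start in (theta0, theta1):
        result = minimize(
            lambda th: cohort_fitness(rebuild(th), sim),
            np.asarray(start),
            method="Nelder-Mead",
            options=dict(maxfev=maxfev, xatol=1e-9, fatol=1e-14),
        )
        if float(result.fun) < best_fit:
            best_model, best_fit = rebuild(result.x), float(result.fun)
    return best_model, best_fit


def _tournament(
    fits: Sequence[float], config: EvolutionConfig, rng: np.random.Generator
) -> int:
    idx = rng.integers(0, len(fits), size=config.tournament_size)
    best = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if (fits[i], i) < (fits[best], best):
            best = i
    return best


def evolve(
    cohort: ClinicalCohort | CohortSimData,
    config: EvolutionConfig,
    manifest: FeatureManifest | None = None,
) -> EvolutionResult:
    """Run the evolutionary search on a curated, normalized training cohort.

    Per generation: evaluate every model's cohort fitness (evaluations are
    pure and order-independent), keep the elite fraction unchanged, and fill
    the remainder with tournament-selected parents undergoing crossover
    (with probability ``crossover_prob``) followed by mutation.  Every
    ``local_search_interval`` generations (and at the final one) the best
    individual's continuous parameters get a short Nelder-Mead polish
    (Lamarckian: the refined model re-enters the population).  Stops when
    the best fitness drops to ``zero_error_epsilon`` or the generation
    budget is exhausted.  Ranking is a stable sort on (fitness, population
    index), so runs are reproducible for any worker count.
    """
    sim = cohort if isinstance(cohort, CohortSimData) else \
        CohortSimData.from_cohort(cohort, config.dt)
    if manifest is None:
        manifest = sim.manifest
    rng = np.random.default_rng(config.seed)
    population = init_population(config, manifest, rng)
    fits = _evaluate(population, sim, config.n_workers)
    n_elite = max(1, int(round(config.elite_fraction * config.population_size)))

    history: list[GenerationRecord] = []
    terminated_by = "budget"
    generation = 0
    while True:
        interval = config.local_search_interval
        due = interval > 0 and generation > 0 and (
            generation % interval == 0 or generation >= config.max_generations
        )
        if due:
            order = np.argsort(fits, kind="stable")
            seen_structures: set = set()
            for i in order:
                i = int(i)
                if len(seen_structures) >= config.local_search_top_k:
                    break
                if not np.isfinite(fits[i]):
                    break
                signature = _structure_signature(population[i])
                if signature in seen_structures:
                    continue
                seen_structures.add(signature)
                polished, polished_fit = _polish_parameters(
                    population[i], sim, config.local_search_maxfev
                )
                if polished_fit < fits[i]:
                    population[i] = polished
                    fits[i] = polished_fit
        order = np.argsort(fits, kind="stable")
        best_i = int(order[0])
        finite = [f for f in fits if np.isfinite(f)]
        history.append(GenerationRecord(
            generation, float(fits[best_i]),
            float(np.mean(finite)) if finite else float("inf"),
            complexity(population[best_i]),
        ))
        if fits[best_i] <= config.zero_error_epsilon:
            terminated_by = "epsilon"
            break
        if generation >= config.max_generations:
            break
        elites = [population[int(i)] for i in order[:n_elite]]
        elite_fits = [fits[int(i)] for i in order[:n_elite]]
        offspring: list[RegulatoryModel] = []
        while len(offspring) < config.population_size - n_elite:
            i = _tournament(fits, config, rng)
            child = population[i]
            if rng.random() < config.crossover_prob:
                j = _tournament(fits, config, rng)
                child = crossover_models(child, population[j], rng)
            child = mutate_model(child, config, rng)
            offspring.append(child)
        population = elites + offspring
        fits = elite_fits + _evaluate(offspring, sim, config.n_workers)
        generation += 1

    order = np.argsort(fits, kind="stable")
    best_i = int(order[0])
    return EvolutionResult(
        best_model=population[best_i],
        best_fitness=float(fits[best_i]),
        history=history,
        config=config,
        seed=config.seed,
        terminated_by=terminated_by,
    )


def run_ensemble(
    cohort: ClinicalCohort | CohortSimData,
    config: EvolutionConfig,
    n_runs: int = 20,
) -> RunEnsemble:
    """Independent runs with seeds config.seed, config.seed + 1, ..."""
    sim = cohort if isinstance(cohort, CohortSimData) else \
        CohortSimData.from_cohort(cohort, config.dt)
    results = []
    for i in range(n_runs):
        cfg = replace(config, mutation_rates=dict(config.mutation_rates),
                      seed=config.seed + i)
        results.append(evolve(sim, cfg))
    return RunEnsemble(results, sim.manifest)


# ---------------------------------------------------------------------------
# Ensemble analytics
# ---------------------------------------------------------------------------

def feature_frequency(ensemble: RunEnsemble) -> dict[str, float]:
    """Fraction of runs whose best model selects each manifest feature."""
    if not ensemble.results:
        raise ValueError("empty ensemble")
    selections = [selected_features(r.best_model) for r in ensemble.results]
    return {
        name: sum(1 for s in selections if name in s) / len(selections)
        for name in ensemble.manifest.names()
    }


MAX_PATH_LENGTH = 6
MAX_PATHS_PER_FEATURE = 10_000


def _signed_strength(model: RegulatoryModel, feature: str) -> float | None:
    """Sum of signed path strengths from a feature's input to the output.

    A path's sign is the product of its link signs; its magnitude is the
    mean of (1 - K) over its links (a lower half-response means a stronger
    regulation).  Simple paths only, capped in length and count.
    """
    input_id = None
    for nid, feat in model.feature_bindings.items():
        if feat == feature:
            input_id = nid
            break
    if input_id is None:
        return None
    G = nx.DiGraph()
    G.add_nodes_from(n.node_id for n in model.nodes)
    params = {}
    for l in model.links:
        G.add_edge(l.source, l.target)
        params[(l.source, l.target)] = l
    out_id = model.output_node.node_id
    total = 0.0
    count = 0
    found = False
    for path in nx.all_simple_paths(G, input_id, out_id, cutoff=MAX_PATH_LENGTH):
        found = True
        sign = 1
        mags = []
        for a, b in zip(path[:-1], path[1:]):
            link = params[(a, b)]
            sign *= link.sign
            mags.append(1.0 - link.K)
        total += sign * float(np.mean(mags))
        count += 1
        if count >= MAX_PATHS_PER_FEATURE:
            warnings.warn(
                f"path enumeration for feature {feature!r} capped at "
                f"{MAX_PATHS_PER_FEATURE} paths"
            )
            break
    return total if found else None


def link_strength_summary(ensemble: RunEnsemble) -> dict[str, float]:
    """Per-feature signed regulation strength averaged over the ensemble.

    For each run where the feature is selected, its value is the sum of
    signed simple-path strengths to the output; the summary is the mean over
    those runs, and 0 for features never selected.
    """
    if not ensemble.results:
        raise ValueError("empty ensemble")
    out: dict[str, float] = {}
    for name in ensemble.manifest.names():
        values = []
        for result in ensemble.results:
            strength = _signed_strength(result.best_model, name)
            if strength is not None:
                values.append(strength)
        out[name] = float(np.mean(values)) if values else 0.0
    return out


@dataclass
class EnsemblePrediction:
    time_grid: np.ndarray
    mean: np.ndarray  # blast %
    std: np.ndarray  # blast %
    n_models: int
    n_failed: int


def ensemble_prediction(
    models: Sequence[RegulatoryModel],
    patient: PatientRecord,
    manifest: FeatureManifest,
    dt: float = DEFAULT_DT,
    normalized: bool = False,
) -> EnsemblePrediction:
    """Pointwise mean and std of the predicted blast trajectory (in percent).

    Models whose simulation diverges on this patient are excluded (and
    counted), not fatal.
    """
    if not models:
        raise ValueError("empty model list")
    outputs = []
    grid = None
    n_failed = 0
    for model in models:
        try:
            result = simulate_patient(model, patient, manifest, dt=dt,
                                      normalized=normalized)
        except SimulationError:
            n_failed += 1
            continue
        grid = result.time_grid
        outputs.append(result.output * 100.0)
    if not outputs:
        raise SimulationError("every model's simulation failed for this patient")
    stack = np.vstack(outputs)
    return EnsemblePrediction(grid, stack.mean(axis=0), stack.std(axis=0),
                              n_models=len(outputs), n_failed=n_failed)
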