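"""Regulatory-network ODE formalism.

A :class:`RegulatoryModel` is a small typed graph: *input* nodes carry
interpolated clinical signals (age, mutation status, treatment exposure),
*hidden* nodes are inferred intermediate variables, and the single *output*
node predicts disease progression (blast percentage, in normalized [0, 1]
units).  Directed links are signed Hill-type regulations, each assigned to a
*necessary* or *sufficient* group.  Every hidden/output node ``i`` obeys

    dx_i/dt = m_i * R_i(x, u(t)) - d_i * x_i

where ``R_i`` combines the Hill terms of the node's incoming links
(noisy-OR over the sufficient group times product over the necessary group)
and ``u(t)`` are the input signals.  Input nodes are exogenous: they can
regulate but are never regulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Node",
    "RegulatoryLink",
    "RegulatoryModel",
    "hill_term",
    "combine_regulation",
    "model_rhs",
    "validate_model",
    "complexity",
    "selected_features",
    "render_equations",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

ROLE_INPUT = "input"
ROLE_HIDDEN = "hidden"
ROLE_OUTPUT = "output"
ROLES = (ROLE_INPUT, ROLE_HIDDEN, ROLE_OUTPUT)

GROUP_NECESSARY = "necessary"
GROUP_SUFFICIENT = "sufficient"
GROUPS = (GROUP_NECESSARY, GROUP_SUFFICIENT)

MODEL_SCHEMA = "amldyn-model/1"

#: valid Hill exponents (small integers keep the ODEs non-stiff and the
#: parameter search compact)
HILL_EXPONENTS = (1, 2, 3, 4)


@dataclass(frozen=True)
class Node:
    """One model variable.

    Input nodes carry no kinetic parameters; hidden and output nodes have a
    maximum production rate ``m`` (1/day), a degradation rate ``d`` (1/day)
    and an initial value ``initial_value`` in normalized [0, 1] units.
    """

    node_id: str
    role: str
    m: float | None = None
    d: float | None = None
    initial_value: float | None = None

    @property
    def is_dynamic(self) -> bool:
        return self.role in (ROLE_HIDDEN, ROLE_OUTPUT)


@dataclass(frozen=True)
class RegulatoryLink:
    """A signed, grouped Hill regulation from ``source`` to ``target``.

    ``sign`` is +1 (activation) or -1 (repression); ``group`` decides how the
    term combines with the target's other regulators; ``K`` is the
    half-response level in (0, 1]; ``n`` the Hill exponent (integer >= 1).
    """

    source: str
    target: str
    sign: int
    group: str
    K: float
    n: int


@dataclass
class RegulatoryModel:
    """Typed node set + regulatory links + input-to-feature bindings."""

    nodes: list[Node]
    links: list[RegulatoryLink]
    feature_bindings: dict[str, str] = field(default_factory=dict)

    # -- convenience views -------------------------------------------------
    def node_map(self) -> dict[str, Node]:
        return {n.node_id: n for n in self.nodes}

    @property
    def input_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.role == ROLE_INPUT]

    @property
    def hidden_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.role == ROLE_HIDDEN]

    @property
    def output_node(self) -> Node:
        outs = [n for n in self.nodes if n.role == ROLE_OUTPUT]
        if len(outs) != 1:
            raise ValueError(f"model must have exactly one output node, found {len(outs)}")
        return outs[0]

    @property
    def dynamic_nodes(self) -> list[Node]:
        """Hidden + output nodes, in stored order."""
        return [n for n in self.nodes if n.is_dynamic]

    def incoming(self, node_id: str) -> list[RegulatoryLink]:
        return [l for l in self.links if l.target == node_id]

    def copy(self) -> "RegulatoryModel":
        """Shallow structural copy (Node/RegulatoryLink are immutable)."""
        return RegulatoryModel(list(self.nodes), list(self.links), dict(self.feature_bindings))


# ---------------------------------------------------------------------------
# Regulation algebra
# ---------------------------------------------------------------------------

def hill_term(x: float, K: float, n: int, sign: int) -> float:
    """Hill activation/repression of a regulator at level ``x``.

    Activator (sign=+1): x^n / (x^n + K^n); repressor (sign=-1):
    K^n / (x^n + K^n).  At x == K either form equals 1/2.
    """
    if K <= 0:
        raise ValueError(f"half-response K must be positive, got {K}")
    if n < 1:
        raise ValueError(f"Hill exponent must be >= 1, got {n}")
    x = max(float(x), 0.0)
    xn = x**n
    Kn = K**n
    if sign == 1:
        return xn / (xn + Kn)
    if sign == -1:
        return Kn / (xn + Kn)
    raise ValueError(f"sign must be +1 or -1, got {sign}")


def combine_regulation(terms: Iterable[tuple[float, str]]) -> float:
    """Combine grouped regulator terms into the production drive R in [0, 1].

    Sufficient terms combine as a noisy-OR, necessary terms as a product,
    and R = S * N.  A node with only necessary regulators gets S = 1 (the
    necessary terms gate a full drive); a node with no regulators at all gets
    R = 0 and is purely decaying.
    """
    suff_prod = 1.0
    nec_prod = 1.0
    n_suff = 0
    n_terms = 0
    for value, group in terms:
        n_terms += 1
        if group == GROUP_SUFFICIENT:
            suff_prod *= 1.0 - value
            n_suff += 1
        elif group == GROUP_NECESSARY:
            nec_prod *= value
        else:
            raise ValueError(f"unknown regulation group {group!r}")
    if n_terms == 0:
        return 0.0
    S = (1.0 - suff_prod) if n_suff > 0 else 1.0
    return S * nec_prod


def model_rhs(
    model: RegulatoryModel,
    state: Mapping[str, float],
    input_values: Mapping[str, float],
) -> dict[str, float]:
    """Reference right-hand side: derivative of every hidden/output node.

    This is the plain-Python definition of the dynamics; the fast simulator
    kernel must agree with it (and is tested to).
    """
    deriv: dict[str, float] = {}
    for node in model.dynamic_nodes:
        terms = []
        for link in model.incoming(node.node_id):
            if link.source in state:
                src_val = state[link.source]
            elif link.source in input_values:
                src_val = input_values[link.source]
            else:
                raise KeyError(f"no state or input value supplied for node {link.source!r}")
            terms.append((hill_term(src_val, link.K, link.n, link.sign), link.group))
        R = combine_regulation(terms)
        if node.node_id not in state:
            raise KeyError(f"no state value supplied for node {node.node_id!r}")
        deriv[node.node_id] = node.m * R - node.d * state[node.node_id]
    return deriv


# ---------------------------------------------------------------------------
# Validation / structural queries
# ---------------------------------------------------------------------------

def validate_model(model: RegulatoryModel, manifest=None) -> list[str]:
    """Return all structural/parameter violations (empty list iff valid).

    Checks: exactly one output node; unique node ids; kinetic parameters
    present and in range exactly on hidden/output nodes; no link targets an
    input node; link endpoints exist; (source, target) pairs unique; K in
    (0, 1], n >= 1, sign in {+1, -1}, known group; every input node bound to
    a feature (and, when a manifest is given, to a feature it contains).
    """
    violations: list[str] = []
    ids = [n.node_id for n in model.nodes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        violations.append(f"duplicate node ids: {dupes}")
    nmap = {n.node_id: n for n in model.nodes}

    n_out = sum(1 for n in model.nodes if n.role == ROLE_OUTPUT)
    if n_out != 1:
        violations.append(f"model must have exactly one output node, found {n_out}")

    for node in model.nodes:
        if node.role not in ROLES:
            violations.append(f"node {node.node_id}: unknown role {node.role!r}")
            continue
        if node.role == ROLE_INPUT:
            if node.m is not None or node.d is not None or node.initial_value is not None:
                violations.append(f"input node {node.node_id} must carry no kinetic parameters")
        else:
            if node.m is None or node.m < 0:
                violations.append(f"node {node.node_id}: production m must be >= 0, got {node.m}")
            if node.d is None or node.d <= 0:
                violations.append(f"node {node.node_id}: degradation d must be > 0, got {node.d}")
            if node.initial_value is None or not (0.0 <= node.initial_value <= 1.0):
                violations.append(
                    f"node {node.node_id}: initial value must be in [0,1], got {node.initial_value}"
                )

    seen_pairs: set[tuple[str, str]] = set()
    for link in model.links:
        tag = f"link {link.source}->{link.target}"
        if link.source not in nmap:
            violations.append(f"{tag}: unknown source node")
        if link.target not in nmap:
            violations.append(f"{tag}: unknown target node")
        elif nmap[link.target].role == ROLE_INPUT:
            violations.append(f"{tag}: input nodes cannot be regulated")
        pair = (link.source, link.target)
        if pair in seen_pairs:
            violations.append(f"{tag}: duplicate (source, target) pair")
        seen_pairs.add(pair)
        if not (0.0 < link.K <= 1.0):
            violations.append(f"{tag}: K must be in (0,1], got {link.K}")
        if link.n < 1 or int(link.n) != link.n:
            violations.append(f"{tag}: Hill exponent must be an integer >= 1, got {link.n}")
        if link.sign not in (1, -1):
            violations.append(f"{tag}: sign must be +1 or -1, got {link.sign}")
        if link.group not in GROUPS:
            violations.append(f"{tag}: unknown group {link.group!r}")

    for node in model.nodes:
        if node.role == ROLE_INPUT and node.node_id not in model.feature_bindings:
            violations.append(f"input node {node.node_id} is not bound to a feature")
    if manifest is not None:
        names = set(manifest.names())
        for node_id, feat in model.feature_bindings.items():
            if feat not in names:
                violations.append(f"binding {node_id}->{feat!r}: feature not in manifest")
    return violations


def complexity(model: RegulatoryModel) -> int:
    """Model complexity = number of nodes + number of links."""
    return len(model.nodes) + len(model.links)


def selected_features(model: RegulatoryModel) -> set[str]:
    """Features bound to inputs with a directed path to the output node.

    This is the model's automatic feature selection: an input that cannot
    influence the output (no directed path) is a structural decoy and its
    feature is not counted as selected.
    """
    out_id = model.output_node.node_id
    # reverse-reachability from the output over the link graph
    preds: dict[str, list[str]] = {}
    for link in model.links:
        preds.setdefault(link.target, []).append(link.source)
    reachable: set[str] = set()
    stack = [out_id]
    while stack:
        node = stack.pop()
        for src in preds.get(node, ()):
            if src not in reachable:
                reachable.add(src)
                stack.append(src)
    return {
        model.feature_bindings[n.node_id]
        for n in model.input_nodes
        if n.node_id in reachable
    }


# ---------------------------------------------------------------------------
# Rendering and (de)serialization
# ---------------------------------------------------------------------------

def _term_text(link: RegulatoryLink, var: str) -> str:
    if link.sign == 1:
        return f"{var}^{link.n}/({var}^{link.n} + {link.K:.6g}^{link.n})"
    return f"{link.K:.6g}^{link.n}/({var}^{link.n} + {link.K:.6g}^{link.n})"


def render_equations(model: RegulatoryModel) -> str:
    """Human-readable ODE listing, one line per hidden/output node.

    Node order is deterministic (output last, hidden nodes sorted by id), so
    two renders of the same model are byte-identical.
    """
    lines = []
    dyn = sorted(model.hidden_nodes, key=lambda n: n.node_id) + [model.output_node]
    for node in dyn:
        incoming = sorted(model.incoming(node.node_id), key=lambda l: l.source)
        suff = [l for l in incoming if l.group == GROUP_SUFFICIENT]
        nec = [l for l in incoming if l.group == GROUP_NECESSARY]
        if not incoming:
            drive = "0"
        else:
            parts = []
            if suff:
                ors = " , ".join(_term_text(l, l.source) for l in suff)
                parts.append(f"OR[{ors}]")
            if nec:
                ands = " * ".join(_term_text(l, l.source) for l in nec)
                parts.append(f"({ands})" if len(nec) > 1 else ands)
            drive = " * ".join(parts) if parts else "1"
        lines.append(
            f"d{node.node_id}/dt = {node.m:.6g} * {drive} - {node.d:.6g} * {node.node_id}"
            f"    [x0 = {node.initial_value:.6g}]"
        )
    return "\n".join(lines) + "\n"


def model_to_dict(model: RegulatoryModel) -> dict:
    return {
        "schema": MODEL_SCHEMA,
        "nodes": [
            {"id": n.node_id, "role": n.role, "m": n.m, "d": n.d, "x0": n.initial_value}
            for n in model.nodes
        ],
        "links": [
            {"source": l.source, "target": l.target, "sign": l.sign,
             "group": l.group, "K": l.K, "n": l.n}
            for l in model.links
        ],
        "bindings": dict(model.feature_bindings),
    }


def model_from_dict(data: Mapping) -> RegulatoryModel:
    if data.get("schema") != MODEL_SCHEMA:
        raise ValueError(f"unsupported model schema {data.get('schema')!r}")
    nodes = []
    for nd in data["nodes"]:
        if nd["role"] not in ROLES:
            raise ValueError(f"unknown node role {nd['role']!r}")
        nodes.append(Node(nd["id"], nd["role"], nd.get("m"), nd.get("d"), nd.get("x0")))
    links = []
    for ld in data["links"]:
        if ld["group"] not in GROUPS:
            raise ValueError(f"unknown link group {ld['group']!r}")
        links.append(
            RegulatoryLink(ld["source"], ld["target"], int(ld["sign"]),
                           ld["group"], float(ld["K"]), int(ld["n"]))
        )
    return RegulatoryModel(nodes, links, dict(data.get("bindings", {})))


def save_model(model: RegulatoryModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> RegulatoryModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
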