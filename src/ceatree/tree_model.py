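"""Decision-tree engine for short-horizon cost-effectiveness models.

A strategy (treatment arm) is one tree.  Chance nodes carry observed
branch counts plus an estimation regime; terminals carry a cost payoff
in GBP (2011 values) and a vector of binary clinical outcomes —
survival to 28 days, survival to 1 year, and morbidity-free survival to
1 year (MFS).  Evaluation is by expected-value rollback; an independent
path-enumeration routine serves as a cross-check.

No discounting or half-cycle machinery: the horizon is at most one
year, for which a single-pass tree is the appropriate model.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import estimation

__all__ = [
    "HealthState",
    "EffectVector",
    "TERMINAL_EFFECTS",
    "ProbabilitySpec",
    "TerminalPayoff",
    "Branch",
    "Node",
    "DecisionTree",
    "StrategyResult",
    "ValidationReport",
    "PathOutcome",
    "chance",
    "terminal",
    "validate_tree",
    "resolve_probs",
    "enumerate_paths",
    "rollback",
]

EFFECT_NAMES = ("surv28", "surv1y", "mfs")


class HealthState(str, Enum):
    """Closed set of terminal health states for the bladder-outflow
    obstruction (LUTO) pathway model.

    Pregnancy losses before 24 weeks are split by cause (elective
    termination, chorioamnionitis, unexplained miscarriage); later
    deaths by timing (in utero after 24 weeks; within 24 hours of
    birth; 24 hours to 28 days; 28 days to 1 year); survivors to one
    year by renal-impairment grade.
    """

    MISCARRIAGE = "miscarriage"
    TERMINATION = "termination"
    CHORIOAMNIONITIS_LOSS = "chorioamnionitis_loss"
    DIED_IN_UTERO = "died_in_utero"
    DIED_AT_DELIVERY = "died_at_delivery"
    NEONATAL_DEATH = "neonatal_death"
    INFANT_DEATH_1Y = "infant_death_1y"
    ALIVE_NO_MORBIDITY = "alive_no_morbidity"
    ALIVE_MILD_RENAL = "alive_mild_renal"
    ALIVE_MODERATE_RENAL = "alive_moderate_renal"
    ALIVE_SEVERE_RENAL = "alive_severe_renal"


@dataclass(frozen=True)
class EffectVector:
    """(surv28, surv1y, mfs) payoff triple.

    At terminals each component is 0 or 1; after rollback each is an
    expectation in [0, 1].  The ordering mfs <= surv1y <= surv28 holds
    at every terminal and is preserved by expectation.
    """

    surv28: float
    surv1y: float
    mfs: float

    def as_array(self) -> np.ndarray:
        return np.array([self.surv28, self.surv1y, self.mfs], dtype=float)

    @staticmethod
    def from_array(a) -> "EffectVector":
        return EffectVector(float(a[0]), float(a[1]), float(a[2]))


#: Structural outcome payoffs implied by each terminal health state.
TERMINAL_EFFECTS: dict[HealthState, EffectVector] = {
    HealthState.MISCARRIAGE: EffectVector(0, 0, 0),
    HealthState.TERMINATION: EffectVector(0, 0, 0),
    HealthState.CHORIOAMNIONITIS_LOSS: EffectVector(0, 0, 0),
    HealthState.DIED_IN_UTERO: EffectVector(0, 0, 0),
    HealthState.DIED_AT_DELIVERY: EffectVector(0, 0, 0),
    HealthState.NEONATAL_DEATH: EffectVector(0, 0, 0),
    HealthState.INFANT_DEATH_1Y: EffectVector(1, 0, 0),
    HealthState.ALIVE_NO_MORBIDITY: EffectVector(1, 1, 1),
    HealthState.ALIVE_MILD_RENAL: EffectVector(1, 1, 0),
    HealthState.ALIVE_MODERATE_RENAL: EffectVector(1, 1, 0),
    HealthState.ALIVE_SEVERE_RENAL: EffectVector(1, 1, 0),
}


@dataclass
class ProbabilitySpec:
    """Observed branch counts plus the regime turning them into
    probabilities: ``mle``, ``uniform_prior`` or ``fixed`` (the latter
    uses ``fixed_values`` verbatim)."""

    counts: tuple
    regime: str = "mle"
    fixed_values: tuple | None = None

    def __post_init__(self):
        self.counts = tuple(int(c) for c in self.counts)
        if self.fixed_values is not None:
            self.fixed_values = tuple(float(v) for v in self.fixed_values)


@dataclass
class TerminalPayoff:
    cost: float
    effects: EffectVector
    state: HealthState | None = None


@dataclass
class Branch:
    label: str
    child: str


@dataclass
class Node:
    id: str
    kind: str  # "chance" | "terminal" | "decision"
    branches: tuple = ()
    spec: ProbabilitySpec | None = None
    payoff: TerminalPayoff | None = None


@dataclass
class DecisionTree:
    strategy: str
    root: str
    nodes: dict = field(default_factory=dict)

    def copy(self) -> "DecisionTree":
        return copy.deepcopy(self)

    def chance_nodes(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.kind == "chance"]

    def terminals(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.kind == "terminal"]

    def parent_map(self) -> dict:
        """child id -> (parent id, branch index); assumes valid tree."""
        parents = {}
        for node in self.nodes.values():
            for i, br in enumerate(node.branches):
                parents[br.child] = (node.id, i)
        return parents


@dataclass
class StrategyResult:
    strategy: str
    expected_cost: float
    expected_effects: EffectVector


@dataclass
class PathOutcome:
    terminal: str
    probability: float
    payoff: TerminalPayoff


def chance(node_id: str, branches, spec: ProbabilitySpec | None = None) -> Node:
    return Node(node_id, "chance", tuple(Branch(l, c) for l, c in branches), spec=spec)


def terminal(node_id: str, cost: float = 0.0, state: HealthState | None = None,
             effects: EffectVector | None = None) -> Node:
    if effects is None:
        if state is None:
            raise ValueError("terminal needs a health state or explicit effects")
        effects = TERMINAL_EFFECTS[state]
    return Node(node_id, "terminal", payoff=TerminalPayoff(float(cost), effects, state))


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_tree(tree: DecisionTree) -> ValidationReport:
    """Structural checks; violations are reported, never raised.

    Flags: missing/duplicate parentage ("not a tree"), cycles, orphan
    nodes, chance-node arity vs. count-vector mismatches, fixed
    probabilities not summing to 1, terminals without payoffs, and
    decision nodes with more than one branch (a single-strategy tree
    has its decision pre-made; alternatives belong in separate trees).
    """
    v: list[str] = []
    if tree.root not in tree.nodes:
        return ValidationReport([f"root node {tree.root!r} not defined"])

    parent_count: dict[str, int] = {nid: 0 for nid in tree.nodes}
    for node in tree.nodes.values():
        for br in node.branches:
            if br.child not in tree.nodes:
                v.append(f"branch {node.id}->{br.child} targets unknown node")
            else:
                parent_count[br.child] += 1
    for nid, k in parent_count.items():
        if k > 1:
            v.append(f"not a tree: node {nid!r} has {k} parents")
    if parent_count.get(tree.root, 0) > 0:
        v.append(f"not a tree: root {tree.root!r} has a parent")

    # reachability / cycles (DFS from root)
    seen: set[str] = set()
    stack = [tree.root]
    on_path: set[str] = set()

    def dfs(nid: str):
        if nid in on_path:
            v.append(f"cycle through node {nid!r}")
            return
        if nid in seen or nid not in tree.nodes:
            return
        seen.add(nid)
        on_path.add(nid)
        for br in tree.nodes[nid].branches:
            dfs(br.child)
        on_path.discard(nid)

    dfs(tree.root)
    for nid in tree.nodes:
        if nid not in seen:
            v.append(f"orphan node {nid!r} unreachable from root")

    for node in tree.nodes.values():
        if node.kind == "terminal":
            if node.branches:
                v.append(f"terminal {node.id!r} has outgoing branches")
            if node.payoff is None:
                v.append(f"terminal {node.id!r} without payoff")
        elif node.kind == "chance":
            if len(node.branches) < 2:
                v.append(f"chance node {node.id!r} has fewer than 2 branches")
            if node.spec is None:
                v.append(f"chance node {node.id!r} has no probability spec")
            else:
                s = node.spec
                if len(s.counts) != len(node.branches):
                    v.append(
                        f"chance node {node.id!r}: {len(s.counts)} counts for "
                        f"{len(node.branches)} branches"
                    )
                if any(c < 0 for c in s.counts):
                    v.append(f"chance node {node.id!r} has negative counts")
                if s.regime == "fixed":
                    if s.fixed_values is None or len(s.fixed_values) != len(node.branches):
                        v.append(f"chance node {node.id!r}: fixed regime without matching fixed_values")
                    elif abs(sum(s.fixed_values) - 1.0) > 1e-9:
                        v.append(
                            f"chance node {node.id!r}: probabilities sum to "
                            f"{sum(s.fixed_values):g}"
                        )
                elif s.regime not in ("mle", "uniform_prior"):
                    v.append(f"chance node {node.id!r}: unknown regime {s.regime!r}")
        elif node.kind == "decision":
            if len(node.branches) != 1:
                v.append(
                    f"decision node {node.id!r} has {len(node.branches)} branches; "
                    "single-strategy trees carry one pre-chosen branch"
                )
        else:
            v.append(f"node {node.id!r} has unknown kind {node.kind!r}")
    return ValidationReport(v)


# ---------------------------------------------------------------------------
# probability resolution and evaluation

def resolve_probs(tree: DecisionTree, regime: str | None = None) -> dict:
    """Point probability vector per chance node.

    ``regime`` overrides each node's own regime (``mle`` or
    ``uniform_prior``) except where a node is ``fixed``, which always
    wins.
    """
    out = {}
    for node in tree.chance_nodes():
        s = node.spec
        if s is None:
            raise ValueError(f"chance node {node.id!r} has no probability spec")
        r = s.regime if (regime is None or s.regime == "fixed") else regime
        if r == "fixed":
            out[node.id] = np.asarray(s.fixed_values, dtype=float)
        elif r == "mle":
            if sum(s.counts) == 0:
                # node is reached with probability 0 under MLE (flow
                # conservation: its parent branch count is also 0), so any
                # proper vector is inert; use uniform.
                out[node.id] = np.full(len(s.counts), 1.0 / len(s.counts))
            else:
                out[node.id] = estimation.mle_probs(s.counts)
        elif r == "uniform_prior":
            out[node.id] = estimation.uniform_prior_probs(s.counts)
        else:
            raise ValueError(f"unknown regime {r!r} at node {node.id!r}")
    return out


def _node_probs(tree: DecisionTree, probs: dict, node: Node) -> np.ndarray:
    try:
        p = probs[node.id]
    except KeyError:
        raise ValueError(f"unresolved chance node {node.id!r}") from None
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != len(node.branches):
        raise ValueError(f"probability vector arity mismatch at node {node.id!r}")
    return p


def enumerate_paths(tree: DecisionTree, probs: dict) -> list:
    """All root-to-terminal paths with their probabilities and payoffs.

    Path probability is the product of branch probabilities along the
    path; across a resolved tree they sum to 1 (to 1e-9).  This is the
    brute-force oracle against which :func:`rollback` is checked.
    """
    out: list[PathOutcome] = []

    def walk(nid: str, p: float):
        node = tree.nodes[nid]
        if node.kind == "terminal":
            if node.payoff is None:
                raise ValueError(f"terminal {nid!r} without payoff")
            out.append(PathOutcome(nid, p, node.payoff))
        elif node.kind == "decision":
            walk(node.branches[0].child, p)
        else:
            bp = _node_probs(tree, probs, node)
            for prob, br in zip(bp, node.branches):
                walk(br.child, p * float(prob))

    walk(tree.root, 1.0)
    return out


def rollback(tree: DecisionTree, probs: dict) -> StrategyResult:
    """Expected cost and expected effect vector by bottom-up rollback."""

    def value(nid: str):
        node = tree.nodes[nid]
        if node.kind == "terminal":
            if node.payoff is None:
                raise ValueError(f"terminal {nid!r} without payoff")
            return node.payoff.cost, node.payoff.effects.as_array()
        if node.kind == "decision":
            return value(node.branches[0].child)
        bp = _node_probs(tree, probs, node)
        cost = 0.0
        eff = np.zeros(3)
        for prob, br in zip(bp, node.branches):
            c, e = value(br.child)
            cost += float(prob) * c
            eff += float(prob) * e
        return cost, eff

    cost, eff = value(tree.root)
    return StrategyResult(tree.strategy, cost, EffectVector.from_array(eff))
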