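"""Serialisation: tree definitions as YAML, provenance sidecars.

A tree file is a YAML stream with one document per strategy.  Each
document has keys ``strategy``, ``root``, ``nodes`` (id -> kind),
``branches`` (parent/label/child records), ``probability_specs``
(chance-node id -> counts/regime/fixed_values) and ``payoffs``
(terminal id -> cost plus either a health-state label or explicit
effect components).  Round-tripping a tree through this format yields
a structurally identical object.
"""

from __future__ import annotations

import hashlib

import yaml

from .tree_model import (
    Branch,
    DecisionTree,
    EffectVector,
    HealthState,
    Node,
    ProbabilitySpec,
    TerminalPayoff,
)

__all__ = [
    "tree_to_dict",
    "tree_from_dict",
    "save_trees",
    "load_trees",
    "sha256_of_file",
]


def tree_to_dict(tree: DecisionTree) -> dict:
    doc = {
        "strategy": tree.strategy,
        "root": tree.root,
        "nodes": {n.id: n.kind for n in tree.nodes.values()},
        "branches": [
            {"parent": n.id, "label": br.label, "child": br.child}
            for n in tree.nodes.values() for br in n.branches
        ],
        "probability_specs": {},
        "payoffs": {},
    }
    for n in tree.nodes.values():
        if n.spec is not None:
            spec = {"counts": list(n.spec.counts), "regime": n.spec.regime}
            if n.spec.fixed_values is not None:
                spec["fixed_values"] = [float(v) for v in n.spec.fixed_values]
            doc["probability_specs"][n.id] = spec
        if n.payoff is not None:
            p = {"cost": float(n.payoff.cost)}
            if n.payoff.state is not None:
                p["state"] = n.payoff.state.value
            else:
                e = n.payoff.effects
                p["effects"] = {"surv28": e.surv28, "surv1y": e.surv1y, "mfs": e.mfs}
            doc["payoffs"][n.id] = p
    return doc


def tree_from_dict(doc: dict) -> DecisionTree:
    nodes: dict[str, Node] = {}
    branches: dict[str, list[Branch]] = {nid: [] for nid in doc["nodes"]}
    for b in doc.get("branches", []):
        branches[b["parent"]].append(Branch(b["label"], b["child"]))
    for nid, kind in doc["nodes"].items():
        spec = None
        raw = doc.get("probability_specs", {}).get(nid)
        if raw is not None:
            spec = ProbabilitySpec(tuple(raw["counts"]), raw.get("regime", "mle"),
                                   tuple(raw["fixed_values"]) if raw.get("fixed_values") else None)
        payoff = None
        rawp = doc.get("payoffs", {}).get(nid)
        if rawp is not None:
            if "state" in rawp:
                state = HealthState(rawp["state"])
                from .tree_model import TERMINAL_EFFECTS
                payoff = TerminalPayoff(float(rawp["cost"]), TERMINAL_EFFECTS[state], state)
            else:
                e = rawp["effects"]
                payoff = TerminalPayoff(float(rawp["cost"]),
                                        EffectVector(e["surv28"], e["surv1y"], e["mfs"]))
        nodes[nid] = Node(nid, kind, tuple(branches[nid]), spec=spec, payoff=payoff)
    return DecisionTree(doc["strategy"], doc["root"], nodes)


def save_trees(trees, path) -> None:
    """Write an iterable (or arm-keyed mapping) of trees as a YAML
    stream, one document per strategy."""
    seq = trees.values() if isinstance(trees, dict) else trees
    with open(path, "w") as fh:
        yaml.safe_dump_all([tree_to_dict(t) for t in seq], fh, sort_keys=False)


def load_trees(path) -> dict:
    with open(path) as fh:
        docs = list(yaml.safe_load_all(fh))
    trees = [tree_from_dict(d) for d in docs if d]
    return {t.strategy: t for t in trees}


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
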