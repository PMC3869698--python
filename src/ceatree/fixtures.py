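"""Reconstructed pathway trees for the two trial strategies.

The published model figures describe, without printing exact branch
counts, the clinical pathways of a fetus with lower urinary tract
obstruction from randomisation to one year: possible pregnancy loss
before 24 weeks (termination / chorioamnionitis / miscarriage), death
in utero after 24 weeks, death within 24 hours of delivery, neonatal
death (24 h – 28 d), infant death before 1 year, and survival to one
year with no / mild / moderate / severe renal impairment.  The shunted
(VAS) arm additionally branches at the top on the course of the shunt
itself: uncomplicated, dislodgement requiring re-insertion, or
chorioamnionitis ending the pregnancy — the first two leading to
structurally identical subtrees with their own probabilities.

These trees are a faithful reconstruction of that textual description,
not a transcription of unpublished figures; they are the structures
the cohort module fills with observed counts and cost payoffs.
"""

from __future__ import annotations

import numpy as np

from .cohort import GroupedCohort, node_counts
from .tree_model import (
    DecisionTree,
    HealthState,
    ProbabilitySpec,
    chance,
    terminal,
)

__all__ = [
    "conservative_tree",
    "vas_tree",
    "arm_tree",
    "terminal_of",
    "populate_tree",
    "trees_from_cohort",
]

_HS = HealthState


def _pathway_subtree(prefix: str, include_chorio_loss: bool) -> list:
    """Nodes for one loss/continue pathway subtree.

    Root of the subtree is ``{prefix}_gest``.  The conservative arm
    keeps chorioamnionitis as a spontaneous early-loss cause; in the
    VAS arm chorioamnionitis is a shunt complication handled above the
    subtree, so its early-loss split has two causes.
    """
    loss_branches = [("termination", f"{prefix}_term")]
    if include_chorio_loss:
        loss_branches.append(("chorioamnionitis", f"{prefix}_chorio"))
    loss_branches.append(("miscarriage", f"{prefix}_misc"))

    nodes = [
        chance(f"{prefix}_gest",
               [("loss_lt24w", f"{prefix}_loss_type"),
                ("continue", f"{prefix}_pregnancy")],
               ProbabilitySpec((0, 0))),
        chance(f"{prefix}_loss_type", loss_branches,
               ProbabilitySpec((0,) * len(loss_branches))),
        chance(f"{prefix}_pregnancy",
               [("died_in_utero", f"{prefix}_diu"),
                ("live_birth", f"{prefix}_perinatal")],
               ProbabilitySpec((0, 0))),
        chance(f"{prefix}_perinatal",
               [("died_at_delivery", f"{prefix}_dad"),
                ("neonatal_death", f"{prefix}_nnd"),
                ("alive_28d", f"{prefix}_year1")],
               ProbabilitySpec((0, 0, 0))),
        chance(f"{prefix}_year1",
               [("infant_death", f"{prefix}_inf"),
                ("alive_1y", f"{prefix}_morbidity")],
               ProbabilitySpec((0, 0))),
        chance(f"{prefix}_morbidity",
               [("no_morbidity", f"{prefix}_alive_none"),
                ("mild_renal", f"{prefix}_alive_mild"),
                ("moderate_renal", f"{prefix}_alive_mod"),
                ("severe_renal", f"{prefix}_alive_sev")],
               ProbabilitySpec((0, 0, 0, 0))),
        terminal(f"{prefix}_term", state=_HS.TERMINATION),
        terminal(f"{prefix}_misc", state=_HS.MISCARRIAGE),
        terminal(f"{prefix}_diu", state=_HS.DIED_IN_UTERO),
        terminal(f"{prefix}_dad", state=_HS.DIED_AT_DELIVERY),
        terminal(f"{prefix}_nnd", state=_HS.NEONATAL_DEATH),
        terminal(f"{prefix}_inf", state=_HS.INFANT_DEATH_1Y),
        terminal(f"{prefix}_alive_none", state=_HS.ALIVE_NO_MORBIDITY),
        terminal(f"{prefix}_alive_mild", state=_HS.ALIVE_MILD_RENAL),
        terminal(f"{prefix}_alive_mod", state=_HS.ALIVE_MODERATE_RENAL),
        terminal(f"{prefix}_alive_sev", state=_HS.ALIVE_SEVERE_RENAL),
    ]
    if include_chorio_loss:
        nodes.append(terminal(f"{prefix}_chorio", state=_HS.CHORIOAMNIONITIS_LOSS))
    return nodes


def conservative_tree() -> DecisionTree:
    nodes = _pathway_subtree("c", include_chorio_loss=True)
    return DecisionTree("conservative", "c_gest", {n.id: n for n in nodes})


def vas_tree() -> DecisionTree:
    nodes = [
        chance("v_course",
               [("uncomplicated", "vA_gest"),
                ("dislodged_reinserted", "vB_gest"),
                ("chorioamnionitis", "v_chorio")],
               ProbabilitySpec((0, 0, 0))),
        terminal("v_chorio", state=_HS.CHORIOAMNIONITIS_LOSS),
    ]
    nodes += _pathway_subtree("vA", include_chorio_loss=False)
    nodes += _pathway_subtree("vB", include_chorio_loss=False)
    return DecisionTree("vas", "v_course", {n.id: n for n in nodes})


def arm_tree(arm: str) -> DecisionTree:
    if arm == "vas":
        return vas_tree()
    if arm == "conservative":
        return conservative_tree()
    raise ValueError(f"unknown arm {arm!r}")


_STATE_SUFFIX = {
    _HS.TERMINATION: "term",
    _HS.MISCARRIAGE: "misc",
    _HS.DIED_IN_UTERO: "diu",
    _HS.DIED_AT_DELIVERY: "dad",
    _HS.NEONATAL_DEATH: "nnd",
    _HS.INFANT_DEATH_1Y: "inf",
    _HS.ALIVE_NO_MORBIDITY: "alive_none",
    _HS.ALIVE_MILD_RENAL: "alive_mild",
    _HS.ALIVE_MODERATE_RENAL: "alive_mod",
    _HS.ALIVE_SEVERE_RENAL: "alive_sev",
}


def terminal_of(record, arm: str) -> str:
    """Terminal id a patient reaches in the given arm's tree.

    In the VAS tree, chorioamnionitis losses take the complication
    branch at the root; the re-insertion subtree (B) is entered by
    patients with more than one shunt insertion, everyone else —
    including crossovers who never received a shunt — follows the
    uncomplicated subtree (A).
    """
    state = record.final_state
    if arm == "conservative":
        if state == _HS.CHORIOAMNIONITIS_LOSS:
            return "c_chorio"
        return f"c_{_STATE_SUFFIX[state]}"
    if arm == "vas":
        if state == _HS.CHORIOAMNIONITIS_LOSS:
            return "v_chorio"
        prefix = "vB" if record.shunt_insertions >= 2 else "vA"
        return f"{prefix}_{_STATE_SUFFIX[state]}"
    raise ValueError(f"unknown arm {arm!r}")


def populate_tree(tree: DecisionTree, arm_patients: list, arm: str,
                  regime: str = "mle") -> DecisionTree:
    """Fill a structural tree with the arm's observed counts and cost
    payoffs; returns a new tree.

    Chance-node counts come from routing every patient to its terminal.
    A terminal's cost payoff is the mean total cost of the patients
    reaching it; a terminal nobody reaches inherits the nearest
    ancestor's subtree mean (ultimately the arm mean), so regimes that
    put positive probability on unobserved branches do not price those
    states at zero.
    """
    out = tree.copy()
    counts = node_counts(arm_patients, out, lambda p: terminal_of(p, arm))
    for nid, c in counts.items():
        spec = out.nodes[nid].spec
        out.nodes[nid].spec = ProbabilitySpec(tuple(int(x) for x in c), regime,
                                              spec.fixed_values if spec else None)

    by_terminal: dict[str, list[float]] = {}
    for p in arm_patients:
        by_terminal.setdefault(terminal_of(p, arm), []).append(p.total_cost)

    # subtree (sum, n) of observed costs per node, bottom-up
    subtree: dict[str, tuple[float, int]] = {}

    def collect(nid: str) -> tuple[float, int]:
        node = out.nodes[nid]
        if node.kind == "terminal":
            costs = by_terminal.get(nid, [])
            subtree[nid] = (float(sum(costs)), len(costs))
        else:
            tot, n = 0.0, 0
            for br in node.branches:
                s, k = collect(br.child)
                tot, n = tot + s, n + k
            subtree[nid] = (tot, n)
        return subtree[nid]

    collect(out.root)
    parents = out.parent_map()
    for t in out.terminals():
        nid = t.id
        while subtree[nid][1] == 0 and nid != out.root:
            nid = parents[nid][0]
        s, n = subtree[nid]
        t.payoff.cost = s / n if n else 0.0
    return out


def trees_from_cohort(grouped: GroupedCohort, regime: str = "mle") -> dict:
    """Populated {arm: DecisionTree} for both strategies."""
    return {a: populate_tree(arm_tree(a), grouped.arm(a), a, regime) for a in grouped.arms}
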