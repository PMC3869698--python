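"""Shared test utilities: random tree generation and a deterministic
cohort whose state counts equal the generator's default pathway table."""

from __future__ import annotations

import itertools

import numpy as np

from ceatree.cohort import COST_CATEGORIES, SHUNT_PROCEDURE_COST, PatientRecord
from ceatree.tree_model import (
    TERMINAL_EFFECTS,
    DecisionTree,
    HealthState,
    ProbabilitySpec,
    chance,
    terminal,
)

_HS = HealthState
STATES = list(HealthState)


def random_tree(rng: np.random.Generator, max_depth: int = 4,
                strategy: str = "random") -> DecisionTree:
    """Random valid tree: chance nodes with 2-3 branches and positive
    counts, terminals with health-state payoffs and uniform costs."""
    counter = itertools.count()
    nodes = {}

    def build(depth: int) -> str:
        nid = f"n{next(counter)}"
        if depth > 0 and (depth >= max_depth or rng.random() < 0.35):
            state = STATES[rng.integers(len(STATES))]
            nodes[nid] = terminal(nid, cost=float(rng.uniform(0, 10_000)), state=state)
        else:
            k = int(rng.integers(2, 4))
            children = [build(depth + 1) for _ in range(k)]
            counts = tuple(int(c) for c in rng.integers(1, 20, size=k))
            nodes[nid] = chance(nid, [(f"b{i}", c) for i, c in enumerate(children)],
                                ProbabilitySpec(counts))
        return nid

    root = build(0)
    return DecisionTree(strategy, root, nodes)


def make_patient(pid: str, arm_rand: str, arm_recv: str, state: HealthState,
                 total: float = 5_000.0, insertions: int | None = None,
                 terminated: bool | None = None) -> PatientRecord:
    if insertions is None:
        insertions = 1 if arm_recv == "vas" else 0
    comp = {c: 0.0 for c in COST_CATEGORIES}
    shunt = SHUNT_PROCEDURE_COST * insertions if arm_recv == "vas" else 0.0
    comp["shunt_insertion"] = shunt
    comp["other"] = max(total - shunt, 0.0)
    eff = TERMINAL_EFFECTS[state]
    return PatientRecord(
        id=pid, arm_randomised=arm_rand, arm_received=arm_recv,
        terminated_post_randomisation=(state == _HS.TERMINATION
                                       if terminated is None else terminated),
        final_state=state, shunt_insertions=insertions, cost_components=comp,
        surv28=int(eff.surv28), surv1y=int(eff.surv1y), mfs=int(eff.mfs),
    )


#: (state, count) rows matching the generator's default pathway tables.
VAS_STATE_COUNTS = [
    (_HS.TERMINATION, 1), (_HS.CHORIOAMNIONITIS_LOSS, 1), (_HS.MISCARRIAGE, 1),
    (_HS.DIED_IN_UTERO, 2), (_HS.DIED_AT_DELIVERY, 1), (_HS.NEONATAL_DEATH, 2),
    (_HS.INFANT_DEATH_1Y, 1), (_HS.ALIVE_NO_MORBIDITY, 1),
    (_HS.ALIVE_MILD_RENAL, 2), (_HS.ALIVE_MODERATE_RENAL, 2),
    (_HS.ALIVE_SEVERE_RENAL, 2),
]
CONS_STATE_COUNTS = [
    (_HS.TERMINATION, 2), (_HS.MISCARRIAGE, 1), (_HS.DIED_IN_UTERO, 3),
    (_HS.DIED_AT_DELIVERY, 2), (_HS.NEONATAL_DEATH, 3), (_HS.INFANT_DEATH_1Y, 1),
    (_HS.ALIVE_MILD_RENAL, 1), (_HS.ALIVE_MODERATE_RENAL, 1),
    (_HS.ALIVE_SEVERE_RENAL, 1),
]


def exact_margin_cohort() -> list:
    """Deterministic 16+15 cohort reproducing the published margins
    exactly: survival 8/16 vs 4/15 (28 d) and 7/16 vs 3/15 (1 yr),
    crossovers 3 and 2, three VAS-arm cost outliers above £50,000.
    Two shunted survivors carry a re-inserted (dislodged) shunt."""
    patients = []
    i = 0
    for state, k in VAS_STATE_COUNTS:
        for _ in range(k):
            i += 1
            recv = "conservative" if i <= 3 else "vas"
            ins = 0 if recv == "conservative" else (2 if state == _HS.ALIVE_MILD_RENAL else 1)
            total = {_HS.ALIVE_SEVERE_RENAL: 60_000.0,
                     _HS.ALIVE_MODERATE_RENAL: 26_000.0}.get(state, 9_000.0)
            patients.append(make_patient(f"vas-{i:02d}", "vas", recv, state,
                                         total=total, insertions=ins))
    # third outlier: one moderate-renal shunted survivor
    patients[-3].cost_components["other"] = 70_000.0
    j = 0
    for state, k in CONS_STATE_COUNTS:
        for _ in range(k):
            j += 1
            recv = "vas" if j <= 2 else "conservative"
            patients.append(make_patient(f"con-{j:02d}", "conservative", recv, state,
                                         total=6_000.0))
    return patients
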