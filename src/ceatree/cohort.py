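"""Patient-level trial records and the analysis views derived from them.

One row per randomised participant: randomised and received arm,
whether the pregnancy was terminated after randomisation, the final
health state, shunt-insertion count, an itemised cost breakdown in GBP
(2011 values), and the three binary outcomes.  The module turns a
cohort into the inputs the tree model needs — per-arm groupings (ITT,
per-protocol, as-treated), branch counts at every chance node, cost
payoffs — and implements the deterministic sensitivity transformations
and the summary statistics reported alongside the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tree_model import TERMINAL_EFFECTS, DecisionTree, HealthState

__all__ = [
    "COST_CATEGORIES",
    "ARMS",
    "VIEWS",
    "PatientRecord",
    "GroupedCohort",
    "ShuntCostBreakdown",
    "DEFAULT_SHUNT_BREAKDOWN",
    "SHUNT_PROCEDURE_COST",
    "shunt_cost",
    "build_view",
    "node_counts",
    "scale_shunt_costs",
    "substitute_outliers",
    "survival_summary",
    "required_qaly_gain",
    "patients_to_frame",
    "patients_from_frame",
    "write_patients_csv",
    "read_patients_csv",
]

ARMS = ("vas", "conservative")
VIEWS = ("itt", "per_protocol", "as_treated")
COST_CATEGORIES = (
    "antenatal_scans",
    "karyotyping",
    "shunt_insertion",
    "delivery",
    "neonatal_admission",
    "procedures",
    "renal_care",
    "other",
)


@dataclass
class PatientRecord:
    id: str
    arm_randomised: str
    arm_received: str
    terminated_post_randomisation: bool
    final_state: HealthState
    shunt_insertions: int
    cost_components: dict
    surv28: int
    surv1y: int
    mfs: int

    def __post_init__(self):
        if self.arm_randomised not in ARMS or self.arm_received not in ARMS:
            raise ValueError(f"patient {self.id}: arms must be one of {ARMS}")
        self.final_state = HealthState(self.final_state)
        if self.arm_received == "vas" and self.shunt_insertions < 1:
            raise ValueError(f"patient {self.id}: received VAS but shunt_insertions < 1")
        missing = set(COST_CATEGORIES) - set(self.cost_components)
        if missing:
            raise ValueError(f"patient {self.id}: missing cost components {sorted(missing)}")
        if any(v < 0 for v in self.cost_components.values()):
            raise ValueError(f"patient {self.id}: negative cost component")
        eff = TERMINAL_EFFECTS[self.final_state]
        if (self.surv28, self.surv1y, self.mfs) != (eff.surv28, eff.surv1y, eff.mfs):
            raise ValueError(
                f"patient {self.id}: outcome flags inconsistent with state "
                f"{self.final_state.value}"
            )

    @property
    def total_cost(self) -> float:
        return float(sum(self.cost_components.values()))


@dataclass
class GroupedCohort:
    """Two-arm partition of retained patients under one analysis view."""

    view: str
    arms: dict  # arm label -> list[PatientRecord]

    def arm(self, label: str) -> list:
        return self.arms[label]

    def sizes(self) -> dict:
        return {k: len(v) for k, v in self.arms.items()}


# ---------------------------------------------------------------------------
# bottom-up shunt costing

@dataclass(frozen=True)
class ShuntCostBreakdown:
    """Itemised cost of one vesico-amniotic shunt placement: device,
    guidance scan, 30 min consultant counselling, and the insertion
    itself (30 min consultant + 30 min senior-nurse assistant)."""

    shunt_device: float
    scan: float
    counselling: float
    consultant_insertion_time: float
    assistant_insertion_time: float

    def components(self) -> tuple:
        return (self.shunt_device, self.scan, self.counselling,
                self.consultant_insertion_time, self.assistant_insertion_time)


#: 2011 unit costs (device and scan from the treating centre;
#: staff time from PSSRU 2011).  They sum to £821.80 per insertion.
DEFAULT_SHUNT_BREAKDOWN = ShuntCostBreakdown(154.30, 445.50, 80.50, 80.50, 61.00)
SHUNT_PROCEDURE_COST = 821.80


def shunt_cost(breakdown: ShuntCostBreakdown = DEFAULT_SHUNT_BREAKDOWN,
               scale_factor: float = 1.0) -> float:
    """Bottom-up procedure cost, exact to the penny.

    Components are summed in integer pence to avoid float drift;
    ``scale_factor`` supports the doubled/halved-cost sensitivity
    scenarios.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    if any(c < 0 for c in breakdown.components()):
        raise ValueError("negative cost component")
    pence = sum(round(c * 100) for c in breakdown.components())
    return round(pence * scale_factor) / 100.0


# ---------------------------------------------------------------------------
# analysis views

def build_view(patients: list, view: str) -> GroupedCohort:
    """Partition the cohort under an analysis view.

    ``itt`` groups by randomised arm; ``per_protocol`` additionally
    drops patients whose pregnancy was terminated after randomisation
    (from either arm); ``as_treated`` groups by the arm actually
    received, regrouping crossovers.
    """
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")
    retained = patients
    if view == "per_protocol":
        retained = [p for p in patients if not p.terminated_post_randomisation]
    key = "arm_received" if view == "as_treated" else "arm_randomised"
    arms = {a: [p for p in retained if getattr(p, key) == a] for a in ARMS}
    for a, members in arms.items():
        if not members:
            raise ValueError(f"empty {a!r} arm under the {view!r} view")
    return GroupedCohort(view, arms)


def node_counts(arm_patients: list, tree: DecisionTree, terminal_of) -> dict:
    """Observed branch counts at every chance node of an arm's tree.

    ``terminal_of`` maps a PatientRecord to the id of the terminal it
    reaches.  Each patient increments the count of every branch on the
    root-to-terminal path, so counts at a node sum to the number of
    patients flowing through it and the root counts sum to arm size.
    """
    counts = {n.id: np.zeros(len(n.branches), dtype=int) for n in tree.chance_nodes()}
    parents = tree.parent_map()
    for p in arm_patients:
        tid = terminal_of(p)
        if tid not in tree.nodes or tree.nodes[tid].kind != "terminal":
            raise ValueError(
                f"patient {p.id}: state {p.final_state.value!r} maps to "
                f"{tid!r}, not a terminal of tree {tree.strategy!r}"
            )
        nid = tid
        while nid != tree.root:
            parent, branch_idx = parents[nid]
            if tree.nodes[parent].kind == "chance":
                counts[parent][branch_idx] += 1
            nid = parent
    return counts


# ---------------------------------------------------------------------------
# deterministic sensitivity transformations

def scale_shunt_costs(patients: list, factor: float) -> list:
    """Scale every patient's shunt-procedure cost component by
    ``factor`` (doubled/halved-VAS-cost scenarios).  Touches any
    patient who received a shunt, including comparator-arm crossovers."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    out = []
    for p in patients:
        comp = dict(p.cost_components)
        comp["shunt_insertion"] = comp["shunt_insertion"] * factor
        out.append(replace(p, cost_components=comp))
    return out


def substitute_outliers(patients: list, threshold: float = 50_000.0) -> list:
    """Replace extreme total costs with the same randomised arm's
    non-outlier mean total cost.

    Every patient whose total cost exceeds ``threshold`` has all cost
    components rescaled proportionally so the total equals the mean
    total of that arm's non-outlier patients; everyone else is
    untouched.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ref_mean = {}
    for a in ARMS:
        keep = [p.total_cost for p in patients
                if p.arm_randomised == a and p.total_cost <= threshold]
        members = [p for p in patients if p.arm_randomised == a]
        if members and not keep:
            raise ValueError(f"arm {a!r} consists entirely of outliers; no reference mean")
        ref_mean[a] = float(np.mean(keep)) if keep else math.nan
    out = []
    for p in patients:
        if p.total_cost > threshold:
            scale = ref_mean[p.arm_randomised] / p.total_cost
            comp = {k: v * scale for k, v in p.cost_components.items()}
            out.append(replace(p, cost_components=comp))
        else:
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# summaries

def survival_summary(grouped: GroupedCohort) -> pd.DataFrame:
    """Per-arm survival proportions and VAS-vs-conservative relative
    risks at 28 days and 1 year (relative risks to 2 decimals).

    A zero comparator proportion leaves the relative risk undefined
    (NaN) with a flag column set.
    """
    rows = {}
    for a in ARMS:
        members = grouped.arm(a)
        if not members:
            raise ValueError(f"empty arm {a!r}")
        n = len(members)
        rows[a] = {
            "n": n,
            "surv28": sum(p.surv28 for p in members) / n,
            "surv1y": sum(p.surv1y for p in members) / n,
            "mfs": sum(p.mfs for p in members) / n,
        }
    out = pd.DataFrame(rows).T
    for col in ("surv28", "surv1y"):
        denom = rows["conservative"][col]
        rr = round(rows["vas"][col] / denom, 2) if denom > 0 else math.nan
        out.loc["vas", f"rr_{col}"] = rr
        out.loc["vas", f"rr_{col}_undefined"] = float(denom == 0)
    return out


def required_qaly_gain(icer: float, threshold: float) -> float:
    """QALY gain per additional effect unit needed for the intervention
    to be cost-effective: ICER / threshold.

    E.g. a cost per survivor of ~£15,000 against a £20,000-per-QALY
    threshold means each extra survivor must yield about 0.77 QALYs.
    """
    if icer <= 0 or threshold <= 0:
        raise ValueError("icer and threshold must be positive")
    return icer / threshold


# ---------------------------------------------------------------------------
# CSV interface

def patients_to_frame(patients: list) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = {
            "id": p.id,
            "arm_randomised": p.arm_randomised,
            "arm_received": p.arm_received,
            "terminated_post_randomisation": int(p.terminated_post_randomisation),
            "final_state": p.final_state.value,
            "shunt_insertions": p.shunt_insertions,
        }
        row.update({c: round(p.cost_components[c], 2) for c in COST_CATEGORIES})
        row.update({"surv28": p.surv28, "surv1y": p.surv1y, "mfs": p.mfs})
        rows.append(row)
    return pd.DataFrame(rows)


def patients_from_frame(df: pd.DataFrame) -> list:
    out = []
    for _, r in df.iterrows():
        out.append(PatientRecord(
            id=str(r["id"]),
            arm_randomised=str(r["arm_randomised"]),
            arm_received=str(r["arm_received"]),
            terminated_post_randomisation=bool(int(r["terminated_post_randomisation"])),
            final_state=HealthState(r["final_state"]),
            shunt_insertions=int(r["shunt_insertions"]),
            cost_components={c: float(r[c]) for c in COST_CATEGORIES},
            surv28=int(r["surv28"]), surv1y=int(r["surv1y"]), mfs=int(r["mfs"]),
        ))
    return out


def write_patients_csv(patients: list, path) -> None:
    patients_to_frame(patients).to_csv(path, index=False)


def read_patients_csv(path) -> list:
    return patients_from_frame(pd.read_csv(path))
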