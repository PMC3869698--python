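"""Synthetic trial cohorts with the structure of the randomised
vesico-amniotic-shunt study.

The real patient-level data are confidential, so the generator emits
cohorts that reproduce every published margin of the randomised arm:
16 shunt (VAS) and 15 conservative participants; 3 and 2 crossovers;
pregnancy losses before 24 weeks (3 of 15 conservative); 28-day
survival probabilities 0.5 and 0.267; 1-year survival 0.4375 and 0.2;
no conservative-arm morbidity-free survivor; right-skewed itemised
costs with a small number of >£50,000 outliers confined to patients
randomised to — and receiving — a shunt, driven by prolonged neonatal
intensive-care admission.

Intermediate branch splits (cause of early loss, renal-impairment
grade mix, shunt dislodgement) are fixture choices consistent with
those margins; they are defaults of this package, not published
values.  Crossovers are assigned deterministically (the first k
records of each arm) so view arithmetic is exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import COST_CATEGORIES, SHUNT_PROCEDURE_COST, PatientRecord
from .tree_model import TERMINAL_EFFECTS, HealthState

__all__ = [
    "STATE_ORDER",
    "DEFAULT_PATHWAY_PROBS",
    "CostModel",
    "GeneratorConfig",
    "default_cost_model",
    "generate_trial",
    "generate_cost_components",
]

_HS = HealthState

STATE_ORDER = tuple(_HS)

#: Per-arm terminal-state distributions.  Numerators are the default
#: fixture's implied patient counts over 16 / 15 participants; the
#: printed margins they reproduce are the survival proportions
#: (8/16, 4/15 at 28 days; 7/16, 3/15 at 1 year), the 3-of-15
#: conservative early losses, and post-randomisation terminations of
#: 1 / 2 (back-solved from the per-protocol effect scaling).
DEFAULT_PATHWAY_PROBS = {
    "vas": {
        _HS.TERMINATION: 1 / 16,
        _HS.CHORIOAMNIONITIS_LOSS: 1 / 16,
        _HS.MISCARRIAGE: 1 / 16,
        _HS.DIED_IN_UTERO: 2 / 16,
        _HS.DIED_AT_DELIVERY: 1 / 16,
        _HS.NEONATAL_DEATH: 2 / 16,
        _HS.INFANT_DEATH_1Y: 1 / 16,
        _HS.ALIVE_NO_MORBIDITY: 1 / 16,
        _HS.ALIVE_MILD_RENAL: 2 / 16,
        _HS.ALIVE_MODERATE_RENAL: 2 / 16,
        _HS.ALIVE_SEVERE_RENAL: 2 / 16,
    },
    "conservative": {
        _HS.TERMINATION: 2 / 15,
        _HS.CHORIOAMNIONITIS_LOSS: 0.0,
        _HS.MISCARRIAGE: 1 / 15,
        _HS.DIED_IN_UTERO: 3 / 15,
        _HS.DIED_AT_DELIVERY: 2 / 15,
        _HS.NEONATAL_DEATH: 3 / 15,
        _HS.INFANT_DEATH_1Y: 1 / 15,
        _HS.ALIVE_NO_MORBIDITY: 0.0,
        _HS.ALIVE_MILD_RENAL: 1 / 15,
        _HS.ALIVE_MODERATE_RENAL: 1 / 15,
        _HS.ALIVE_SEVERE_RENAL: 1 / 15,
    },
}

#: States with no post-24-week pregnancy: no delivery or neonatal costs.
PREGNANCY_LOSS_STATES = frozenset({
    _HS.MISCARRIAGE, _HS.TERMINATION, _HS.CHORIOAMNIONITIS_LOSS, _HS.DIED_IN_UTERO,
})

#: States involving a neonatal-unit admission (outlier-eligible).
NEONATAL_ADMISSION_STATES = frozenset({
    _HS.NEONATAL_DEATH, _HS.INFANT_DEATH_1Y, _HS.ALIVE_NO_MORBIDITY,
    _HS.ALIVE_MILD_RENAL, _HS.ALIVE_MODERATE_RENAL, _HS.ALIVE_SEVERE_RENAL,
})


def _default_cost_means() -> dict:
    """Mean itemised cost (GBP, 2011) by final state.

    Calibrated so the default cohort's expected ITT arm means land near
    the £20,851 / £9,868 totals the fixture targets; placeholders
    standing in for unpublished unit-cost tables, not published values.
    Shunt-insertion costs are handled separately (deterministic
    £821.80 per insertion).
    """
    rows = {
        # state: scans, karyo, delivery, neonatal, procedures, renal, other
        _HS.MISCARRIAGE: (900, 450, 0, 0, 500, 0, 300),
        _HS.TERMINATION: (900, 450, 0, 0, 500, 0, 300),
        _HS.CHORIOAMNIONITIS_LOSS: (900, 450, 0, 0, 500, 0, 300),
        _HS.DIED_IN_UTERO: (1200, 450, 800, 0, 300, 0, 400),
        _HS.DIED_AT_DELIVERY: (1200, 450, 1500, 800, 300, 0, 400),
        _HS.NEONATAL_DEATH: (1200, 450, 1500, 5000, 1000, 0, 500),
        _HS.INFANT_DEATH_1Y: (1200, 450, 1500, 12000, 3000, 2000, 800),
        _HS.ALIVE_NO_MORBIDITY: (1200, 450, 1500, 10000, 1500, 500, 500),
        _HS.ALIVE_MILD_RENAL: (1200, 450, 1500, 12000, 2000, 2000, 500),
        _HS.ALIVE_MODERATE_RENAL: (1200, 450, 1500, 13000, 2500, 4000, 500),
        _HS.ALIVE_SEVERE_RENAL: (1200, 450, 1500, 14000, 2500, 5500, 500),
    }
    cats = ("antenatal_scans", "karyotyping", "delivery", "neonatal_admission",
            "procedures", "renal_care", "other")
    return {s: dict(zip(cats, map(float, v))) for s, v in rows.items()}


@dataclass
class CostModel:
    """Lognormal itemised costs plus a neonatal-admission outlier
    component.

    Each non-shunt component is lognormal with the state-specific mean
    and a common coefficient-of-variation parameter ``sigma`` (log-sd).
    With probability ``outlier_prob``, an outlier-eligible patient
    (randomised to and receiving a shunt, with a neonatal admission)
    has the admission cost redrawn as ``outlier_min`` plus a lognormal
    excess, guaranteeing a total above the outlier minimum dominated by
    neonatal intensive care.
    """

    means: dict = field(default_factory=_default_cost_means)
    sigma: float = 0.25
    outlier_prob: float = 0.27
    outlier_min: float = 50_000.0
    outlier_excess_mean: float = 10_000.0
    outlier_vas_only: bool = True


@dataclass
class GeneratorConfig:
    n_vas: int = 16
    n_conservative: int = 15
    crossover_vas_to_cons: int = 3
    crossover_cons_to_vas: int = 2
    pathway_probs: dict = field(default_factory=lambda: {
        a: dict(t) for a, t in DEFAULT_PATHWAY_PROBS.items()})
    p_dislodge: float = 2 / 16  # shunt dislodgement needing re-insertion
    cost_model: CostModel = field(default_factory=CostModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_vas < 1 or self.n_conservative < 1:
            raise ValueError("arm sizes must be positive")
        if not (0 <= self.crossover_vas_to_cons <= self.n_vas):
            raise ValueError("crossover_vas_to_cons exceeds VAS arm size")
        if not (0 <= self.crossover_cons_to_vas <= self.n_conservative):
            raise ValueError("crossover_cons_to_vas exceeds conservative arm size")
        if not (0 <= self.p_dislodge <= 1):
            raise ValueError("p_dislodge must be a probability")
        for arm, table in self.pathway_probs.items():
            probs = np.array([table.get(s, 0.0) for s in STATE_ORDER], dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"pathway probabilities for arm {arm!r} must be a distribution")
        cm = self.cost_model
        if not (0 <= cm.outlier_prob <= 1):
            raise ValueError("outlier_prob must be a probability")
        vals = [cm.sigma, cm.outlier_min, cm.outlier_excess_mean]
        vals += [v for row in cm.means.values() for v in row.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("cost parameters must be finite")
        if any(v < 0 for row in cm.means.values() for v in row.values()):
            raise ValueError("cost means must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathway_probs"] = {a: {s.value: p for s, p in t.items()}
                              for a, t in self.pathway_probs.items()}
        d["cost_model"]["means"] = {s.value: row for s, row in self.cost_model.means.items()}
        return d


def default_cost_model() -> CostModel:
    return CostModel()


def _lognormal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    if mean <= 0:
        return 0.0
    return float(rng.lognormal(np.log(mean) - sigma ** 2 / 2.0, sigma))


def generate_cost_components(state: HealthState, received_vas: bool,
                             shunt_insertions: int, outlier_eligible: bool,
                             cost_model: CostModel, rng: np.random.Generator) -> dict:
    """Itemised cost draw for one patient.

    Structural zeros are respected: pregnancy-loss states carry no
    delivery or neonatal-admission costs regardless of the mean table.
    The shunt component is deterministic — £821.80 per insertion (zero
    if no shunt was placed).  Outlier draws replace the neonatal
    admission with ``outlier_min`` plus a lognormal excess.
    """
    means = cost_model.means[state]
    comp = {c: 0.0 for c in COST_CATEGORIES}
    for cat in ("antenatal_scans", "karyotyping", "delivery",
                "neonatal_admission", "procedures", "renal_care", "other"):
        comp[cat] = _lognormal(rng, means.get(cat, 0.0), cost_model.sigma)
    if state in PREGNANCY_LOSS_STATES:
        comp["delivery"] = 0.0
    if state not in NEONATAL_ADMISSION_STATES:
        comp["neonatal_admission"] = 0.0
    comp["shunt_insertion"] = SHUNT_PROCEDURE_COST * shunt_insertions if received_vas else 0.0
    if outlier_eligible and state in NEONATAL_ADMISSION_STATES \
            and rng.random() < cost_model.outlier_prob:
        comp["neonatal_admission"] = cost_model.outlier_min + _lognormal(
            rng, cost_model.outlier_excess_mean, cost_model.sigma)
    return comp


def generate_trial(config: GeneratorConfig | None = None,
                   seed: int | None = None) -> list:
    """One synthetic randomised cohort.

    Arm sizes and crossover counts match the config exactly (crossovers
    are the first records of each arm); final states are multinomial
    draws from the per-arm pathway tables; outcome flags follow
    deterministically from the final state.  Bit-reproducible for a
    given seed.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    patients: list[PatientRecord] = []
    arms = (("vas", config.n_vas, config.crossover_vas_to_cons),
            ("conservative", config.n_conservative, config.crossover_cons_to_vas))
    for arm, n, n_cross in arms:
        table = config.pathway_probs[arm]
        probs = np.array([table.get(s, 0.0) for s in STATE_ORDER], dtype=float)
        states = rng.choice(len(STATE_ORDER), size=n, p=probs)
        for i in range(n):
            state = STATE_ORDER[states[i]]
            received = ("conservative" if arm == "vas" else "vas") if i < n_cross else arm
            if received == "vas":
                insertions = 1 + int(rng.random() < config.p_dislodge)
            else:
                insertions = 0
            eligible = (arm == "vas" and received == "vas") \
                if config.cost_model.outlier_vas_only else received == "vas"
            comp = generate_cost_components(state, received == "vas", insertions,
                                            eligible, config.cost_model, rng)
            eff = TERMINAL_EFFECTS[state]
            patients.append(PatientRecord(
                id=f"{arm[:3]}-{i + 1:02d}",
                arm_randomised=arm,
                arm_received=received,
                terminated_post_randomisation=(state == _HS.TERMINATION),
                final_state=state,
                shunt_insertions=insertions,
                cost_components=comp,
                surv28=int(eff.surv28), surv1y=int(eff.surv1y), mfs=int(eff.mfs),
            ))
    return patients
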