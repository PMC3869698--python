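"""Scenario orchestration: one base case x one sensitivity scenario,
from patient records to incremental results, PSA, CEAC and CE-plane.

Base cases: ``itt`` (group by randomised arm, maximum-likelihood
probabilities), ``per_protocol`` (drop post-randomisation
terminations), ``uniform_prior`` (ITT cohort, add-one Dirichlet
posterior-mean probabilities).  Deterministic scenarios: doubled or
halved shunt-procedure cost, outlier-cost substitution, and analysis
as treated.  Every run logs cohort sizes, exclusions, substitutions
and the PSA iteration count — the audit trail an economic-evaluation
submission needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from . import economics as ec
from . import fixtures
from .tree_model import EFFECT_NAMES, StrategyResult, resolve_probs, rollback

__all__ = [
    "BASE_CASES",
    "DSA_SCENARIOS",
    "ScenarioSpec",
    "ScenarioBundle",
    "run_scenario",
    "write_bundle",
    "render_report",
    "run_all_scenarios",
]

logger = logging.getLogger("ceatree")

BASE_CASES = ("itt", "per_protocol", "uniform_prior")
DSA_SCENARIOS = ("none", "dsa1_double_vas_cost", "dsa2_halve_vas_cost",
                 "dsa3_outlier_substitution", "dsa4_as_treated")


@dataclass
class ScenarioSpec:
    base_case: str = "itt"
    dsa: str = "none"
    psa: bool = False
    iterations: int = 20_000
    seed: int | None = None
    wtp_max: float = 100_000.0
    wtp_step: float = 500.0
    outlier_threshold: float = 50_000.0

    def validate(self) -> None:
        if self.base_case not in BASE_CASES:
            raise ValueError(f"unknown base case {self.base_case!r}")
        if self.dsa not in DSA_SCENARIOS:
            raise ValueError(f"unknown DSA scenario {self.dsa!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.wtp_max <= 0 or self.wtp_step <= 0:
            raise ValueError("WTP grid parameters must be positive")

    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_max + 1, self.wtp_step)


@dataclass
class ScenarioBundle:
    spec: ScenarioSpec
    view: str
    arm_sizes: dict
    strategy_results: dict            # arm -> StrategyResult
    incrementals: dict                # outcome -> IncrementalResult
    psa: ec.PSAResult | None = None
    ceac: pd.DataFrame | None = None
    ce_plane: ec.CEPlane | None = None
    log: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for arm in ("vas", "conservative"):
            r = self.strategy_results[arm]
            e = r.expected_effects
            rows.append({"strategy": arm, "total_cost": round(r.expected_cost, 2),
                         "surv28": e.surv28, "surv1y": e.surv1y, "mfs": e.mfs})
        frame = pd.DataFrame(rows)
        for name in EFFECT_NAMES:
            inc = self.incrementals[name]
            frame.loc[frame["strategy"] == "vas", f"icer_{name}"] = (
                round(inc.icer, 2) if inc.icer is not None else np.nan)
            frame.loc[frame["strategy"] == "vas", f"class_{name}"] = inc.classification
        return frame


def _view_for(spec: ScenarioSpec) -> str:
    if spec.dsa == "dsa4_as_treated":
        return "as_treated"
    if spec.base_case == "per_protocol":
        return "per_protocol"
    return "itt"


def _regime_for(spec: ScenarioSpec) -> str:
    return "uniform_prior" if spec.base_case == "uniform_prior" else "mle"


def run_scenario(patients: list, spec: ScenarioSpec,
                 tree_structures: dict | None = None) -> ScenarioBundle:
    """Evaluate one scenario end to end.

    Applies the deterministic transformation, builds the analysis
    view, populates both arm trees with counts and cost payoffs, rolls
    them back, and computes the three incremental comparisons; with
    ``spec.psa`` set it also runs the Monte Carlo PSA and derives the
    CEAC and CE-plane for 28-day survival.  ``tree_structures``
    optionally replaces the built-in {arm: DecisionTree} pathway
    structures (e.g. loaded from YAML).
    """
    spec.validate()
    log: dict = {"n_patients": len(patients), "seed": spec.seed}

    transformed = patients
    if spec.dsa == "dsa1_double_vas_cost":
        transformed = ch.scale_shunt_costs(patients, 2.0)
    elif spec.dsa == "dsa2_halve_vas_cost":
        transformed = ch.scale_shunt_costs(patients, 0.5)
    elif spec.dsa == "dsa3_outlier_substitution":
        transformed = ch.substitute_outliers(patients, spec.outlier_threshold)
        n_sub = sum(1 for a, b in zip(patients, transformed)
                    if a.total_cost != b.total_cost)
        log["outliers_substituted"] = n_sub
        logger.info("DSA3: substituted %d outlier cost totals (> £%.0f)",
                    n_sub, spec.outlier_threshold)

    view = _view_for(spec)
    grouped = ch.build_view(transformed, view)
    log["arm_sizes"] = grouped.sizes()
    log["excluded"] = len(transformed) - sum(grouped.sizes().values())
    logger.info("view=%s arms=%s excluded=%d", view, grouped.sizes(), log["excluded"])

    regime = _regime_for(spec)
    if tree_structures is None:
        trees = fixtures.trees_from_cohort(grouped, regime=regime)
    else:
        trees = {a: fixtures.populate_tree(tree_structures[a], grouped.arm(a), a, regime)
                 for a in grouped.arms}
    results = {arm: rollback(t, resolve_probs(t)) for arm, t in trees.items()}
    incrementals = {name: ec.incremental_analysis(results["vas"], results["conservative"], name)
                    for name in EFFECT_NAMES}

    bundle = ScenarioBundle(spec, view, grouped.sizes(), results, incrementals, log=log)
    if spec.psa:
        psa_regime = "uniform_prior" if regime == "uniform_prior" else "auto"
        bundle.psa = ec.run_psa(trees["vas"], trees["conservative"],
                                n_iter=spec.iterations, seed=spec.seed,
                                regime=psa_regime)
        bundle.ceac = ec.ceac(bundle.psa, "surv28", spec.wtp_grid())
        bundle.ce_plane = ec.ce_plane(bundle.psa, "surv28")
        log["psa_iterations"] = spec.iterations
        logger.info("PSA: %d iterations, regime=%s", spec.iterations, psa_regime)
    return bundle


def write_bundle(bundle: ScenarioBundle, out_dir, patients_path=None) -> Path:
    """Write summary/CEAC/CE-plane CSVs plus a YAML provenance sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.summary_frame().to_csv(out / "summary.csv", index=False)
    if bundle.ceac is not None:
        bundle.ceac.to_csv(out / "ceac.csv", index=False)
    if bundle.ce_plane is not None:
        bundle.ce_plane.points.to_csv(out / "ce_plane.csv", index=False)
    prov = {
        "base_case": bundle.spec.base_case,
        "dsa": bundle.spec.dsa,
        "view": bundle.view,
        "psa": bool(bundle.spec.psa),
        "iterations": int(bundle.spec.iterations) if bundle.spec.psa else 0,
        "seed": bundle.spec.seed,
        "arm_sizes": bundle.arm_sizes,
        "log": bundle.log,
    }
    if bundle.ce_plane is not None:
        prov["ce_plane_quadrants"] = bundle.ce_plane.quadrants
    if patients_path is not None:
        from .io import sha256_of_file
        prov["patients_sha256"] = sha256_of_file(patients_path)
    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)
    return out


_ROW_ORDER = ("none", "psa", "dsa1_double_vas_cost", "dsa2_halve_vas_cost",
              "dsa3_outlier_substitution", "dsa4_as_treated")
_ROW_LABEL = {"none": "Base case", "psa": "Probabilistic sensitivity analysis",
              "dsa1_double_vas_cost": "DSA1 (doubled VAS costs)",
              "dsa2_halve_vas_cost": "DSA2 (halved VAS costs)",
              "dsa3_outlier_substitution": "DSA3 (adjusted outlier costs)",
              "dsa4_as_treated": "DSA4 (as per treatment received)"}


def render_report(bundles: dict) -> dict:
    """Summary table per base case from {(base_case, scenario): bundle}.

    Scenario keys are the DSA labels plus ``"psa"`` for the
    probabilistic row.  Rows follow the base/PSA/DSA1-4 layout; a
    dominant comparison renders as ``dominant`` with the signed ratio
    in a footnote column.  Missing scenarios are rendered as absent
    with a logged warning.
    """
    tables: dict[str, pd.DataFrame] = {}
    for base in BASE_CASES:
        rows = []
        for scen in _ROW_ORDER:
            bundle = bundles.get((base, scen))
            if bundle is None:
                logger.warning("report: missing scenario %s/%s", base, scen)
                continue
            for arm in ("vas", "conservative"):
                r = bundle.strategy_results[arm]
                e = r.expected_effects
                row = {"analysis": _ROW_LABEL[scen], "strategy": arm,
                       "total_cost": round(r.expected_cost),
                       "surv28": round(e.surv28, 2), "surv1y": round(e.surv1y, 2),
                       "mfs": round(e.mfs, 2)}
                if arm == "vas":
                    notes = []
                    for name in EFFECT_NAMES:
                        inc = bundle.incrementals[name]
                        if inc.classification == "icer_reported":
                            row[f"icer_{name}"] = round(inc.icer)
                        else:
                            row[f"icer_{name}"] = inc.classification.replace(
                                "intervention_", "")
                            if inc.signed_ratio is not None:
                                notes.append(f"{name}: signed ratio {inc.signed_ratio:.0f}")
                    row["footnote"] = "; ".join(notes)
                rows.append(row)
        if rows:
            tables[base] = pd.DataFrame(rows)
    return tables


def run_all_scenarios(patients: list, seed: int | None = None,
                      iterations: int = 20_000) -> dict:
    """All 3 base cases x (base + PSA + 4 DSA) = 18 rows / 15 distinct
    runs; returns the {(base_case, scenario): bundle} mapping that
    :func:`render_report` consumes."""
    bundles = {}
    for base in BASE_CASES:
        for scen in _ROW_ORDER:
            spec = ScenarioSpec(base_case=base,
                                dsa="none" if scen == "psa" else scen,
                                psa=(scen == "psa"),
                                iterations=iterations, seed=seed)
            bundles[(base, scen)] = run_scenario(patients, spec)
    return bundles
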