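"""Incremental cost-effectiveness arithmetic and probabilistic
sensitivity analysis.

The comparison is always intervention (index) versus comparator:
delta C = C_int - C_comp, delta E = E_int - E_comp, ICER = dC/dE.
Dominance (cheaper and more effective, or dearer and less effective)
is reported as a classification rather than a signed ratio, because a
negative ICER conflates two opposite situations; the signed quotient
remains available for verbose reporting.

PSA redraws every chance node's probability vector from its
Beta/Dirichlet posterior and rolls both trees back per iteration
(vectorised over iterations).  Cost payoffs stay at their base-case
values: the trial reports no distributional family for costs, so
probability uncertainty is what the simulation propagates.  The CEAC
is the fraction of iterations in which the intervention has the higher
net monetary benefit, NMB = WTP x effect - cost, as a function of the
willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimation
from .tree_model import (
    DecisionTree,
    EFFECT_NAMES,
    EffectVector,
    StrategyResult,
    resolve_probs,
    validate_tree,
)

__all__ = [
    "IncrementalResult",
    "PSAResult",
    "CEPlane",
    "incremental_analysis",
    "net_monetary_benefit",
    "run_psa",
    "ceac",
    "ce_plane",
    "default_wtp_grid",
]

#: £0 – £100,000 in £500 steps: covers the £20,000 and £40,000
#: willingness-to-pay landmarks with room above.
def default_wtp_grid() -> np.ndarray:
    return np.arange(0.0, 100_000.0 + 1, 500.0)


def _effect_index(outcome: str) -> int:
    try:
        return EFFECT_NAMES.index(outcome)
    except ValueError:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {EFFECT_NAMES}") from None


@dataclass
class IncrementalResult:
    """One intervention-vs-comparator comparison on one outcome.

    ``icer`` is present only for ``icer_reported`` comparisons (both
    increments of like sign, effect increment nonzero).  Dominance and
    equal-effect comparisons leave it None; ``signed_ratio`` carries
    the raw quotient for verbose report footnotes.
    """

    outcome: str
    delta_cost: float
    delta_effect: float
    classification: str
    icer: float | None = None
    signed_ratio: float | None = None


def incremental_analysis(res_intervention: StrategyResult,
                         res_comparator: StrategyResult,
                         outcome: str) -> IncrementalResult:
    i = _effect_index(outcome)
    dc = res_intervention.expected_cost - res_comparator.expected_cost
    de = (res_intervention.expected_effects.as_array()[i]
          - res_comparator.expected_effects.as_array()[i])
    ratio = dc / de if de != 0 else None
    if de == 0:
        cls = "equal_effect"
        icer = None
    elif dc < 0 and de > 0:
        cls = "intervention_dominant"
        icer = None
    elif dc > 0 and de < 0:
        cls = "intervention_dominated"
        icer = None
    else:
        cls = "icer_reported"
        icer = ratio
    return IncrementalResult(outcome, float(dc), float(de), cls, icer, ratio)


def net_monetary_benefit(res: StrategyResult, outcome: str, wtp: float) -> float:
    """NMB = WTP x expected effect - expected cost (GBP)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    i = _effect_index(outcome)
    return float(wtp * res.expected_effects.as_array()[i] - res.expected_cost)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass
class PSAResult:
    """Paired per-iteration (cost, effect-vector) draws for both arms."""

    strategy_intervention: str
    strategy_comparator: str
    cost_intervention: np.ndarray      # (n,)
    effects_intervention: np.ndarray   # (n, 3) in EFFECT_NAMES order
    cost_comparator: np.ndarray
    effects_comparator: np.ndarray
    seed: int | None = None
    regime: str = "auto"

    @property
    def iterations(self) -> int:
        return int(self.cost_intervention.shape[0])

    def deltas(self, outcome: str):
        i = _effect_index(outcome)
        dc = self.cost_intervention - self.cost_comparator
        de = self.effects_intervention[:, i] - self.effects_comparator[:, i]
        return dc, de

    def to_frame(self) -> pd.DataFrame:
        d = {"cost_intervention": self.cost_intervention,
             "cost_comparator": self.cost_comparator}
        for j, name in enumerate(EFFECT_NAMES):
            d[f"{name}_intervention"] = self.effects_intervention[:, j]
            d[f"{name}_comparator"] = self.effects_comparator[:, j]
        return pd.DataFrame(d)


def _sample_node_draws(tree: DecisionTree, n_iter: int, regime: str,
                       rng: np.random.Generator) -> dict:
    """(n_iter, K) Dirichlet draw matrix per chance node.

    Nodes with a ``fixed`` spec keep their fixed vector in every
    iteration.  Nodes are visited in sorted-id order so a given seed
    always consumes the random stream identically.
    """
    draws = {}
    point = resolve_probs(tree)
    for nid in sorted(n.id for n in tree.chance_nodes()):
        node = tree.nodes[nid]
        if node.spec.regime == "fixed":
            draws[nid] = np.tile(point[nid], (n_iter, 1))
        else:
            try:
                draws[nid] = estimation.sample_probs_matrix(
                    node.spec.counts, regime=regime, n=n_iter, rng=rng)
            except ValueError as err:
                raise ValueError(f"node {nid!r}: {err}") from None
    return draws


def _evaluate_many(tree: DecisionTree, draws: dict, n_iter: int):
    """Vectorised rollback: expected cost (n,) and effects (n, 3) per
    iteration given per-node probability draw matrices."""

    def value(nid: str):
        node = tree.nodes[nid]
        if node.kind == "terminal":
            return (np.full(n_iter, node.payoff.cost),
                    np.tile(node.payoff.effects.as_array(), (n_iter, 1)))
        if node.kind == "decision":
            return value(node.branches[0].child)
        p = draws[node.id]  # (n, K)
        cost = np.zeros(n_iter)
        eff = np.zeros((n_iter, 3))
        for j, br in enumerate(node.branches):
            c, e = value(br.child)
            cost += p[:, j] * c
            eff += p[:, j, None] * e
        return cost, eff

    return value(tree.root)


def run_psa(tree_intervention: DecisionTree, tree_comparator: DecisionTree,
            n_iter: int = 20_000, seed: int | None = None,
            regime: str = "auto") -> PSAResult:
    """Monte Carlo PSA over both arms' trees.

    Each iteration redraws every non-fixed chance node's probabilities
    from Dirichlet(alpha) (Beta when two branches) and rolls both trees
    back.  ``regime`` sets alpha: ``mle_centred`` (alpha = counts,
    rejecting zero counts), ``uniform_prior`` (alpha = counts + 1) or
    ``auto`` (mle-centred, falling back to counts + 1 at nodes with a
    zero count).  Same seed, same result, bit for bit.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    for t in (tree_intervention, tree_comparator):
        rep = validate_tree(t)
        if not rep.ok:
            raise ValueError(f"tree {t.strategy!r} invalid: {rep.violations}")
    rng = np.random.default_rng(seed)
    out = []
    for tree in (tree_intervention, tree_comparator):
        draws = _sample_node_draws(tree, n_iter, regime, rng)
        out.append(_evaluate_many(tree, draws, n_iter))
    (ci, ei), (cc, ec) = out
    return PSAResult(tree_intervention.strategy, tree_comparator.strategy,
                     ci, ei, cc, ec, seed=seed, regime=regime)


def ceac(psa: PSAResult, outcome: str, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    At each threshold, the fraction of iterations in which the
    intervention's NMB strictly exceeds the comparator's (ties count as
    not cost-effective).  At WTP = 0 this is P(dC < 0); as WTP grows it
    tends to P(dE > 0).
    """
    if psa.iterations == 0:
        raise ValueError("empty PSA result")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("willingness-to-pay grid must be non-negative and strictly increasing")
    dc, de = psa.deltas(outcome)
    # NMB_int > NMB_comp  <=>  wtp * dE - dC > 0
    p = [(grid_i * de - dc > 0).mean() for grid_i in grid]
    return pd.DataFrame({"wtp": grid, "p_cost_effective": p})


@dataclass
class CEPlane:
    """Incremental cost-effectiveness scatter plus quadrant counts.

    Quadrants use strict inequalities (NE: dE > 0 and dC > 0, etc.);
    points on an axis are tallied under ``on_axis``.
    """

    outcome: str
    points: pd.DataFrame  # columns delta_effect, delta_cost
    quadrants: dict = field(default_factory=dict)


def ce_plane(psa: PSAResult, outcome: str) -> CEPlane:
    if psa.iterations == 0:
        raise ValueError("empty PSA result")
    dc, de = psa.deltas(outcome)
    pts = pd.DataFrame({"delta_effect": de, "delta_cost": dc})
    q = {
        "NE": int(((de > 0) & (dc > 0)).sum()),
        "NW": int(((de < 0) & (dc > 0)).sum()),
        "SE": int(((de > 0) & (dc < 0)).sum()),
        "SW": int(((de < 0) & (dc < 0)).sum()),
    }
    q["on_axis"] = psa.iterations - sum(q.values())
    return CEPlane(outcome, pts, q)
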