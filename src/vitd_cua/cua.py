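"""Base-case cost-utility analysis.

Rolls back both strategies at point values and reports expected cost,
expected QALY (utility weight over the horizon, unscaled by default),
increments, net monetary benefit NMB = wtp*QALY - cost, and the
dominance/ICER classification. When the intervention is both cheaper and
more effective it dominates absolutely and no ICER is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .parameters import ParameterTable
from .tree_engine import COMPARATOR, INTERVENTION, build_vitd_tree, rollback

__all__ = [
    "StrategyResult",
    "Classification",
    "CUAResult",
    "evaluate_base_case",
    "net_monetary_benefit",
    "classify_increment",
    "dominance_threshold_episode_cost",
]

INTERVENTION_DOMINANT = "intervention-dominant"
INTERVENTION_DOMINATED = "intervention-dominated"
DOMINANCE_BY_COST = "dominance-by-cost"
ICER = "icer"
IDENTICAL = "identical-strategies"


@dataclass(frozen=True)
class StrategyResult:
    name: str
    expected_cost: float
    expected_qaly: float


@dataclass(frozen=True)
class Classification:
    kind: str
    icer_value: Optional[float] = None


@dataclass(frozen=True)
class CUAResult:
    intervention: StrategyResult
    comparator: StrategyResult
    delta_cost: float  # intervention minus comparator
    delta_qaly: float
    savings: float  # comparator minus intervention cost (Table-style "Diff $")
    nmb: dict[str, float]
    classification: Classification
    wtp: float


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = wtp*qaly - cost."""
    if wtp < 0.0:
        raise ValueError(f"willingness-to-pay must be nonnegative, got {wtp}")
    return wtp * qaly - cost


def classify_increment(delta_cost: float, delta_qaly: float) -> Classification:
    """Dominance/ICER classification of (intervention - comparator) increments.

    Lower cost and higher QALYs: the intervention dominates absolutely.
    Higher cost and lower QALYs: it is dominated. Equal QALYs with a cost
    difference: dominance by cost alone. Both increments exactly zero: the
    strategies are identical and no ratio exists. Otherwise the ICER
    delta_cost/delta_qaly is reported.
    """
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return Classification(IDENTICAL)
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return Classification(INTERVENTION_DOMINANT)
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return Classification(INTERVENTION_DOMINATED)
    if delta_qaly == 0.0:
        return Classification(DOMINANCE_BY_COST)
    return Classification(ICER, icer_value=delta_cost / delta_qaly)


def evaluate_base_case(params: ParameterTable) -> CUAResult:
    """Build the tree, roll back both strategies and compute the incremental analysis."""
    comparator_tree, intervention_tree = build_vitd_tree(params)
    scale = params.horizon_days / 365.0 if params.scale_by_horizon else 1.0

    cost_c, util_c = rollback(comparator_tree)
    cost_i, util_i = rollback(intervention_tree)
    qaly_c = util_c * scale
    qaly_i = util_i * scale

    intervention = StrategyResult(INTERVENTION, cost_i, qaly_i)
    comparator = StrategyResult(COMPARATOR, cost_c, qaly_c)
    delta_cost = cost_i - cost_c
    delta_qaly = qaly_i - qaly_c
    nmb = {
        INTERVENTION: net_monetary_benefit(cost_i, qaly_i, params.wtp),
        COMPARATOR: net_monetary_benefit(cost_c, qaly_c, params.wtp),
    }
    return CUAResult(
        intervention=intervention,
        comparator=comparator,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        savings=-delta_cost,
        nmb=nmb,
        classification=classify_increment(delta_cost, delta_qaly),
        wtp=params.wtp,
    )


def dominance_threshold_episode_cost(params: ParameterTable) -> Optional[float]:
    """Episode cost above which supplementation is cost-saving.

    Setting the analytic incremental cost to zero gives the threshold
    c_vitd_day*suppl_days / (p_ari*(1-rr_vitd)). Returns None when
    rr_vitd >= 1 (supplementation prevents nothing, so no episode cost can
    make it cost-saving).
    """
    if params.rr_vitd >= 1.0:
        return None
    if params.p_ari <= 0.0:
        raise ValueError("dominance threshold requires p_ari > 0")
    return params.c_vitd_day * params.suppl_days / (params.p_ari * (1.0 - params.rr_vitd))
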