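"""Two-strategy decision tree over four terminal health states.

Each strategy's tree is a chance node splitting on ARI occurrence; each
branch then splits on death vs survival. The four terminal states are
death after ARI, survival after ARI, survival without ARI, and death from
all causes. The supplemented strategy multiplies the baseline ARI
probability by the relative risk and adds the supplementation cost to
every terminal payoff.

``rollback`` computes expected cost and expected utility weight by
probability-weighted recursion; ``enumerate_paths`` is the independent
path-enumeration oracle used by the test suite. ``closed_form_increments``
gives the analytic incremental cost and QALY of supplementation:

    dQ = p_ari*(1-rr) * [(1-m_all) - (1-m_ari)*(1-du_ari)]
    dC = c_vitd_day*suppl_days - p_ari*(1-rr)*c_ari_day*episode_days
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Union

from .parameters import ParameterTable

__all__ = [
    "TerminalNode",
    "ChanceNode",
    "Strategy",
    "PathOutcome",
    "TreeValidationError",
    "build_vitd_tree",
    "build_trees_from_values",
    "rollback",
    "enumerate_paths",
    "validate_tree",
    "closed_form_increments",
    "strategy_to_json",
    "strategy_from_json",
]

PROB_TOL = 1e-12

INTERVENTION = "vitamin-D"
COMPARATOR = "no-supplementation"


class TreeValidationError(ValueError):
    """Raised when a tree violates its structural invariants."""


@dataclass(frozen=True)
class TerminalNode:
    label: str
    cost_payoff: float
    utility_payoff: float


@dataclass(frozen=True)
class ChanceNode:
    branches: tuple[tuple[float, Union["ChanceNode", TerminalNode]], ...]


@dataclass(frozen=True)
class Strategy:
    name: str
    root: ChanceNode


@dataclass(frozen=True)
class PathOutcome:
    probability: float
    cost: float
    utility: float
    labels: tuple[str, ...] = ()


def build_trees_from_values(
    p_ari: float,
    rr_vitd: float,
    m_ari: float,
    m_all: float,
    du_ari: float,
    c_ari_day: float,
    c_vitd_day: float,
    episode_days: float,
    suppl_days: float,
    *,
    cap_probability: bool = False,
) -> tuple[Strategy, Strategy]:
    """Build (comparator, intervention) strategies from raw parameter values.

    With ``cap_probability`` an effective ARI probability p_ari*rr_vitd above
    1 is clamped to 1 (used by the PSA for extreme relative-risk draws);
    otherwise it raises.
    """
    p_supp = p_ari * rr_vitd
    if p_supp > 1.0:
        if not cap_probability:
            raise TreeValidationError(
                f"infeasible probability: p_ari*rr_vitd = {p_supp} > 1"
            )
        p_supp = 1.0

    episode_cost = c_ari_day * episode_days
    suppl_cost = c_vitd_day * suppl_days

    def arm(name: str, p: float, extra_cost: float) -> Strategy:
        ari = ChanceNode(
            branches=(
                (m_ari, TerminalNode("death-after-ARI", episode_cost + extra_cost, 0.0)),
                (
                    1.0 - m_ari,
                    TerminalNode(
                        "survival-after-ARI", episode_cost + extra_cost, 1.0 - du_ari
                    ),
                ),
            )
        )
        no_ari = ChanceNode(
            branches=(
                (m_all, TerminalNode("death-all-causes", extra_cost, 0.0)),
                (1.0 - m_all, TerminalNode("survival-without-ARI", extra_cost, 1.0)),
            )
        )
        root = ChanceNode(branches=((p, ari), (1.0 - p, no_ari)))
        return Strategy(name=name, root=root)

    return (
        arm(COMPARATOR, p_ari, 0.0),
        arm(INTERVENTION, p_supp, suppl_cost),
    )


def build_vitd_tree(params: ParameterTable) -> tuple[Strategy, Strategy]:
    """The model's two strategies, (comparator, intervention), at point values."""
    return build_trees_from_values(
        params.p_ari,
        params.rr_vitd,
        params.m_ari,
        params.m_all,
        params.du_ari,
        params.c_ari_day,
        params.c_vitd_day,
        params.episode_days,
        params.suppl_days,
    )


def _rollback_node(node: Union[ChanceNode, TerminalNode]) -> tuple[float, float]:
    if isinstance(node, TerminalNode):
        return node.cost_payoff, node.utility_payoff
    cost = 0.0
    utility = 0.0
    for p, child in node.branches:
        c, u = _rollback_node(child)
        cost += p * c
        utility += p * u
    return cost, utility


def rollback(strategy: Strategy) -> tuple[float, float]:
    """Expected (cost, utility weight) of a strategy by backward recursion."""
    report = validate_tree(strategy)
    if report:
        raise TreeValidationError("; ".join(report))
    return _rollback_node(strategy.root)


def _walk(
    node: Union[ChanceNode, TerminalNode], prob: float, labels: tuple[str, ...]
) -> Iterator[PathOutcome]:
    if isinstance(node, TerminalNode):
        yield PathOutcome(prob, node.cost_payoff, node.utility_payoff, labels + (node.label,))
        return
    for p, child in node.branches:
        yield from _walk(child, prob * p, labels)


def enumerate_paths(strategy: Strategy) -> list[PathOutcome]:
    """One record per root-to-leaf path; probabilities multiply along the path."""
    report = validate_tree(strategy)
    if report:
        raise TreeValidationError("; ".join(report))
    return list(_walk(strategy.root, 1.0, ()))


def validate_tree(strategy: Strategy) -> list[str]:
    """Structural check: every chance node's probabilities sum to 1 and lie
    in [0, 1]; every terminal payoff is in range. Returns a list of
    violation messages (empty when well formed)."""
    report: list[str] = []

    def visit(node: Union[ChanceNode, TerminalNode], path: str) -> None:
        if isinstance(node, TerminalNode):
            if not 0.0 <= node.utility_payoff <= 1.0:
                report.append(
                    f"{path}: utility payoff {node.utility_payoff} outside [0, 1]"
                )
            if node.cost_payoff < 0.0:
                report.append(f"{path}: negative cost payoff {node.cost_payoff}")
            return
        total = sum(p for p, _ in node.branches)
        if abs(total - 1.0) > PROB_TOL:
            report.append(f"{path}: branch probabilities sum to {total!r}, not 1")
        for i, (p, child) in enumerate(node.branches):
            if not 0.0 <= p <= 1.0:
                report.append(f"{path}/branch[{i}]: probability {p} outside [0, 1]")
            visit(child, f"{path}/branch[{i}]")

    visit(strategy.root, strategy.name)
    return report


def closed_form_increments(params: ParameterTable) -> tuple[float, float]:
    """Analytic (delta_cost, delta_qaly), intervention minus comparator."""
    reduced = params.p_ari * (1.0 - params.rr_vitd)
    delta_cost = (
        params.c_vitd_day * params.suppl_days
        - reduced * params.c_ari_day * params.episode_days
    )
    delta_qaly = reduced * (
        (1.0 - params.m_all) - (1.0 - params.m_ari) * (1.0 - params.du_ari)
    )
    return delta_cost, delta_qaly


# -- JSON serialization -------------------------------------------------------


def _node_to_dict(node: Union[ChanceNode, TerminalNode]) -> dict:
    if isinstance(node, TerminalNode):
        return {
            "type": "terminal",
            "label": node.label,
            "cost": node.cost_payoff,
            "utility": node.utility_payoff,
        }
    return {
        "type": "chance",
        "branches": [
            {"probability": p, "child": _node_to_dict(child)}
            for p, child in node.branches
        ],
    }


def _node_from_dict(doc: dict) -> Union[ChanceNode, TerminalNode]:
    if doc["type"] == "terminal":
        return TerminalNode(doc["label"], doc["cost"], doc["utility"])
    return ChanceNode(
        branches=tuple(
            (b["probability"], _node_from_dict(b["child"])) for b in doc["branches"]
        )
    )


def strategy_to_json(strategy: Strategy) -> str:
    return json.dumps({"name": strategy.name, "root": _node_to_dict(strategy.root)}, indent=2)


def strategy_from_json(text: str) -> Strategy:
    doc = json.loads(text)
    root = _node_from_dict(doc["root"])
    if not isinstance(root, ChanceNode):
        raise TreeValidationError("strategy root must be a chance node")
    return Strategy(name=doc["name"], root=root)
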