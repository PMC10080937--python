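"""One-way deterministic sensitivity analysis (tornado diagram data).

Each uncertain parameter is moved in turn to the bounds of an equal-tailed
interval of its uncertainty distribution (default 95%), all other
parameters held at base values, and the chosen incremental metric is
re-evaluated. Entries are sorted by descending output range, ties broken
alphabetically, which is the bar ordering of a tornado diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cua import CUAResult, evaluate_base_case
from .parameters import UNCERTAIN_PARAMETERS, ParameterTable, interval_bounds

__all__ = ["TornadoEntry", "one_way_tornado", "TORNADO_METRICS"]

TORNADO_METRICS = ("delta_cost", "delta_qaly", "incremental_nmb")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    low_output: float
    high_output: float

    @property
    def range(self) -> float:
        return abs(self.high_output - self.low_output)


def _metric(result: CUAResult, metric: str) -> float:
    if metric == "delta_cost":
        return result.delta_cost
    if metric == "delta_qaly":
        return result.delta_qaly
    if metric == "incremental_nmb":
        return result.wtp * result.delta_qaly - result.delta_cost
    raise ValueError(f"unknown tornado metric {metric!r}; choose from {TORNADO_METRICS}")


def one_way_tornado(
    params: ParameterTable,
    metric: str = "incremental_nmb",
    level: float = 0.95,
) -> list[TornadoEntry]:
    """Tornado entries for all seven uncertain parameters.

    A parameter with a point distribution yields a zero-range entry. Interval
    bounds are truncated to the parameter's support where needed (the
    relative-risk upper bound is clipped so p_ari*rr stays feasible).
    """
    if metric not in TORNADO_METRICS:
        raise ValueError(f"unknown tornado metric {metric!r}; choose from {TORNADO_METRICS}")
    entries = []
    for name in UNCERTAIN_PARAMETERS:
        spec = params.dists.get(name)
        if spec is None:
            raise ValueError(f"parameter {name} has no distribution and no bounds")
        low, high = interval_bounds(spec, level)
        if name == "rr_vitd" and params.p_ari > 0.0:
            high = min(high, 1.0 / params.p_ari)
        outputs = [
            _metric(evaluate_base_case(params.with_value(name, value)), metric)
            for value in (low, high)
        ]
        entries.append(TornadoEntry(name, low, high, outputs[0], outputs[1]))
    entries.sort(key=lambda e: (-e.range, e.parameter))
    return entries
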