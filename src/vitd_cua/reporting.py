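"""Result serialization, provenance manifests and deterministic formatting.

Costs print to 2 decimals and probabilities/utilities to 6 in CSV; JSON
keeps full precision. Every tabular output carries a provenance header
(comment lines with the config hash, seed and draw count) and is
accompanied by a run manifest, so identical configuration and seed yield
byte-identical numeric outputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .cua import CUAResult
from .dsa import TornadoEntry

__all__ = [
    "RunManifest",
    "config_hash",
    "cua_to_frame",
    "cua_to_dict",
    "tornado_to_frame",
    "write_csv",
    "write_json",
]


def config_hash(config_text: str) -> str:
    return hashlib.sha256(config_text.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    subcommand: str
    config_hash: str
    seed: int | None = None
    n_draws: int | None = None
    package_version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _provenance_lines(manifest: RunManifest | None) -> str:
    if manifest is None:
        return ""
    parts = [f"config_hash={manifest.config_hash}"]
    if manifest.seed is not None:
        parts.append(f"seed={manifest.seed}")
    if manifest.n_draws is not None:
        parts.append(f"n={manifest.n_draws}")
    return "# " + " ".join(parts) + "\n"


def cua_to_frame(result: CUAResult) -> pd.DataFrame:
    """Incremental-analysis table: strategy, cost, diff_cost, qaly, diff_qaly, nmb.

    Cost/QALY differences are printed on the comparator row in the savings
    orientation (comparator minus intervention), the convention of published
    cost-effectiveness tables.
    """
    rows = [
        {
            "strategy": result.intervention.name,
            "cost": result.intervention.expected_cost,
            "diff_cost": "",
            "qaly": result.intervention.expected_qaly,
            "diff_qaly": "",
            "nmb": result.nmb[result.intervention.name],
        },
        {
            "strategy": result.comparator.name,
            "cost": result.comparator.expected_cost,
            "diff_cost": result.savings,
            "qaly": result.comparator.expected_qaly,
            "diff_qaly": -result.delta_qaly,
            "nmb": result.nmb[result.comparator.name],
        },
    ]
    return pd.DataFrame(rows)


def cua_to_dict(result: CUAResult) -> dict:
    return {
        "strategies": {
            result.intervention.name: {
                "expected_cost": result.intervention.expected_cost,
                "expected_qaly": result.intervention.expected_qaly,
                "nmb": result.nmb[result.intervention.name],
            },
            result.comparator.name: {
                "expected_cost": result.comparator.expected_cost,
                "expected_qaly": result.comparator.expected_qaly,
                "nmb": result.nmb[result.comparator.name],
            },
        },
        "delta_cost": result.delta_cost,
        "delta_qaly": result.delta_qaly,
        "savings": result.savings,
        "wtp": result.wtp,
        "classification": result.classification.kind,
        "icer": result.classification.icer_value,
    }


def tornado_to_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "low_output": e.low_output,
                "high_output": e.high_output,
                "range": e.range,
            }
            for e in entries
        ]
    )


_COST_COLUMNS = {
    "cost",
    "diff_cost",
    "nmb",
    "wtp",
    "delta_cost",
    "cost_comparator",
    "cost_intervention",
    "mean_nmb",
    "c_ari_day",
    "c_vitd_day",
}


def _format_value(column: str, value) -> str:
    if isinstance(value, str) or value is None or pd.isna(value):
        return "" if value is None or (not isinstance(value, str) and pd.isna(value)) else value
    if column in _COST_COLUMNS:
        return f"{value:.2f}"
    if column == "draw":
        return str(int(value))
    return f"{value:.6f}"


def write_csv(frame: pd.DataFrame, path: str | Path, manifest: RunManifest | None = None) -> None:
    """Deterministic CSV: fixed column order, 2 decimals for money, 6 for the rest."""
    formatted = frame.copy()
    for column in formatted.columns:
        formatted[column] = [_format_value(column, v) for v in formatted[column]]
    text = _provenance_lines(manifest) + formatted.to_csv(index=False)
    Path(path).write_text(text)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
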