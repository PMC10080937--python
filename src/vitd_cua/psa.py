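"""Second-order Monte Carlo probabilistic sensitivity analysis.

Parameter values are sampled jointly and independently from their
uncertainty distributions; the decision tree is rebuilt and rolled back for
every draw, with both strategies sharing the draw's parameter values
(common random numbers). The per-draw increments feed the
cost-effectiveness plane, the cost-effectiveness acceptability curve
(CEAC) and the acceptability frontier.

Sampling is parameter-major: each parameter has its own random stream,
keyed by the run seed and a stable digest of the parameter name, so adding
a parameter never perturbs another parameter's draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cua import net_monetary_benefit
from .parameters import UNCERTAIN_PARAMETERS, ParameterTable
from .tree_engine import COMPARATOR, INTERVENTION, build_trees_from_values, rollback

__all__ = [
    "PSAResult",
    "sample_parameter_draws",
    "run_psa",
    "ceac_curve",
    "quadrant_shares",
    "acceptability_frontier",
    "default_wtp_grid",
]

#: Boundary rule for the CE plane: points on a quadrant boundary are
#: assigned to the adjacent quadrant clockwise (x = delta QALY, y = delta cost):
#: +x axis -> SE, +y axis -> NE, -x axis -> NW, -y axis -> SW, origin -> NE.
QUADRANT_BOUNDARY_RULE = "adjacent-clockwise"


def default_wtp_grid() -> np.ndarray:
    """Default willingness-to-pay grid: 0 to 60,000 USD/QALY in steps of 500."""
    return np.arange(0.0, 60_500.0, 500.0)


def _param_rng(seed: int, name: str) -> np.random.Generator:
    digest = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))


def sample_parameter_draws(params: ParameterTable, n: int, seed: int) -> pd.DataFrame:
    """``n`` independent joint draws of the uncertain parameters.

    Parameters without a distribution entry are held at their point value.
    Deterministic under (params, n, seed).
    """
    if n < 1:
        raise ValueError(f"draw count must be at least 1, got {n}")
    columns = {}
    for name in UNCERTAIN_PARAMETERS:
        spec = params.dists.get(name)
        if spec is None or spec.family == "point":
            columns[name] = np.full(n, getattr(params, name))
        else:
            columns[name] = spec.sample(_param_rng(seed, name), n)
    frame = pd.DataFrame(columns)
    frame.insert(0, "draw", np.arange(n))
    return frame


@dataclass
class PSAResult:
    """Per-draw strategy outcomes and increments.

    ``draws`` has one row per replication: the sampled parameter values, the
    expected cost/QALY of both strategies under those values, and the
    increments (intervention minus comparator). ``n_capped`` counts draws
    where p_ari*rr exceeded 1 and the ARI probability was clamped to 1.
    """

    draws: pd.DataFrame
    n_draws: int
    seed: int
    n_capped: int = 0
    metadata: dict = field(default_factory=dict)


def run_psa(
    params: ParameterTable,
    n: int,
    seed: int,
    *,
    resample_infeasible: bool = False,
    max_resample_rounds: int = 100,
) -> PSAResult:
    """Evaluate the decision tree for each of ``n`` joint parameter draws.

    Draws with p_ari*rr > 1 (possible since the lognormal relative risk is
    unbounded above) have the supplemented-arm ARI probability capped at 1
    and are counted in ``n_capped``; with ``resample_infeasible`` such draws
    are redrawn from a continuation of the same streams instead.
    """
    table = sample_parameter_draws(params, n, seed)
    if resample_infeasible:
        rng_round = 1
        while (table["p_ari"] * table["rr_vitd"] > 1.0).any():
            if rng_round > max_resample_rounds:
                raise RuntimeError("could not find feasible draws by resampling")
            bad = table["p_ari"] * table["rr_vitd"] > 1.0
            fresh = sample_parameter_draws(params, n, seed + rng_round)
            cols = list(UNCERTAIN_PARAMETERS)
            table.loc[bad, cols] = fresh.loc[bad.values, cols].values
            rng_round += 1

    n_capped = int((table["p_ari"] * table["rr_vitd"] > 1.0).sum())

    scale = params.horizon_days / 365.0 if params.scale_by_horizon else 1.0
    cost_c = np.empty(n)
    qaly_c = np.empty(n)
    cost_i = np.empty(n)
    qaly_i = np.empty(n)
    for row in table.itertuples(index=False):
        comparator, intervention = build_trees_from_values(
            row.p_ari,
            row.rr_vitd,
            row.m_ari,
            row.m_all,
            row.du_ari,
            row.c_ari_day,
            row.c_vitd_day,
            params.episode_days,
            params.suppl_days,
            cap_probability=True,
        )
        i = int(row.draw)
        cost_c[i], u_c = rollback(comparator)
        cost_i[i], u_i = rollback(intervention)
        qaly_c[i] = u_c * scale
        qaly_i[i] = u_i * scale

    out = table.copy()
    out["cost_comparator"] = cost_c
    out["qaly_comparator"] = qaly_c
    out["cost_intervention"] = cost_i
    out["qaly_intervention"] = qaly_i
    out["delta_cost"] = cost_i - cost_c
    out["delta_qaly"] = qaly_i - qaly_c
    return PSAResult(
        draws=out,
        n_draws=n,
        seed=seed,
        n_capped=n_capped,
        metadata={"quadrant_boundary_rule": QUADRANT_BOUNDARY_RULE},
    )


def ceac_curve(psa: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Probability each strategy is cost-effective across willingness-to-pay values.

    At each lambda the intervention's probability is the fraction of draws
    with positive incremental net benefit lambda*dQ - dC; ties go to the
    comparator, so the two probabilities always sum to 1.
    """
    if psa.n_draws == 0 or len(psa.draws) == 0:
        raise ValueError("empty PSA result")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    dq = psa.draws["delta_qaly"].to_numpy()
    dc = psa.draws["delta_cost"].to_numpy()
    p_int = np.array([(lam * dq - dc > 0.0).mean() for lam in grid])
    return pd.DataFrame(
        {"wtp": grid, "p_intervention": p_int, "p_comparator": 1.0 - p_int}
    )


def quadrant_shares(psa: PSAResult, wtp: float) -> dict[str, float]:
    """CE-plane quadrant shares and the below-WTP (positive net benefit) share.

    Quadrants on the (delta QALY, delta cost) plane: NE more effective &
    costlier, SE more effective & cheaper, SW less effective & cheaper,
    NW less effective & costlier. Boundary points follow
    ``QUADRANT_BOUNDARY_RULE``. Shares sum to 1.
    """
    if psa.n_draws == 0 or len(psa.draws) == 0:
        raise ValueError("empty PSA result")
    dq = psa.draws["delta_qaly"].to_numpy()
    dc = psa.draws["delta_cost"].to_numpy()
    n = dq.size

    ne = (dq > 0) & (dc > 0)
    se = (dq > 0) & (dc < 0)
    sw = (dq < 0) & (dc < 0)
    nw = (dq < 0) & (dc > 0)
    # boundary: adjacent quadrant clockwise
    se |= (dq > 0) & (dc == 0)
    ne |= (dq == 0) & (dc > 0)
    nw |= (dq < 0) & (dc == 0)
    sw |= (dq == 0) & (dc < 0)
    ne |= (dq == 0) & (dc == 0)

    return {
        "NE": float(ne.mean()),
        "SE": float(se.mean()),
        "SW": float(sw.mean()),
        "NW": float(nw.mean()),
        "below_wtp": float((wtp * dq - dc > 0.0).sum()) / n,
    }


def acceptability_frontier(psa: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """At each lambda, the strategy maximizing mean NMB and its CEAC value.

    The frontier strategy is the one a net-benefit-maximizing decision maker
    would adopt; its CEAC value is the probability that the adopted strategy
    is in fact the cost-effective one.
    """
    ceac = ceac_curve(psa, wtp_grid)
    cost_i = psa.draws["cost_intervention"].to_numpy()
    qaly_i = psa.draws["qaly_intervention"].to_numpy()
    cost_c = psa.draws["cost_comparator"].to_numpy()
    qaly_c = psa.draws["qaly_comparator"].to_numpy()

    rows = []
    for _, rec in ceac.iterrows():
        lam = rec["wtp"]
        nmb_i = net_monetary_benefit(cost_i.mean(), qaly_i.mean(), lam)
        nmb_c = net_monetary_benefit(cost_c.mean(), qaly_c.mean(), lam)
        if nmb_i >= nmb_c:
            frontier, p, nmb = INTERVENTION, rec["p_intervention"], nmb_i
        else:
            frontier, p, nmb = COMPARATOR, rec["p_comparator"], nmb_c
        rows.append(
            {
                "wtp": lam,
                "frontier_strategy": frontier,
                "ceac_value": p,
                "mean_nmb": nmb,
            }
        )
    return pd.DataFrame(rows)
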