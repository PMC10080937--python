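"""Monte Carlo PSA: sampling, per-draw outcomes, CEAC, plane, frontier."""

import math

import numpy as np
import pandas as pd
import pytest

from vitd_cua import (
    DistributionSpec,
    acceptability_frontier,
    ceac_curve,
    closed_form_increments,
    evaluate_base_case,
    quadrant_shares,
    run_psa,
    sample_parameter_draws,
)
from vitd_cua.parameters import UNCERTAIN_PARAMETERS
from vitd_cua.psa import PSAResult
from vitd_cua.scenario_gen import null_scenario
from vitd_cua.tree_engine import COMPARATOR, INTERVENTION

SEED = 20230406


def make_psa(dq, dc):
    """Hand-built PSA result from per-draw increments (plane/CEAC unit tests)."""
    n = len(dq)
    frame = pd.DataFrame(
        {
            "draw": np.arange(n),
            "cost_comparator": np.zeros(n),
            "qaly_comparator": np.zeros(n),
            "cost_intervention": np.asarray(dc, dtype=float),
            "qaly_intervention": np.asarray(dq, dtype=float),
            "delta_cost": np.asarray(dc, dtype=float),
            "delta_qaly": np.asarray(dq, dtype=float),
        }
    )
    return PSAResult(draws=frame, n_draws=n, seed=0)


class TestSampling:
    def test_same_seed_gives_bitwise_identical_draws(self, base_table):
        a = sample_parameter_draws(base_table, 500, SEED)
        b = sample_parameter_draws(base_table, 500, SEED)
        pd.testing.assert_frame_equal(a, b)
        c = sample_parameter_draws(base_table, 500, SEED + 1)
        assert not a["p_ari"].equals(c["p_ari"])

    def test_point_distributions_reproduce_base_values(self, null_table):
        draws = sample_parameter_draws(null_table, 50, SEED)
        assert (draws["rr_vitd"] == 1.0).all()
        assert (draws["c_vitd_day"] == 0.0).all()

    def test_sample_mean_recovers_ari_probability(self, base_table):
        draws = sample_parameter_draws(base_table, 10_000, SEED)
        assert abs(draws["p_ari"].mean() - 0.22) <= 4 * 0.005 / math.sqrt(10_000)

    def test_parameter_streams_independent_of_each_other(self, base_table):
        """Collapsing one parameter to a point must not move other draws."""
        frozen = base_table.with_value("m_ari", base_table.m_ari)
        a = sample_parameter_draws(base_table, 200, SEED)
        b = sample_parameter_draws(frozen, 200, SEED)
        for name in UNCERTAIN_PARAMETERS:
            if name != "m_ari":
                assert a[name].equals(b[name])

    def test_invalid_draw_count_rejected(self, base_table):
        with pytest.raises(ValueError):
            sample_parameter_draws(base_table, 0, SEED)


class TestRunPSA:
    def test_null_scenario_increments_all_zero(self, null_table):
        result = run_psa(null_table, 200, SEED)
        assert (result.draws["delta_cost"] == 0.0).all()
        assert (result.draws["delta_qaly"] == 0.0).all()

    def test_per_draw_increments_match_closed_form(self, base_table):
        """Each draw's tree roll-back equals the analytic increment identities."""
        result = run_psa(base_table, 200, SEED)
        for row in result.draws.itertuples(index=False):
            table = base_table.model_copy(
                update={name: getattr(row, name) for name in UNCERTAIN_PARAMETERS},
                deep=False,
            )
            dc = (
                table.c_vitd_day * table.suppl_days
                - table.p_ari * (1 - table.rr_vitd) * table.c_ari_day * table.episode_days
            )
            dq = table.p_ari * (1 - table.rr_vitd) * (
                (1 - table.m_all) - (1 - table.m_ari) * (1 - table.du_ari)
            )
            assert abs(row.delta_cost - dc) <= 1e-12 * max(1.0, abs(row.cost_comparator))
            assert abs(row.delta_qaly - dq) <= 1e-12

    def test_psa_mean_close_to_plugin_base_case(self, base_table):
        """Second-order means agree with the plug-in roll-back within 4 SE."""
        result = run_psa(base_table, 10_000, SEED)
        base = evaluate_base_case(base_table)
        for col, target in (
            ("qaly_intervention", base.intervention.expected_qaly),
            ("qaly_comparator", base.comparator.expected_qaly),
        ):
            se = result.draws[col].std(ddof=1) / math.sqrt(len(result.draws))
            assert abs(result.draws[col].mean() - target) <= 4 * se

    def test_capped_draws_counted(self, base_table):
        wild = base_table.with_value("p_ari", 0.9)
        data = wild.model_dump()
        data["dists"] = {
            **dict(wild.dists),
            "rr_vitd": DistributionSpec(family="lognormal", center=0.71, spread=1.5),
        }
        from vitd_cua import ParameterTable

        table = ParameterTable(**data)
        result = run_psa(table, 500, SEED)
        capped = (result.draws["p_ari"] * result.draws["rr_vitd"] > 1.0).sum()
        assert result.n_capped == capped > 0

    def test_resampling_eliminates_infeasible_draws(self, base_table):
        wild = base_table.with_value("p_ari", 0.9)
        data = wild.model_dump()
        data["dists"] = {
            **dict(wild.dists),
            "rr_vitd": DistributionSpec(family="lognormal", center=0.71, spread=1.5),
        }
        from vitd_cua import ParameterTable

        result = run_psa(ParameterTable(**data), 500, SEED, resample_infeasible=True)
        assert result.n_capped == 0


class TestCEAC:
    def test_probabilities_sum_to_one(self, base_table):
        result = run_psa(base_table, 1000, SEED)
        curve = ceac_curve(result, [0, 4000, 19_000, 60_000])
        assert np.allclose(curve["p_intervention"] + curve["p_comparator"], 1.0)

    def test_null_scenario_with_positive_supplement_cost(self):
        """Every draw has dNMB = -14.56: the intervention never wins."""
        from vitd_cua import ParameterTable

        data = null_scenario().model_dump()
        data["c_vitd_day"] = 0.08
        data["dists"] = {
            **dict(null_scenario().dists),
            "c_vitd_day": DistributionSpec(family="point", center=0.08),
        }
        result = run_psa(ParameterTable(**data), 300, SEED)
        curve = ceac_curve(result, [0, 10_000, 60_000])
        assert (curve["p_intervention"] == 0.0).all()

    def test_ties_favor_comparator(self, null_table):
        result = run_psa(null_table, 100, SEED)
        curve = ceac_curve(result, [0, 19_000])
        assert (curve["p_intervention"] == 0.0).all()

    def test_dominant_point_mass_gives_probability_one(self):
        psa = make_psa(dq=[0.01] * 5, dc=[-500.0] * 5)
        curve = ceac_curve(psa, [0, 19_000, 60_000])
        assert (curve["p_intervention"] == 1.0).all()

    def test_monotone_in_wtp_when_all_draws_effective(self, base_table):
        result = run_psa(base_table, 2000, SEED)
        keep = result.draws[result.draws["delta_qaly"] >= 0]
        filtered = PSAResult(draws=keep.reset_index(drop=True), n_draws=len(keep), seed=SEED)
        curve = ceac_curve(filtered, np.arange(0, 60_500, 500))
        assert (np.diff(curve["p_intervention"]) >= -1e-12).all()

    def test_empty_grid_rejected(self, base_table):
        result = run_psa(base_table, 10, SEED)
        with pytest.raises(ValueError):
            ceac_curve(result, [])


class TestQuadrantShares:
    def test_all_dominant_draws_land_in_se(self):
        psa = make_psa(dq=[0.01, 0.02], dc=[-10.0, -20.0])
        shares = quadrant_shares(psa, 19_000)
        assert shares["SE"] == 1.0
        assert shares["NE"] == shares["SW"] == shares["NW"] == 0.0

    def test_one_draw_per_quadrant(self):
        psa = make_psa(dq=[0.01, 0.01, -0.01, -0.01], dc=[10.0, -10.0, -10.0, 10.0])
        shares = quadrant_shares(psa, 19_000)
        assert shares["NE"] == shares["SE"] == shares["SW"] == shares["NW"] == 0.25

    def test_shares_sum_to_one_with_boundary_points(self):
        psa = make_psa(dq=[0.01, 0.0, -0.01, 0.0, 0.0], dc=[0.0, 10.0, 0.0, -10.0, 0.0])
        shares = quadrant_shares(psa, 19_000)
        total = shares["NE"] + shares["SE"] + shares["SW"] + shares["NW"]
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_below_wtp_share_equals_ceac_value(self, base_table):
        result = run_psa(base_table, 1000, SEED)
        shares = quadrant_shares(result, 19_000)
        curve = ceac_curve(result, [19_000])
        assert shares["below_wtp"] == curve["p_intervention"].iloc[0]


class TestFrontier:
    def test_dominant_point_mass_frontier_is_intervention(self):
        psa = make_psa(dq=[0.01] * 4, dc=[-100.0] * 4)
        frontier = acceptability_frontier(psa, [0, 19_000, 60_000])
        assert (frontier["frontier_strategy"] == INTERVENTION).all()

    def test_null_with_supplement_cost_frontier_is_comparator(self):
        psa = make_psa(dq=[0.0] * 4, dc=[14.56] * 4)
        frontier = acceptability_frontier(psa, [0, 19_000])
        assert (frontier["frontier_strategy"] == COMPARATOR).all()
        assert (frontier["ceac_value"] == 1.0).all()

    def test_frontier_maximizes_mean_nmb(self, base_table):
        result = run_psa(base_table, 500, SEED)
        frontier = acceptability_frontier(result, [0, 5000, 19_000])
        cost_i = result.draws["cost_intervention"].mean()
        qaly_i = result.draws["qaly_intervention"].mean()
        cost_c = result.draws["cost_comparator"].mean()
        qaly_c = result.draws["qaly_comparator"].mean()
        for _, rec in frontier.iterrows():
            other = (
                rec["wtp"] * qaly_c - cost_c
                if rec["frontier_strategy"] == INTERVENTION
                else rec["wtp"] * qaly_i - cost_i
            )
            assert rec["mean_nmb"] >= other - 1e-9


class TestReproducibility:
    def test_identical_inputs_identical_results(self, base_table):
        a = run_psa(base_table, 300, SEED)
        b = run_psa(base_table, 300, SEED)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(
            ceac_curve(a, [0, 19_000]), ceac_curve(b, [0, 19_000])
        )
        assert quadrant_shares(a, 19_000) == quadrant_shares(b, 19_000)
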