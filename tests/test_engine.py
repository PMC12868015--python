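"""Markov cohort engine: transition matrices, discounting, trace algebra."""

import numpy as np
import pytest

from cryocea.engine import (
    DEAD,
    DISEASE_FREE,
    STATES,
    build_transition_matrix,
    discount_factor,
    run_cohort,
)
from cryocea.fixtures import generate_synthetic_scenario
from cryocea.params import UncertainParam, VariantFlags

from _helpers import brute_force_totals


def _prob(v):
    return UncertainParam(base_value=v, unit="probability_per_year")


class TestDiscountFactor:
    def test_values(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(1, 0.03) == pytest.approx(0.970874, abs=1e-6)
        total = sum(discount_factor(k, 0.03) for k in range(5))
        assert total == pytest.approx(4.717098, abs=1e-6)

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)


class TestTransitionMatrix:
    def test_bca_base_disease_free_persistence(self, low_risk):
        P = build_transition_matrix(low_risk.bca, low_risk.structural_variant)
        # 1 - 0.0086 - 0.0023 - 0.0073
        assert P[DISEASE_FREE, DISEASE_FREE] == pytest.approx(0.9818, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_rows_stochastic(self, seed):
        sc = generate_synthetic_scenario(seed)
        for arm in ("bca", "bcs"):
            P = build_transition_matrix(getattr(sc, arm), sc.structural_variant)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-15)
            assert (P >= 0).all()
            assert P[DEAD, DEAD] == 1.0

    def test_zero_risks_identity_on_alive_states(self, low_risk):
        sp = low_risk.bca.model_copy(
            update={
                "p_local_annual": _prob(0.0),
                "p_distant_annual": _prob(0.0),
                "p_mortality_annual": _prob(0.0),
            }
        )
        P = build_transition_matrix(sp, VariantFlags())
        np.testing.assert_array_equal(P, np.eye(4))

    def test_probabilities_summing_above_one_rejected(self, low_risk):
        sp = low_risk.bca.model_copy(
            update={
                "p_local_annual": _prob(0.6),
                "p_distant_annual": _prob(0.3),
            }
        )
        sp = sp.model_copy(update={"p_mortality_annual": _prob(0.2)})
        with pytest.raises(ValueError):
            build_transition_matrix(sp, VariantFlags())

    def test_mortality_routing_flags(self, low_risk):
        pM = low_risk.bca.p_mortality_annual.base_value
        P_all = build_transition_matrix(
            low_risk.bca, VariantFlags(mortality_source_states="all_alive")
        )
        P_df = build_transition_matrix(
            low_risk.bca, VariantFlags(mortality_source_states="disease_free_only")
        )
        assert P_all[1, DEAD] == pytest.approx(pM) and P_all[2, DEAD] == pytest.approx(pM)
        assert P_df[1, DEAD] == 0.0 and P_df[2, 2] == 1.0


def _degenerate(low_risk, procedure_cost=2501.0):
    """All risks zero, all utilities 1, no disutilities, routine cost only."""
    from cryocea.params import point

    sc = low_risk.model_copy(deep=True)
    for arm in (sc.bca, sc.bcs):
        arm.p_local_annual = _prob(0.0)
        arm.p_distant_annual = _prob(0.0)
        arm.p_mortality_annual = _prob(0.0)
        arm.complication_prob = _prob(0.0)
        arm.treatment_disutility = UncertainParam(base_value=0.0, unit="utility")
        arm.procedure_cost = UncertainParam(
            base_value=procedure_cost, dist=point(procedure_cost), unit="usd"
        )
    for name in ("u_first_year", "u_subsequent", "u_local", "u_distant"):
        setattr(sc.shared, name, UncertainParam(base_value=1.0, unit="utility"))
    return sc


class TestRunCohort:
    def test_degenerate_geometric_series(self, low_risk):
        sc = _degenerate(low_risk)
        res = run_cohort(sc, "bca")
        series = sum(1.03 ** (-k) for k in range(5))
        assert res.total_qaly == pytest.approx(series, abs=1e-9)
        assert res.total_cost == pytest.approx(2501.0 + 36_351.0 * series, rel=1e-12)

    def test_no_discount_no_events_closed_form(self, low_risk):
        sc = _degenerate(low_risk)
        sc.econ = sc.econ.model_copy(update={"discount_rate": 0.0})
        assert run_cohort(sc, "bca").total_qaly == pytest.approx(5.0)

    def test_certain_mortality_entry_cycle(self, low_risk):
        sc = low_risk.model_copy(deep=True)
        sc.bca.p_local_annual = _prob(0.0)
        sc.bca.p_distant_annual = _prob(0.0)
        sc.bca.p_mortality_annual = _prob(1.0)
        sc.structural_variant = sc.structural_variant.model_copy(
            update={"event_timing": "entry_cycle", "dead_accrues_routine": False}
        )
        res = run_cohort(sc, "bca")
        u0 = (
            sc.shared.u_first_year.base_value
            - sc.bca.treatment_disutility.base_value
            - sc.bca.complication_prob.base_value
            * sc.bca.complication_disutility.base_value
        )
        assert res.total_qaly == pytest.approx(u0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(24))
    @pytest.mark.parametrize("arm", ["bca", "bcs"])
    def test_path_enumeration_oracle(self, seed, arm):
        """Matrix trace equals exhaustive 4^(H-1)-path enumeration to 1e-10."""
        sc = generate_synthetic_scenario(seed)
        res = run_cohort(sc, arm)
        cost, qaly = brute_force_totals(sc, arm)
        assert res.total_cost == pytest.approx(cost, rel=1e-10, abs=1e-8)
        assert res.total_qaly == pytest.approx(qaly, rel=1e-10, abs=1e-12)

    @pytest.mark.parametrize("seed", range(300, 500))
    def test_trace_conservation_and_absorbing_death(self, seed):
        sc = generate_synthetic_scenario(seed)
        res = run_cohort(sc, "bca")
        occ = res.trace.occupancy
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        assert (occ >= -1e-15).all()
        assert (np.diff(occ[:, DEAD]) >= -1e-15).all()

    def test_qaly_nonincreasing_in_mortality(self, low_risk):
        qalys = []
        for pm in np.linspace(0.0, 0.5, 11):
            sc = low_risk.model_copy(deep=True)
            sc.bca.p_mortality_annual = _prob(float(pm))
            qalys.append(run_cohort(sc, "bca").total_qaly)
        assert all(a >= b - 1e-12 for a, b in zip(qalys, qalys[1:]))

    def test_cost_slope_one_in_procedure_cost(self, low_risk):
        base = run_cohort(low_risk, "bca").total_cost
        sc = low_risk.model_copy(deep=True)
        sc.bca.procedure_cost = UncertainParam(base_value=2501.0 + 1234.5, unit="usd")
        assert run_cohort(sc, "bca").total_cost - base == pytest.approx(
            1234.5, abs=1e-9
        )

    def test_trace_export_schema(self, low_risk):
        frame = run_cohort(low_risk, "bcs").trace.to_frame()
        assert list(frame.columns) == [
            "cycle",
            "state",
            "occupancy",
            "discounted_cost",
            "discounted_qaly",
        ]
        assert len(frame) == 5 * len(STATES)
        res = run_cohort(low_risk, "bcs")
        assert frame["discounted_cost"].sum() + res.one_time_cost == pytest.approx(
            res.total_cost
        )

    def test_unknown_strategy_rejected(self, low_risk):
        with pytest.raises(ValueError):
            run_cohort(low_risk, "mastectomy")
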