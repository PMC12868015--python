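"""Discounted Markov cohort engine.

Four health states — disease-free (DF), local recurrence (LOCAL), distant
recurrence (DISTANT), dead (DEAD) — evolved over ``horizon_cycles`` one-year
cycles.  The cohort starts fully disease-free; the trace row for cycle 0 is
the pre-transition distribution and each later row applies the transition
matrix once, so a 5-cycle run involves 4 transitions and 5 reward points.

Reward semantics (fixed here, mirrored by the brute-force path oracle used in
the tests):

* cycle-``k`` rewards are computed from the trace row ``k`` under
  ``event_timing == "entry_cycle"`` and from row ``k-1`` (rewards lag the
  transition by one cycle) under ``"next_cycle"``;
* one-time recurrence entry costs are always charged in the cycle of entry,
  discounted by that cycle's index, regardless of ``event_timing``;
* cycle-0 one-time costs (procedure + expected complication cost) and the
  first-year utility decrements (treatment disutility, expected complication
  disutility) are applied undiscounted, to the disease-free fraction;
* everything else is discounted by ``(1 + r)^(-cycle_index)`` — no half-cycle
  correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .params import Scenario, StrategyParams, VariantFlags

__all__ = [
    "STATES",
    "DISEASE_FREE",
    "LOCAL_REC",
    "DISTANT_REC",
    "DEAD",
    "discount_factor",
    "build_transition_matrix",
    "CohortTrace",
    "StrategyResult",
    "run_cohort",
]

STATES = ("disease_free", "local_recurrence", "distant_recurrence", "dead")
DISEASE_FREE, LOCAL_REC, DISTANT_REC, DEAD = range(4)


def discount_factor(cycle_index: int, rate: float) -> float:
    """``(1 + rate)^(-cycle_index)``; cycle 0 is undiscounted."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    return (1.0 + rate) ** (-cycle_index)


def build_transition_matrix(sp: StrategyParams, flags: VariantFlags) -> np.ndarray:
    """Row-stochastic 4x4 annual transition matrix for one arm.

    The disease-free row is ``[1-pL-pD-pM, pL, pD, pM]``.  Recurrence states
    self-persist (a local recurrence is not re-treated and cannot return to
    disease-free within the horizon); whether they are additionally exposed
    to cancer mortality is governed by ``flags.mortality_source_states``.
    DEAD is absorbing.
    """
    pL = sp.p_local_annual.base_value
    pD = sp.p_distant_annual.base_value
    pM = sp.p_mortality_annual.base_value
    s = pL + pD + pM
    if s > 1.0 + 1e-12:
        raise ValueError(f"annual probabilities sum to {s:.6f} > 1")
    P = np.zeros((4, 4))
    P[DISEASE_FREE] = [1.0 - s, pL, pD, pM]
    if flags.mortality_source_states == "all_alive":
        P[LOCAL_REC, LOCAL_REC] = 1.0 - pM
        P[LOCAL_REC, DEAD] = pM
        P[DISTANT_REC, DISTANT_REC] = 1.0 - pM
        P[DISTANT_REC, DEAD] = pM
    else:
        P[LOCAL_REC, LOCAL_REC] = 1.0
        P[DISTANT_REC, DISTANT_REC] = 1.0
    P[DEAD, DEAD] = 1.0
    return P


@dataclass
class CohortTrace:
    """State occupancy and per-cycle discounted rewards.

    ``cycle_cost`` / ``cycle_qaly`` are per-cycle, per-state discounted
    contributions of shape ``(H, 4)``; the cycle-0 one-time costs are *not*
    included here (see :class:`StrategyResult`).
    """

    occupancy: np.ndarray  # (H, 4)
    cycle_cost: np.ndarray  # (H, 4), discounted USD
    cycle_qaly: np.ndarray  # (H, 4), discounted QALY

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: cycle, state, occupancy, discounted_cost,
        discounted_qaly."""
        H = self.occupancy.shape[0]
        rows = []
        for k in range(H):
            for j, state in enumerate(STATES):
                rows.append(
                    {
                        "cycle": k,
                        "state": state,
                        "occupancy": self.occupancy[k, j],
                        "discounted_cost": self.cycle_cost[k, j],
                        "discounted_qaly": self.cycle_qaly[k, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class StrategyResult:
    """Totals for one arm: ``total_cost = one_time_cost + cycle costs``."""

    total_cost: float
    total_qaly: float
    one_time_cost: float
    trace: CohortTrace


def _arm(scenario: Scenario, strategy: str) -> StrategyParams:
    if strategy not in ("bca", "bcs"):
        raise ValueError(f"strategy must be 'bca' or 'bcs', got {strategy!r}")
    return getattr(scenario, strategy)


def run_cohort(
    scenario: Scenario, strategy: Literal["bca", "bcs"]
) -> StrategyResult:
    """Run the discounted cohort simulation for one arm of a scenario."""
    sp = _arm(scenario, strategy)
    sh = scenario.shared
    econ = scenario.econ
    flags = scenario.structural_variant
    H = econ.horizon_cycles

    P = build_transition_matrix(sp, flags)
    pL = P[DISEASE_FREE, LOCAL_REC]
    pD = P[DISEASE_FREE, DISTANT_REC]

    occ = np.zeros((H, 4))
    occ[0, DISEASE_FREE] = 1.0
    for k in range(1, H):
        occ[k] = occ[k - 1] @ P

    d = np.array([discount_factor(k, econ.discount_rate) for k in range(H)])

    routine = sh.routine_annual_cost.base_value + sp.routine_cost_increment.base_value
    lr_cost = sh.local_recurrence_cost.base_value
    dr_cost = sh.advanced_disease_cost.base_value
    comp_p = sp.complication_prob.base_value

    u_df_first = (
        sh.u_first_year.base_value
        - sp.treatment_disutility.base_value
        - comp_p * sp.complication_disutility.base_value
    )

    cost = np.zeros((H, 4))
    qaly = np.zeros((H, 4))
    for k in range(H):
        r = occ[k] if flags.event_timing == "entry_cycle" else occ[max(k - 1, 0)]
        inflow_L = occ[k - 1, DISEASE_FREE] * pL if k >= 1 else 0.0
        inflow_D = occ[k - 1, DISEASE_FREE] * pD if k >= 1 else 0.0

        cost[k, DISEASE_FREE] = routine * r[DISEASE_FREE]
        if flags.dead_accrues_routine:
            cost[k, DEAD] = routine * r[DEAD]

        if flags.lr_cost_mode == "per_cycle":
            cost[k, LOCAL_REC] = lr_cost * r[LOCAL_REC]
        elif flags.lr_cost_mode == "one_time_on_entry":
            cost[k, LOCAL_REC] = lr_cost * inflow_L
        else:  # on_entry_plus_routine
            cost[k, LOCAL_REC] = lr_cost * inflow_L + routine * r[LOCAL_REC]

        if flags.dr_cost_mode == "per_cycle":
            cost[k, DISTANT_REC] = dr_cost * r[DISTANT_REC]
        elif flags.dr_cost_mode == "one_time_on_entry":
            cost[k, DISTANT_REC] = dr_cost * inflow_D
        else:
            cost[k, DISTANT_REC] = dr_cost * inflow_D + routine * r[DISTANT_REC]

        u_df = u_df_first if k == 0 else sh.u_subsequent.base_value
        qaly[k, DISEASE_FREE] = u_df * r[DISEASE_FREE]
        qaly[k, LOCAL_REC] = sh.u_local.base_value * r[LOCAL_REC]
        qaly[k, DISTANT_REC] = sh.u_distant.base_value * r[DISTANT_REC]
        # u_dead is fixed at 0

        cost[k] *= d[k]
        qaly[k] *= d[k]

    one_time = (
        sp.procedure_cost.base_value + comp_p * sp.complication_cost.base_value
    )
    trace = CohortTrace(occupancy=occ, cycle_cost=cost, cycle_qaly=qaly)
    return StrategyResult(
        total_cost=one_time + float(cost.sum()),
        total_qaly=float(qaly.sum()),
        one_time_cost=one_time,
        trace=trace,
    )
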