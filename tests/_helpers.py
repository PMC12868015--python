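"""Independent oracles and utilities for the test suite.

The brute-force oracle below re-derives a strategy's expected discounted
cost and QALYs by enumerating every state path of the cohort (4^(H-1) paths
for H cycles, the first cycle being disease-free by construction) and
weighting per-path rewards by path probability.  It shares nothing with the
matrix-based engine except the published reward conventions, so agreement is
a real check of the cohort algebra.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from cryocea.engine import (
    DEAD,
    DISEASE_FREE,
    DISTANT_REC,
    LOCAL_REC,
    build_transition_matrix,
)
from cryocea.params import Scenario, point


def brute_force_totals(scenario: Scenario, strategy: str) -> tuple[float, float]:
    """Expected (total_cost, total_qaly) by exhaustive path enumeration."""
    sp = getattr(scenario, strategy)
    sh = scenario.shared
    flags = scenario.structural_variant
    H = scenario.econ.horizon_cycles
    P = build_transition_matrix(sp, flags)
    d = [(1.0 + scenario.econ.discount_rate) ** (-k) for k in range(H)]

    routine = sh.routine_annual_cost.base_value + sp.routine_cost_increment.base_value
    lr_cost = sh.local_recurrence_cost.base_value
    dr_cost = sh.advanced_disease_cost.base_value
    comp_p = sp.complication_prob.base_value
    u_df_first = (
        sh.u_first_year.base_value
        - sp.treatment_disutility.base_value
        - comp_p * sp.complication_disutility.base_value
    )
    one_time = sp.procedure_cost.base_value + comp_p * sp.complication_cost.base_value

    def state_cost(state: int) -> float:
        if state == DISEASE_FREE:
            return routine
        if state == DEAD:
            return routine if flags.dead_accrues_routine else 0.0
        if state == LOCAL_REC:
            if flags.lr_cost_mode == "per_cycle":
                return lr_cost
            if flags.lr_cost_mode == "on_entry_plus_routine":
                return routine
            return 0.0
        if flags.dr_cost_mode == "per_cycle":
            return dr_cost
        if flags.dr_cost_mode == "on_entry_plus_routine":
            return routine
        return 0.0

    def state_utility(state: int, cycle: int) -> float:
        if state == DISEASE_FREE:
            return u_df_first if cycle == 0 else sh.u_subsequent.base_value
        if state == LOCAL_REC:
            return sh.u_local.base_value
        if state == DISTANT_REC:
            return sh.u_distant.base_value
        return 0.0

    total_cost = one_time
    total_qaly = 0.0
    for tail in product(range(4), repeat=H - 1):
        path = (DISEASE_FREE,) + tail
        prob = 1.0
        for k in range(1, H):
            prob *= P[path[k - 1], path[k]]
        if prob == 0.0:
            continue
        cost = 0.0
        qaly = 0.0
        for k in range(H):
            reward_state = (
                path[k] if flags.event_timing == "entry_cycle" else path[max(k - 1, 0)]
            )
            cost += state_cost(reward_state) * d[k]
            qaly += state_utility(reward_state, k) * d[k]
            # one-time recurrence entry costs, charged in the entry cycle
            if k >= 1 and path[k] != path[k - 1]:
                if path[k] == LOCAL_REC and flags.lr_cost_mode in (
                    "one_time_on_entry",
                    "on_entry_plus_routine",
                ):
                    cost += lr_cost * d[k]
                if path[k] == DISTANT_REC and flags.dr_cost_mode in (
                    "one_time_on_entry",
                    "on_entry_plus_routine",
                ):
                    cost += dr_cost * d[k]
        total_cost += prob * cost
        total_qaly += prob * qaly
    return total_cost, total_qaly


def as_point_scenario(scenario: Scenario) -> Scenario:
    """Copy of a scenario with every distribution collapsed to a point mass
    at its base value (degenerate PSA)."""
    from cryocea.params import UncertainParam

    sc = scenario.model_copy(deep=True)
    for group in ("bca", "bcs", "shared"):
        obj = getattr(sc, group)
        for name, value in obj:
            if isinstance(value, UncertainParam):
                setattr(
                    obj,
                    name,
                    value.model_copy(update={"dist": point(value.base_value)}),
                )
    return sc


def grid_search_threshold(f, lo: float, hi: float, n: int) -> float | None:
    """First zero crossing of ``f`` on an ``n``-point grid (midpoint of the
    first sign-changing interval), or None."""
    xs = np.linspace(lo, hi, n)
    prev = f(float(xs[0]))
    for x in xs[1:]:
        cur = f(float(x))
        if np.sign(prev) != np.sign(cur):
            return float(x) - 0.5 * (hi - lo) / (n - 1)
        prev = cur
    return None
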