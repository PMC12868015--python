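"""Probabilistic sensitivity analysis.

Each iteration draws every uncertain parameter from its distribution,
reruns both cohort arms, and records the comparison.  Parameters whose
economic-table rows are identical across arms (all shared costs/utilities,
plus the complication cost) are drawn once per iteration and applied to both
arms, inducing the positive correlation standard for "parallel cohorts";
independent sampling is available behind ``shared_draws=False``.

Reproducibility contract: one ``numpy`` Generator seeded per run, parameters
drawn in the fixed order below — same seed, bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import run_cohort
from .metrics import compare
from .params import Scenario, UncertainParam

__all__ = ["SHARED_DRAW_ORDER", "ARM_DRAW_ORDER", "draw_scenario", "PsaRun", "run_psa"]

#: draw order for parameters shared between arms (one draw, both arms)
SHARED_DRAW_ORDER = (
    "shared.routine_annual_cost",
    "shared.local_recurrence_cost",
    "shared.advanced_disease_cost",
    "shared.u_first_year",
    "shared.u_subsequent",
    "shared.u_local",
    "shared.u_distant",
)

#: draw order within each arm (bca first, then bcs)
ARM_DRAW_ORDER = (
    "procedure_cost",
    "complication_prob",
    "complication_cost",
    "treatment_disutility",
    "complication_disutility",
    "p_local_annual",
    "p_distant_annual",
    "p_mortality_annual",
    "routine_cost_increment",
)


def _clip_for_unit(value: float, unit: str) -> float:
    if unit == "probability_per_year":
        return min(max(value, 0.0), 1.0)
    if unit == "usd":
        return max(value, 0.0)
    if unit == "utility":
        return min(max(value, 0.0), 1.0)
    return value


def _drawn(param: UncertainParam, rng: np.random.Generator) -> UncertainParam:
    value = _clip_for_unit(param.dist.draw(rng), param.unit)
    return param.model_copy(update={"base_value": value})


def draw_scenario(
    base: Scenario, rng: np.random.Generator, shared_draws: bool = True
) -> Scenario:
    """One PSA realization: every uncertain parameter replaced by a draw.

    Draws land in ``base_value`` (the distributions are kept), so a scenario
    whose distributions are all point masses is returned unchanged.  If an
    arm's drawn annual event probabilities sum above 1 they are rescaled
    proportionally — essentially impossible for the published distributions
    but required for arbitrary synthetic ones.
    """
    sc = base.model_copy(deep=True)

    for path in SHARED_DRAW_ORDER:
        group, name = path.split(".")
        obj = getattr(sc, group)
        setattr(obj, name, _drawn(getattr(obj, name), rng))

    arm_shared = {
        name
        for name in ARM_DRAW_ORDER
        if shared_draws
        and getattr(base.bca, name) == getattr(base.bcs, name)
    }
    for arm_name in ("bca", "bcs"):
        arm = getattr(sc, arm_name)
        for name in ARM_DRAW_ORDER:
            if arm_name == "bcs" and name in arm_shared:
                setattr(arm, name, getattr(sc.bca, name))
            else:
                setattr(arm, name, _drawn(getattr(arm, name), rng))
        total = (
            arm.p_local_annual.base_value
            + arm.p_distant_annual.base_value
            + arm.p_mortality_annual.base_value
        )
        if total > 1.0:
            for name in ("p_local_annual", "p_distant_annual", "p_mortality_annual"):
                p = getattr(arm, name)
                setattr(
                    arm,
                    name,
                    p.model_copy(update={"base_value": p.base_value / total}),
                )
    return sc


DEFAULT_WTP_GRID = tuple(range(0, 200_001, 10_000))


@dataclass
class PsaRun:
    """Aggregated result of a probabilistic sensitivity analysis."""

    n_iterations: int
    seed: int
    wtp: float
    draws: pd.DataFrame  # per-iteration cost/qaly per arm + comparison
    ceac: pd.DataFrame  # columns: wtp, p_bca_preferred
    proportion_bca_preferred: float
    summary: pd.DataFrame = field(repr=False)  # mean/sd of cost & qaly per arm


def run_psa(
    base: Scenario,
    n: int,
    seed: int,
    wtp_grid=DEFAULT_WTP_GRID,
    shared_draws: bool = True,
) -> PsaRun:
    """Run ``n`` PSA iterations on ``base`` with the given seed.

    The headline ``proportion_bca_preferred`` is evaluated at the scenario's
    own willingness-to-pay; the CEAC re-evaluates each stored iteration over
    ``wtp_grid``.  Ties (exact NMB equality) count toward neither strategy.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    wtp = base.econ.wtp

    records = []
    for _ in range(n):
        sc = draw_scenario(base, rng, shared_draws=shared_draws)
        res_bca = run_cohort(sc, "bca")
        res_bcs = run_cohort(sc, "bcs")
        cr = compare(res_bca, res_bcs, wtp)
        records.append(
            (
                res_bca.total_cost,
                res_bca.total_qaly,
                res_bcs.total_cost,
                res_bcs.total_qaly,
                cr.delta_cost,
                cr.delta_qaly,
                cr.preferred,
            )
        )
    draws = pd.DataFrame.from_records(
        records,
        columns=[
            "cost_bca",
            "qaly_bca",
            "cost_bcs",
            "qaly_bcs",
            "inc_cost",
            "inc_qaly",
            "preferred",
        ],
    )
    draws.index.name = "iteration"

    proportion = float((draws["preferred"] == "bca").mean())

    inc_nmb = -draws["inc_cost"].to_numpy()
    inc_q = draws["inc_qaly"].to_numpy()
    ceac = pd.DataFrame(
        {
            "wtp": list(wtp_grid),
            "p_bca_preferred": [
                float(np.mean(w * inc_q + inc_nmb > 0.0)) for w in wtp_grid
            ],
        }
    )

    summary = pd.DataFrame(
        {
            "mean": draws[["cost_bca", "qaly_bca", "cost_bcs", "qaly_bcs"]].mean(),
            "sd": draws[["cost_bca", "qaly_bca", "cost_bcs", "qaly_bcs"]].std(
                ddof=1
            ),
        }
    )

    return PsaRun(
        n_iterations=n,
        seed=seed,
        wtp=wtp,
        draws=draws,
        ceac=ceac,
        proportion_bca_preferred=proportion,
        summary=summary,
    )
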