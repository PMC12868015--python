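"""Incremental cost-effectiveness statistics.

Conventions: deltas are BCA minus BCS; "dominant" means BCA is cheaper and
more effective; the preferred strategy is the argmax of net monetary benefit
at the given willingness-to-pay, with exact ties reported explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .engine import StrategyResult

__all__ = ["nmb", "ComparisonResult", "compare"]


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit: ``wtp * qaly - cost``."""
    if wtp < 0.0:
        raise ValueError("wtp must be >= 0")
    return wtp * qaly - cost


IcerFlag = Literal["dominant", "dominated", "tie", "icer"]
Preferred = Literal["bca", "bcs", "tie"]


@dataclass
class ComparisonResult:
    delta_cost: float  # BCA - BCS
    delta_qaly: float  # BCA - BCS
    icer: Optional[float]  # only when cost and QALY deltas share a sign
    icer_flag: IcerFlag
    nmb_bca: float
    nmb_bcs: float
    preferred: Preferred
    wtp: float


def compare(
    bca: StrategyResult, bcs: StrategyResult, wtp: float
) -> ComparisonResult:
    """Compare the two arms at one willingness-to-pay."""
    dc = bca.total_cost - bcs.total_cost
    dq = bca.total_qaly - bcs.total_qaly

    if dc < 0.0 and dq > 0.0:
        flag: IcerFlag = "dominant"
        icer = None
    elif dc > 0.0 and dq < 0.0:
        flag = "dominated"
        icer = None
    elif dc == 0.0 and dq == 0.0:
        flag = "tie"
        icer = None
    elif dc != 0.0 and dq != 0.0:
        # same nonzero sign: a genuine trade-off
        flag = "icer"
        icer = dc / dq
    else:
        # one delta exactly zero: weak dominance, no finite/meaningful ratio
        flag = "dominant" if (dc < 0.0 or dq > 0.0) else "dominated"
        icer = None

    n_bca = nmb(bca.total_cost, bca.total_qaly, wtp)
    n_bcs = nmb(bcs.total_cost, bcs.total_qaly, wtp)
    if n_bca > n_bcs:
        preferred: Preferred = "bca"
    elif n_bcs > n_bca:
        preferred = "bcs"
    else:
        preferred = "tie"

    return ComparisonResult(
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        icer_flag=flag,
        nmb_bca=n_bca,
        nmb_bcs=n_bcs,
        preferred=preferred,
        wtp=wtp,
    )
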