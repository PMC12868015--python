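"""Deterministic sensitivity analysis on the net-monetary-benefit difference.

All routines perturb one (or two) parameters of a scenario, rerun both
cohort arms at base values otherwise, and work with

    f(x) = NMB_bca(x) - NMB_bcs(x)

at the scenario's willingness-to-pay.  Parameters are addressed by
dot-separated paths (``"bca.procedure_cost"``, ``"shared.u_distant"``, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import run_cohort
from .metrics import compare, nmb
from .params import Scenario, UncertainParam

__all__ = [
    "ParamRef",
    "get_param",
    "with_value",
    "nmb_difference",
    "one_way_sweep",
    "ThresholdResult",
    "find_threshold",
    "two_way_map",
    "two_way_boundary",
    "tornado",
    "uncertain_param_paths",
]

_GROUPS = ("bca", "bcs", "shared")


@dataclass(frozen=True)
class ParamRef:
    """Dot-separated address of one uncertain parameter in a Scenario."""

    path: str

    @property
    def applies_to(self) -> str:
        group = self.path.split(".", 1)[0]
        if group not in _GROUPS:
            raise ValueError(f"unknown parameter group {group!r} in {self.path!r}")
        return group


def _as_path(param) -> str:
    return param.path if isinstance(param, ParamRef) else str(param)


def get_param(scenario: Scenario, param) -> UncertainParam:
    """Resolve a path to its UncertainParam; raises on a bad address."""
    path = _as_path(param)
    parts = path.split(".")
    if len(parts) != 2 or parts[0] not in _GROUPS:
        raise ValueError(f"cannot resolve parameter path {path!r}")
    obj = getattr(scenario, parts[0])
    target = getattr(obj, parts[1], None)
    if not isinstance(target, UncertainParam):
        raise ValueError(f"{path!r} does not address an uncertain parameter")
    return target


def with_value(scenario: Scenario, param, value: float) -> Scenario:
    """A deep copy of ``scenario`` with one parameter's base value replaced."""
    path = _as_path(param)
    current = get_param(scenario, path)  # validates the address
    sc = scenario.model_copy(deep=True)
    group, name = path.split(".")
    obj = getattr(sc, group)
    setattr(obj, name, current.model_copy(update={"base_value": value}))
    return sc


def _valid_range(param: UncertainParam) -> tuple[float, float]:
    if param.unit == "probability_per_year":
        return (0.0, 1.0)
    if param.unit == "utility":
        return (-1.0, 1.0)
    return (0.0, np.inf)


def nmb_difference(scenario: Scenario, wtp: Optional[float] = None) -> float:
    """``NMB_bca - NMB_bcs`` at base values (scenario WTP unless given)."""
    w = scenario.econ.wtp if wtp is None else wtp
    bca = run_cohort(scenario, "bca")
    bcs = run_cohort(scenario, "bcs")
    return nmb(bca.total_cost, bca.total_qaly, w) - nmb(
        bcs.total_cost, bcs.total_qaly, w
    )


def _check_range(scenario: Scenario, path: str, lo: float, hi: float) -> None:
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    vlo, vhi = _valid_range(get_param(scenario, path))
    if lo < vlo or hi > vhi:
        raise ValueError(
            f"range [{lo}, {hi}] outside the valid range [{vlo}, {vhi}] of {path!r}"
        )


def one_way_sweep(
    scenario: Scenario,
    param,
    lo: float,
    hi: float,
    steps: int = 21,
    wtp: Optional[float] = None,
) -> pd.DataFrame:
    """Sweep one parameter over ``steps`` equally spaced values.

    Returns a frame with columns value, nmb_bca, nmb_bcs, nmb_diff,
    preferred.  A point at the base value reproduces the base-case NMBs
    exactly (nothing else is perturbed).
    """
    path = _as_path(param)
    _check_range(scenario, path, lo, hi)
    w = scenario.econ.wtp if wtp is None else wtp
    rows = []
    for x in np.linspace(lo, hi, steps):
        sc = with_value(scenario, path, float(x))
        cr = compare(run_cohort(sc, "bca"), run_cohort(sc, "bcs"), w)
        rows.append(
            {
                "value": float(x),
                "nmb_bca": cr.nmb_bca,
                "nmb_bcs": cr.nmb_bcs,
                "nmb_diff": cr.nmb_bca - cr.nmb_bcs,
                "preferred": cr.preferred,
            }
        )
    return pd.DataFrame(rows)


ThresholdStatus = Literal["found", "no_crossing", "multiple_crossings_first_reported"]


@dataclass
class ThresholdResult:
    param: ParamRef
    value: Optional[float]
    bracket: tuple[float, float]
    achieved_tolerance: Optional[float]  # |f| at the reported crossing
    status: ThresholdStatus
    f_lo: float
    f_hi: float


def find_threshold(
    scenario: Scenario,
    param,
    bracket: tuple[float, float],
    tol: Optional[float] = None,
    wtp: Optional[float] = None,
    scan: int = 65,
) -> ThresholdResult:
    """Bisection root of the NMB difference along one parameter.

    The bracket is first scanned on ``scan`` equally spaced points to locate
    sign changes; the crossing nearest the lower end is then bisected until
    the abscissa interval shrinks below ``tol`` (default ``1e-6`` of the
    bracket width).  More than one sign change is reported via the status
    field; no sign change anywhere returns ``no_crossing``.
    """
    path = _as_path(param)
    lo, hi = float(bracket[0]), float(bracket[1])
    _check_range(scenario, path, lo, hi)
    if tol is None:
        tol = 1e-6 * (hi - lo)

    def f(x: float) -> float:
        return nmb_difference(with_value(scenario, path, x), wtp)

    xs = np.linspace(lo, hi, scan)
    fs = np.array([f(float(x)) for x in xs])
    signs = np.sign(fs)
    crossings = [
        i
        for i in range(scan - 1)
        if signs[i] != signs[i + 1] and (signs[i] != 0 or i == 0)
    ]
    if not crossings:
        return ThresholdResult(
            param=ParamRef(path),
            value=None,
            bracket=(lo, hi),
            achieved_tolerance=None,
            status="no_crossing",
            f_lo=float(fs[0]),
            f_hi=float(fs[-1]),
        )

    a, b = float(xs[crossings[0]]), float(xs[crossings[0] + 1])
    fa = float(fs[crossings[0]])
    while b - a > tol:
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0.0:
            a = b = m
            break
        if (fa > 0) == (fm > 0):
            a, fa = m, fm
        else:
            b = m
    root = 0.5 * (a + b)
    status: ThresholdStatus = (
        "found" if len(crossings) == 1 else "multiple_crossings_first_reported"
    )
    return ThresholdResult(
        param=ParamRef(path),
        value=root,
        bracket=(lo, hi),
        achieved_tolerance=abs(f(root)),
        status=status,
        f_lo=float(fs[0]),
        f_hi=float(fs[-1]),
    )


def two_way_map(
    scenario: Scenario,
    param_a,
    param_b,
    grid_a: Sequence[float],
    grid_b: Sequence[float],
    wtp: Optional[float] = None,
) -> pd.DataFrame:
    """Preference map over a grid of two parameters (long format:
    value_a, value_b, preferred)."""
    path_a, path_b = _as_path(param_a), _as_path(param_b)
    w = scenario.econ.wtp if wtp is None else wtp
    for path, grid in ((path_a, grid_a), (path_b, grid_b)):
        vlo, vhi = _valid_range(get_param(scenario, path))
        for v in grid:
            if not vlo <= v <= vhi:
                raise ValueError(f"grid value {v} outside valid range of {path!r}")
    rows = []
    for a in grid_a:
        sc_a = with_value(scenario, path_a, float(a))
        for b in grid_b:
            sc = with_value(sc_a, path_b, float(b))
            cr = compare(run_cohort(sc, "bca"), run_cohort(sc, "bcs"), w)
            rows.append(
                {"value_a": float(a), "value_b": float(b), "preferred": cr.preferred}
            )
    return pd.DataFrame(rows)


def two_way_boundary(
    scenario: Scenario,
    param_a,
    param_b,
    a_values: Sequence[float],
    b_bracket: tuple[float, float],
    wtp: Optional[float] = None,
) -> pd.DataFrame:
    """Preference boundary of a two-way analysis.

    For each value of parameter A, finds the parameter-B threshold by
    bisection and reports it alongside the A - B difference — the natural
    summary when both axes carry the same quantity for the two arms (e.g.
    annual mortality after either treatment).
    """
    path_a, path_b = _as_path(param_a), _as_path(param_b)
    rows = []
    for a in a_values:
        sc_a = with_value(scenario, path_a, float(a))
        tr = find_threshold(sc_a, path_b, b_bracket, wtp=wtp)
        rows.append(
            {
                "value_a": float(a),
                "b_threshold": tr.value,
                "status": tr.status,
                "a_minus_b": (float(a) - tr.value) if tr.value is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def uncertain_param_paths(scenario: Scenario, include_point: bool = False) -> list[str]:
    """All parameter paths in a scenario, optionally including point masses."""
    paths = []
    for group in _GROUPS:
        obj = getattr(scenario, group)
        for name, value in obj:
            if isinstance(value, UncertainParam) and (
                include_point or not value.dist.is_point()
            ):
                paths.append(f"{group}.{name}")
    return paths


def tornado(
    scenario: Scenario,
    params: Optional[Sequence] = None,
    quantiles: tuple[float, float] = (0.025, 0.975),
    overrides: Optional[dict[str, tuple[float, float]]] = None,
    wtp: Optional[float] = None,
) -> pd.DataFrame:
    """Tornado bars: NMB-difference range as each parameter moves between its
    low/high values (distribution quantiles by default, or explicit
    ``overrides[path] = (lo, hi)``), sorted by descending width.

    Point-mass parameters without an override are skipped with a warning.
    """
    overrides = overrides or {}
    if params is None:
        paths = sorted(set(uncertain_param_paths(scenario)) | set(overrides))
    else:
        paths = [_as_path(p) for p in params]

    rows = []
    for path in paths:
        p = get_param(scenario, path)
        if path in overrides:
            lo, hi = overrides[path]
        elif p.dist.is_point():
            warnings.warn(
                f"skipping {path!r}: point distribution and no override",
                stacklevel=2,
            )
            continue
        else:
            lo, hi = p.dist.ppf(quantiles[0]), p.dist.ppf(quantiles[1])
        vlo, vhi = _valid_range(p)
        lo, hi = max(lo, vlo), min(hi, vhi)
        f_lo = nmb_difference(with_value(scenario, path, lo), wtp)
        f_hi = nmb_difference(with_value(scenario, path, hi), wtp)
        rows.append(
            {
                "param": path,
                "low_value": lo,
                "high_value": hi,
                "nmb_diff_low": f_lo,
                "nmb_diff_high": f_hi,
                "width": abs(f_hi - f_lo),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("width", ascending=False, ignore_index=True)
    return out
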