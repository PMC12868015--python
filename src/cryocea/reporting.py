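"""Result serialization: analysis reports, trace exports and run manifests.

Every report directory gets exactly one ``manifest.json`` recording the
scenario name, a content hash of its configuration, the analysis kind, the
seed (when randomness was involved), the package version, a UTC timestamp
and the list of files written.  Floats are serialized at full precision;
no locale-dependent formatting ever reaches a file.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from typing import Optional

import pandas as pd

from . import __version__
from .engine import StrategyResult, run_cohort
from .metrics import ComparisonResult, compare
from .params import Scenario
from .psa import PsaRun
from .dsa import ThresholdResult

__all__ = [
    "RunManifest",
    "scenario_hash",
    "write_manifest",
    "read_manifest",
    "comparison_report",
    "write_base_case_report",
    "read_base_case_report",
    "write_psa_report",
    "write_threshold_report",
]


def scenario_hash(scenario: Scenario) -> str:
    """SHA-256 of the canonical JSON dump — changes iff the config changes."""
    payload = json.dumps(scenario.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


@dataclass
class RunManifest:
    scenario_name: str
    scenario_hash: str
    analysis: str
    seed: Optional[int]
    version: str = __version__
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)


def write_manifest(out_dir, manifest: RunManifest) -> str:
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=1)
    return path


def read_manifest(out_dir) -> RunManifest:
    with open(os.path.join(out_dir, "manifest.json"), "r", encoding="utf-8") as fh:
        return RunManifest(**json.load(fh))


def _strategy_dict(res: StrategyResult) -> dict:
    return {
        "total_cost": res.total_cost,
        "total_qaly": res.total_qaly,
        "one_time_cost": res.one_time_cost,
    }


def comparison_report(
    scenario: Scenario,
    bca: StrategyResult,
    bcs: StrategyResult,
    comparisons: list[ComparisonResult],
) -> dict:
    """JSON-ready base-case report: both arms' totals plus one comparison
    block per willingness-to-pay."""
    return {
        "scenario": scenario.name,
        "scenario_hash": scenario_hash(scenario),
        "bca": _strategy_dict(bca),
        "bcs": _strategy_dict(bcs),
        "comparisons": [
            {
                "wtp": cr.wtp,
                "delta_cost": cr.delta_cost,
                "delta_qaly": cr.delta_qaly,
                "icer": cr.icer,
                "icer_flag": cr.icer_flag,
                "nmb_bca": cr.nmb_bca,
                "nmb_bcs": cr.nmb_bcs,
                "preferred": cr.preferred,
            }
            for cr in comparisons
        ],
    }


def write_base_case_report(
    scenario: Scenario, out_dir, wtps: Optional[list[float]] = None
) -> dict:
    """Run both arms at base values and write base_case.json, per-arm trace
    CSVs and the manifest.  Returns the report dict."""
    os.makedirs(out_dir, exist_ok=True)
    wtps = wtps or [scenario.econ.wtp]
    bca = run_cohort(scenario, "bca")
    bcs = run_cohort(scenario, "bcs")
    report = comparison_report(
        scenario, bca, bcs, [compare(bca, bcs, w) for w in wtps]
    )

    outputs = []
    path = os.path.join(out_dir, "base_case.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    outputs.append("base_case.json")
    for arm, res in (("bca", bca), ("bcs", bcs)):
        name = f"trace_{arm}.csv"
        res.trace.to_frame().to_csv(os.path.join(out_dir, name), index=False)
        outputs.append(name)

    manifest = RunManifest(
        scenario_name=scenario.name,
        scenario_hash=report["scenario_hash"],
        analysis="base",
        seed=None,
        outputs=outputs,
    )
    write_manifest(out_dir, manifest)
    return report


def read_base_case_report(out_dir) -> dict:
    with open(os.path.join(out_dir, "base_case.json"), "r", encoding="utf-8") as fh:
        return json.load(fh)


def write_psa_report(scenario: Scenario, run: PsaRun, out_dir) -> None:
    """Write per-iteration draws (cost-effectiveness plane data), the CEAC,
    a summary JSON and the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    run.draws.to_csv(os.path.join(out_dir, "iterations.csv"))
    run.ceac.to_csv(os.path.join(out_dir, "ceac.csv"), index=False)
    summary = {
        "n_iterations": run.n_iterations,
        "seed": run.seed,
        "wtp": run.wtp,
        "proportion_bca_preferred": run.proportion_bca_preferred,
        "moments": {
            col: {
                "mean": float(run.summary.loc[col, "mean"]),
                "sd": float(run.summary.loc[col, "sd"]),
            }
            for col in run.summary.index
        },
    }
    with open(os.path.join(out_dir, "psa_summary.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    manifest = RunManifest(
        scenario_name=scenario.name,
        scenario_hash=scenario_hash(scenario),
        analysis="psa",
        seed=run.seed,
        outputs=["iterations.csv", "ceac.csv", "psa_summary.json"],
    )
    write_manifest(out_dir, manifest)


def write_threshold_report(
    scenario: Scenario, result: ThresholdResult, out_dir
) -> None:
    os.makedirs(out_dir, exist_ok=True)
    payload = {
        "param": result.param.path,
        "value": result.value,
        "bracket": list(result.bracket),
        "achieved_tolerance": result.achieved_tolerance,
        "status": result.status,
        "f_lo": result.f_lo,
        "f_hi": result.f_hi,
    }
    with open(os.path.join(out_dir, "threshold.json"), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
    manifest = RunManifest(
        scenario_name=scenario.name,
        scenario_hash=scenario_hash(scenario),
        analysis="threshold",
        seed=None,
        outputs=["threshold.json"],
    )
    write_manifest(out_dir, manifest)


def sweep_to_csv(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, index=False)
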