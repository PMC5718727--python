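"""End-to-end runs: deterministic base case and scenario analysis.

``run_base_case`` evaluates every selected strategy under one parameter
bundle — detection, testing cost, lifetime QALYs and costs — and attaches
frontier membership and ICERs in both the detection-per-pound and the
cost-per-QALY planes. ``run_scenario`` re-runs the pipeline under
parameter overrides and reports what changed, including the
cost-effective strategy at each willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .bundle import ModelBundle, bundle_checksum
from .economics import CEPoint, FrontierResult, best_at_threshold, efficiency_frontier
from .psa import evaluate_strategies
from .strategies import EnumerationConfig, Strategy, enumerate_strategies, parse_strategy_label

#: Willingness-to-pay thresholds (GBP per QALY) used in the base case.
DEFAULT_THRESHOLDS = (13_000.0, 20_000.0, 30_000.0)


@dataclass
class BaseCaseResult:
    table: pd.DataFrame
    qaly_frontier: FrontierResult
    detection_frontier: FrontierResult
    best_by_threshold: Dict[float, str]
    checksum: str

    def frontier_table(self, plane: str = "qaly") -> pd.DataFrame:
        fr = self.qaly_frontier if plane == "qaly" else self.detection_frontier
        return fr.to_frame()


def _resolve_strategies(selection) -> List[Strategy]:
    if selection is None or selection == "all":
        return enumerate_strategies(EnumerationConfig(warn_on_count_mismatch=False))
    if isinstance(selection, (list, tuple)) and selection and isinstance(selection[0], Strategy):
        return list(selection)
    return [parse_strategy_label(label) for label in selection]


def run_base_case(
    bundle: ModelBundle,
    strategies=None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> BaseCaseResult:
    """Deterministic evaluation of the selected strategies under a bundle."""
    strats = _resolve_strategies(strategies)
    table = evaluate_strategies(bundle, strats)

    qaly_points = [
        CEPoint(r.label, float(r.qalys), float(r.total_cost)) for r in table.itertuples()
    ]
    det_points = [
        CEPoint(r.label, float(r.detection), float(r.testing_cost)) for r in table.itertuples()
    ]
    qaly_frontier = efficiency_frontier(qaly_points)
    det_frontier = efficiency_frontier(det_points)

    qaly_class = qaly_frontier.classification()
    det_class = det_frontier.classification()
    qaly_icers = {
        m.point.label: m.icer_vs_previous for m in qaly_frontier.members
    }
    det_icers = {m.point.label: m.icer_vs_previous for m in det_frontier.members}
    table = table.assign(
        qaly_frontier=[qaly_class[l] == "frontier" for l in table["label"]],
        qaly_icer=[qaly_icers.get(l, np.nan) for l in table["label"]],
        detection_frontier=[det_class[l] == "frontier" for l in table["label"]],
        detection_icer=[det_icers.get(l, np.nan) for l in table["label"]],
        total_cost_eur=table["total_cost"] * bundle.euro_per_gbp,
        testing_cost_eur=table["testing_cost"] * bundle.euro_per_gbp,
    )
    best = {
        float(lam): best_at_threshold(qaly_points, lam).label for lam in thresholds
    }
    return BaseCaseResult(
        table=table,
        qaly_frontier=qaly_frontier,
        detection_frontier=det_frontier,
        best_by_threshold=best,
        checksum=bundle_checksum(bundle),
    )


@dataclass
class ScenarioResult:
    base: BaseCaseResult
    scenario: BaseCaseResult
    overrides: Dict[str, float]
    comparison: pd.DataFrame
    frontier_changes: Dict[str, List[str]] = field(default_factory=dict)


def run_scenario(
    bundle: ModelBundle,
    overrides: Dict[str, float],
    strategies=None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> ScenarioResult:
    """Re-run the pipeline under overrides and compare with the base case."""
    base = run_base_case(bundle, strategies, thresholds)
    scenario = run_base_case(bundle.with_overrides(overrides), strategies, thresholds)
    merged = base.table.merge(
        scenario.table, on="label", suffixes=("_base", "_scenario")
    )
    for col in ("detection", "testing_cost", "qalys", "total_cost"):
        merged[f"{col}_delta"] = merged[f"{col}_scenario"] - merged[f"{col}_base"]
    changes = {
        "entered_qaly_frontier": sorted(
            set(scenario.qaly_frontier.labels) - set(base.qaly_frontier.labels)
        ),
        "left_qaly_frontier": sorted(
            set(base.qaly_frontier.labels) - set(scenario.qaly_frontier.labels)
        ),
    }
    return ScenarioResult(
        base=base,
        scenario=scenario,
        overrides=dict(overrides),
        comparison=merged,
        frontier_changes=changes,
    )
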