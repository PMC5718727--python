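"""Parameter bundle: everything one model run needs, with YAML round-trip.

A bundle collects the test-performance table, subgroup prevalence, unit
costs, management costs, utilities, long-term transitions, economic
settings, uncertainty hyper-parameters for probabilistic analysis, and
optional calibration targets. Bundles are plain-text (YAML) so runs are
reproducible and diffable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .calibration import CalibrationTarget, TargetQuantity
from .core import SUBGROUPS, Subgroup, SubgroupPrevalence, TestContext, TestKind
from .markov import (
    CancerTransitions,
    CostModel,
    EconomicSettings,
    GompertzMortality,
    Management,
    TableMortality,
    TransitionSet,
    UtilityModel,
)
from .perftable import TestPerformanceTable, load_packaged_tables


@dataclass(frozen=True)
class UncertaintySettings:
    """Hyper-parameters of the probabilistic distributions.

    Dirichlet effective sample sizes for classification rows and
    prevalence, a coefficient of variation for gamma-distributed costs,
    and beta effective sample sizes for utility decrements and transition
    probabilities. ``degenerate`` collapses every distribution to its
    point estimate.
    """

    ess_performance: float = 500.0
    ess_prevalence: float = 500.0
    cost_cv: float = 0.2
    ess_utility: float = 200.0
    ess_transitions: float = 500.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if min(self.ess_performance, self.ess_prevalence, self.ess_utility, self.ess_transitions) <= 0:
            raise ValueError("effective sample sizes must be > 0")
        if self.cost_cv < 0:
            raise ValueError("cost coefficient of variation must be >= 0")


@dataclass
class ModelBundle:
    perf: TestPerformanceTable
    prevalence: SubgroupPrevalence
    test_costs: Dict[TestKind, float]
    cost_model: CostModel
    utility_model: UtilityModel
    transitions: TransitionSet
    econ: EconomicSettings = field(default_factory=EconomicSettings)
    uncertainty: UncertaintySettings = field(default_factory=UncertaintySettings)
    calibration_targets: List[CalibrationTarget] = field(default_factory=list)
    euro_per_gbp: float = 1.18

    def with_overrides(self, overrides: Dict[str, float]) -> "ModelBundle":
        """Return a copy with dotted-path scalar overrides applied.

        Supported paths: ``test_costs.<mpmri|trusb|tpmb>``,
        ``cost_model.<field>``, ``utility_model.<field>``,
        ``econ.<field>``, ``prevalence.<subgroup>`` (renormalised), and
        ``transitions.<subgroup>.<management>.<field>``.
        """
        bundle = self
        for path, value in overrides.items():
            parts = path.split(".")
            if parts[0] == "test_costs" and len(parts) == 2:
                costs = dict(bundle.test_costs)
                costs[TestKind(parts[1])] = float(value)
                bundle = replace(bundle, test_costs=costs)
            elif parts[0] == "cost_model" and len(parts) == 2:
                bundle = replace(bundle, cost_model=replace(bundle.cost_model, **{parts[1]: float(value)}))
            elif parts[0] == "utility_model" and len(parts) == 2:
                bundle = replace(bundle, utility_model=replace(bundle.utility_model, **{parts[1]: float(value)}))
            elif parts[0] == "econ" and len(parts) == 2:
                bundle = replace(bundle, econ=replace(bundle.econ, **{parts[1]: float(value)}))
            elif parts[0] == "prevalence" and len(parts) == 2:
                probs = dict(bundle.prevalence.probabilities)
                probs[Subgroup(parts[1])] = float(value)
                total = sum(probs.values())
                probs = {s: p / total for s, p in probs.items()}
                bundle = replace(bundle, prevalence=SubgroupPrevalence(probs))
            elif parts[0] == "transitions" and len(parts) == 4:
                key = (Subgroup(parts[1]), Management(parts[2]))
                regimes = dict(bundle.transitions.regimes)
                regimes[key] = replace(regimes[key], **{parts[3]: float(value)})
                bundle = replace(
                    bundle, transitions=TransitionSet(regimes, bundle.transitions.mortality)
                )
            else:
                raise KeyError(f"unknown override path {path!r}")
        return bundle


def _mortality_to_dict(mortality) -> dict:
    if isinstance(mortality, GompertzMortality):
        return {"model": "gompertz", "a": mortality.a, "b": mortality.b}
    if isinstance(mortality, TableMortality):
        return {
            "model": "table",
            "ages": list(mortality.ages),
            "probabilities": list(mortality.probabilities),
        }
    raise TypeError(f"cannot serialise mortality {mortality!r}")


def _mortality_from_dict(d: dict):
    if d["model"] == "gompertz":
        return GompertzMortality(a=float(d["a"]), b=float(d["b"]))
    if d["model"] == "table":
        return TableMortality(tuple(float(a) for a in d["ages"]), tuple(float(p) for p in d["probabilities"]))
    raise ValueError(f"unknown mortality model {d['model']!r}")


def bundle_to_dict(bundle: ModelBundle) -> dict:
    def _plain(v):
        if isinstance(v, np.generic):
            v = v.item()
        if isinstance(v, float) and np.isnan(v):
            return None
        return v

    perf_rows = [
        {k: _plain(v) for k, v in rec.items()}
        for rec in bundle.perf.to_frame().to_dict(orient="records")
    ]
    return {
        "performance": perf_rows,
        "prevalence": {s.value: bundle.prevalence[s] for s in SUBGROUPS},
        "test_costs": {k.value: float(v) for k, v in bundle.test_costs.items()},
        "costs": {
            "radical_treatment": bundle.cost_model.radical_treatment,
            "surveillance_per_cycle": bundle.cost_model.surveillance_per_cycle,
            "metastatic_per_cycle": bundle.cost_model.metastatic_per_cycle,
        },
        "utilities": {
            "baseline_at_start": bundle.utility_model.baseline_at_start,
            "decline_per_year": bundle.utility_model.decline_per_year,
            "metastatic_decrement": bundle.utility_model.metastatic_decrement,
            "tpmb_decrement": bundle.utility_model.tpmb_decrement,
            "start_age": bundle.utility_model.start_age,
        },
        "transitions": [
            {
                "subgroup": sg.value,
                "management": mgmt.value,
                "p_localised_to_metastatic": tr.p_localised_to_metastatic,
                "p_localised_to_death": tr.p_localised_to_death,
                "p_metastatic_to_death": tr.p_metastatic_to_death,
            }
            for (sg, mgmt), tr in sorted(
                bundle.transitions.regimes.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
            )
        ],
        "mortality": _mortality_to_dict(bundle.transitions.mortality),
        "economics": {
            "discount_rate_costs": bundle.econ.discount_rate_costs,
            "discount_rate_effects": bundle.econ.discount_rate_effects,
            "cycle_length": bundle.econ.cycle_length,
            "start_age": bundle.econ.start_age,
            "max_age": bundle.econ.max_age,
            "half_cycle_correction": bundle.econ.half_cycle_correction,
            "price_year": bundle.econ.price_year,
            "currency": bundle.econ.currency,
        },
        "uncertainty": {
            "ess_performance": bundle.uncertainty.ess_performance,
            "ess_prevalence": bundle.uncertainty.ess_prevalence,
            "cost_cv": bundle.uncertainty.cost_cv,
            "ess_utility": bundle.uncertainty.ess_utility,
            "ess_transitions": bundle.uncertainty.ess_transitions,
            "degenerate": bundle.uncertainty.degenerate,
        },
        "calibration_targets": [
            {
                "subgroup": t.subgroup.value,
                "management": t.management.value,
                "time": t.time,
                "quantity": t.quantity.value,
                "value": t.value,
                "weight": t.weight,
            }
            for t in bundle.calibration_targets
        ],
        "euro_per_gbp": bundle.euro_per_gbp,
    }


def _opt_int(value) -> Optional[int]:
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    return int(value)


def _perf_from_records(records: List[dict]) -> TestPerformanceTable:
    entries = {}
    for rec in records:
        kind = TestKind(rec["test"])
        ctx = TestContext(
            kind,
            trusb_type=_opt_int(rec.get("trusb_type")),
            mpmri_definition=_opt_int(rec.get("mpmri_definition")),
            mpmri_cutoff=_opt_int(rec.get("mpmri_cutoff")),
            histology_definition=_opt_int(rec.get("histology_definition")),
        )
        entries[(ctx, Subgroup(rec["subgroup"]))] = np.array(
            [rec["p_nc"], rec["p_noncs"], rec["p_cs"]], dtype=float
        )
    return TestPerformanceTable(entries)


def bundle_from_dict(d: dict) -> ModelBundle:
    regimes = {
        (Subgroup(rec["subgroup"]), Management(rec["management"])): CancerTransitions(
            float(rec["p_localised_to_metastatic"]),
            float(rec["p_localised_to_death"]),
            float(rec["p_metastatic_to_death"]),
        )
        for rec in d["transitions"]
    }
    return ModelBundle(
        perf=_perf_from_records(d["performance"]),
        prevalence=SubgroupPrevalence({Subgroup(k): float(v) for k, v in d["prevalence"].items()}),
        test_costs={TestKind(k): float(v) for k, v in d["test_costs"].items()},
        cost_model=CostModel(**{k: float(v) for k, v in d["costs"].items()}),
        utility_model=UtilityModel(**{k: float(v) for k, v in d["utilities"].items()}),
        transitions=TransitionSet(regimes, _mortality_from_dict(d["mortality"])),
        econ=EconomicSettings(
            discount_rate_costs=float(d["economics"]["discount_rate_costs"]),
            discount_rate_effects=float(d["economics"]["discount_rate_effects"]),
            cycle_length=float(d["economics"]["cycle_length"]),
            start_age=float(d["economics"]["start_age"]),
            max_age=float(d["economics"]["max_age"]),
            half_cycle_correction=bool(d["economics"]["half_cycle_correction"]),
            price_year=int(d["economics"]["price_year"]),
            currency=str(d["economics"]["currency"]),
        ),
        uncertainty=UncertaintySettings(
            ess_performance=float(d["uncertainty"]["ess_performance"]),
            ess_prevalence=float(d["uncertainty"]["ess_prevalence"]),
            cost_cv=float(d["uncertainty"]["cost_cv"]),
            ess_utility=float(d["uncertainty"]["ess_utility"]),
            ess_transitions=float(d["uncertainty"]["ess_transitions"]),
            degenerate=bool(d["uncertainty"]["degenerate"]),
        ),
        calibration_targets=[
            CalibrationTarget(
                subgroup=Subgroup(rec["subgroup"]),
                management=Management(rec["management"]),
                time=float(rec["time"]),
                quantity=TargetQuantity(rec["quantity"]),
                value=float(rec["value"]),
                weight=float(rec["weight"]),
            )
            for rec in d.get("calibration_targets", [])
        ],
        euro_per_gbp=float(d.get("euro_per_gbp", 1.18)),
    )


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(bundle_to_dict(bundle), sort_keys=False))


def load_bundle(path: str | Path) -> ModelBundle:
    return bundle_from_dict(yaml.safe_load(Path(path).read_text()))


def bundle_checksum(bundle: ModelBundle) -> str:
    """Stable digest of the serialised bundle, for run logs."""
    text = yaml.safe_dump(bundle_to_dict(bundle), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
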