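"""Synthetic, internally consistent parameter sets.

The individual-level study behind the packaged classification tables is
not public, and neither are the unit costs, utilities and long-term
transition inputs of the original economic model. This module generates
complete stand-in parameter bundles with the right structure: Dirichlet
perturbations of the packaged classification rows (structural zeros
frozen, so perfect specificity survives), gamma-like cost draws around
realistic UK secondary-care magnitudes, beta-like utility decrements,
and long-term transitions that respect the treatment-benefit ordering
(radical treatment progresses no faster than surveillance). Every draw
is fully determined by the seed.

All default values here are synthetic study conditions, labelled as
such; none is presented as an estimate from the original study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bundle import ModelBundle, UncertaintySettings
from .calibration import CalibrationTarget, TargetQuantity, simulate_targets
from .core import SUBGROUPS, Subgroup, SubgroupPrevalence, TestKind
from .markov import (
    CancerTransitions,
    CostModel,
    GompertzMortality,
    Management,
    TransitionSet,
    UtilityModel,
)
from .perftable import TestPerformanceTable, load_packaged_tables

#: Synthetic prevalence of true status among men referred with a raised
#: suspicion of prostate cancer (roughly: 40% clinically significant).
DEFAULT_PREVALENCE = {
    Subgroup.NO_CANCER: 0.42,
    Subgroup.LOW_RISK: 0.18,
    Subgroup.INTERMEDIATE_RISK: 0.25,
    Subgroup.HIGH_RISK: 0.15,
}

#: Synthetic unit costs per test, including expected complication costs (GBP).
DEFAULT_TEST_COSTS = {TestKind.MPMRI: 350.0, TestKind.TRUSB: 450.0, TestKind.TPMB: 1100.0}

#: Synthetic annual ranges for surveillance-managed disease transitions,
#: per subgroup: (localised->metastatic, localised->death, metastatic->death).
DEFAULT_TRANSITION_RANGES: Dict[Subgroup, Dict[str, Tuple[float, float]]] = {
    Subgroup.LOW_RISK: {
        "p_localised_to_metastatic": (0.004, 0.012),
        "p_localised_to_death": (0.001, 0.004),
        "p_metastatic_to_death": (0.10, 0.20),
    },
    Subgroup.INTERMEDIATE_RISK: {
        "p_localised_to_metastatic": (0.03, 0.06),
        "p_localised_to_death": (0.005, 0.015),
        "p_metastatic_to_death": (0.12, 0.22),
    },
    Subgroup.HIGH_RISK: {
        "p_localised_to_metastatic": (0.08, 0.15),
        "p_localised_to_death": (0.01, 0.03),
        "p_metastatic_to_death": (0.15, 0.30),
    },
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration for one synthetic parameter bundle (seed mandatory)."""

    seed: int
    prevalence: Dict[Subgroup, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    #: Dirichlet effective sample size for perturbing the packaged
    #: classification rows; None keeps the packaged tables exactly.
    perf_ess: Optional[float] = 500.0
    test_cost_means: Dict[TestKind, float] = field(default_factory=lambda: dict(DEFAULT_TEST_COSTS))
    radical_treatment_cost: float = 7000.0
    surveillance_cost_per_cycle: float = 250.0
    metastatic_cost_per_cycle: float = 2200.0
    cost_jitter: float = 0.15  # relative half-width of uniform cost draws
    metastatic_decrement_range: Tuple[float, float] = (0.20, 0.30)
    tpmb_decrement_range: Tuple[float, float] = (0.003, 0.008)
    transition_ranges: Dict[Subgroup, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRANSITION_RANGES.items()}
    )
    #: radical-treatment progression as a fraction of surveillance progression
    treatment_benefit_range: Tuple[float, float] = (0.3, 0.7)
    calibration_times: Sequence[float] = (5.0, 10.0, 15.0)
    uncertainty: UncertaintySettings = field(default_factory=UncertaintySettings)

    def __post_init__(self) -> None:
        if self.perf_ess is not None and self.perf_ess <= 0:
            raise ValueError("perf_ess must be > 0 or None")
        if not 0.0 <= self.cost_jitter < 1.0:
            raise ValueError("cost_jitter must be in [0,1)")
        for rng_ in (self.metastatic_decrement_range, self.tpmb_decrement_range, self.treatment_benefit_range):
            lo, hi = rng_
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError(f"range {rng_} outside [0,1]")
        for sg, ranges in self.transition_ranges.items():
            for name, (lo, hi) in ranges.items():
                if not 0.0 <= lo <= hi <= 1.0:
                    raise ValueError(f"transition range {sg.value}.{name} outside [0,1]")


def perturb_performance(
    perf: TestPerformanceTable, ess: float, rng: np.random.Generator
) -> TestPerformanceTable:
    """Dirichlet perturbation of each non-structural row, zeros frozen."""
    from .psa import _draw_dirichlet_row

    entries = {}
    for (ctx, subgroup), row in perf.entries.items():
        if ctx.test is TestKind.TPMB or (ctx.test.is_biopsy and subgroup is Subgroup.NO_CANCER):
            entries[(ctx, subgroup)] = row.copy()
        else:
            entries[(ctx, subgroup)] = _draw_dirichlet_row(row, ess, rng)
    return TestPerformanceTable(entries)


def generate_parameter_set(cfg: SyntheticConfig) -> ModelBundle:
    """Generate a complete, seeded, internally consistent model bundle."""
    rng = np.random.default_rng(cfg.seed)
    packaged = load_packaged_tables()
    if cfg.perf_ess is None:
        perf = packaged
    else:
        perf = perturb_performance(packaged, cfg.perf_ess, rng)

    def jitter(mean: float) -> float:
        return float(mean * (1.0 + cfg.cost_jitter * (2.0 * rng.random() - 1.0)))

    test_costs = {k: jitter(v) for k, v in cfg.test_cost_means.items()}
    cost_model = CostModel(
        radical_treatment=jitter(cfg.radical_treatment_cost),
        surveillance_per_cycle=jitter(cfg.surveillance_cost_per_cycle),
        metastatic_per_cycle=jitter(cfg.metastatic_cost_per_cycle),
    )

    def uniform(bounds: Tuple[float, float]) -> float:
        return float(bounds[0] + rng.random() * (bounds[1] - bounds[0]))

    utility_model = UtilityModel(
        metastatic_decrement=uniform(cfg.metastatic_decrement_range),
        tpmb_decrement=uniform(cfg.tpmb_decrement_range),
    )

    regimes: Dict[Tuple[Subgroup, Management], CancerTransitions] = {}
    for subgroup, ranges in cfg.transition_ranges.items():
        surveillance = CancerTransitions(
            uniform(ranges["p_localised_to_metastatic"]),
            uniform(ranges["p_localised_to_death"]),
            uniform(ranges["p_metastatic_to_death"]),
        )
        benefit = uniform(cfg.treatment_benefit_range)
        radical = CancerTransitions(
            surveillance.p_localised_to_metastatic * benefit,
            surveillance.p_localised_to_death * benefit,
            surveillance.p_metastatic_to_death,
        )
        regimes[(subgroup, Management.SURVEILLANCE)] = surveillance
        regimes[(subgroup, Management.RADICAL_TREATMENT)] = radical
    transitions = TransitionSet(regimes, GompertzMortality())

    bundle = ModelBundle(
        perf=perf,
        prevalence=SubgroupPrevalence(dict(cfg.prevalence)),
        test_costs=test_costs,
        cost_model=cost_model,
        utility_model=utility_model,
        transitions=transitions,
        uncertainty=cfg.uncertainty,
    )
    schedule = [(t, q) for t in cfg.calibration_times for q in TargetQuantity]
    targets: List[CalibrationTarget] = []
    for (subgroup, mgmt), tr in sorted(regimes.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)):
        implied = simulate_targets(tr, schedule, mortality=transitions.mortality)
        for (t, q), v in zip(schedule, implied):
            targets.append(CalibrationTarget(subgroup, mgmt, t, q, v))
    bundle.calibration_targets = targets
    return bundle


def generate_calibration_targets(
    transitions: CancerTransitions,
    schedule: Sequence[Tuple[float, TargetQuantity]],
    noise_sd: float = 0.0,
    seed: int = 0,
    subgroup: Subgroup = Subgroup.INTERMEDIATE_RISK,
    management: Management = Management.SURVEILLANCE,
    mortality=None,
) -> List[CalibrationTarget]:
    """Model-implied targets with optional truncated Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    implied = simulate_targets(transitions, schedule, mortality=mortality)
    targets = []
    for (t, q), v in zip(schedule, implied):
        if noise_sd > 0:
            v = float(np.clip(v + rng.normal(0.0, noise_sd), 0.0, 1.0))
        targets.append(CalibrationTarget(subgroup, management, t, q, v))
    return targets
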