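"""Cohort Markov model for long-term outcomes after diagnosis.

Men with cancer occupy three health states (localised, metastatic, dead);
cancer-free men effectively occupy two (alive, dead), modelled here as
the localised state with zero disease transitions. Death is absorbing.
Per-cycle disease transitions depend on the true subgroup and on the
management implied by the diagnosis (radical treatment after a CS
diagnosis, surveillance for other men with cancer, none for cancer-free
men); an age-indexed background mortality applies to everyone.

QALYs and costs accrue at the start of each cycle (no half-cycle
correction by default) and are discounted to present value at the
configured annual rates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .core import Diagnosis, Subgroup, SubgroupPrevalence, TestKind
from .engine import DiagnosisDistribution


class Management(enum.Enum):
    RADICAL_TREATMENT = "radical_treatment"
    SURVEILLANCE = "surveillance"
    NONE = "none"


def management_for(subgroup: Subgroup, diagnosis: Diagnosis) -> Management:
    """CS diagnosis -> radical treatment; other cancer (diagnosed non-CS or
    missed) -> surveillance; cancer-free men -> none."""
    if not subgroup.has_cancer:
        return Management.NONE
    if diagnosis is Diagnosis.CS_DX:
        return Management.RADICAL_TREATMENT
    return Management.SURVEILLANCE


class HealthState(enum.IntEnum):
    LOCALISED = 0  # "alive" for cancer-free men
    METASTATIC = 1
    DEAD = 2


@dataclass(frozen=True)
class CancerTransitions:
    """Per-cycle disease transition probabilities (before background mortality)."""

    p_localised_to_metastatic: float
    p_localised_to_death: float
    p_metastatic_to_death: float

    def __post_init__(self) -> None:
        for name, p in (
            ("p_localised_to_metastatic", self.p_localised_to_metastatic),
            ("p_localised_to_death", self.p_localised_to_death),
            ("p_metastatic_to_death", self.p_metastatic_to_death),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {p}")
        if self.p_localised_to_metastatic + self.p_localised_to_death > 1.0 + 1e-12:
            raise ValueError("localised exits exceed probability 1")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (
            self.p_localised_to_metastatic,
            self.p_localised_to_death,
            self.p_metastatic_to_death,
        )


NO_DISEASE = CancerTransitions(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GompertzMortality:
    """Age-indexed annual background death probability a*exp(b*age), capped at 1."""

    a: float = 4.3e-5
    b: float = 0.087

    def annual_probability(self, age: float) -> float:
        return min(1.0, self.a * math.exp(self.b * age))


@dataclass(frozen=True)
class TableMortality:
    """Background mortality from an explicit (age, annual probability) table."""

    ages: Tuple[float, ...]
    probabilities: Tuple[float, ...]

    def annual_probability(self, age: float) -> float:
        return float(np.interp(age, self.ages, self.probabilities))


ZERO_MORTALITY = TableMortality((0.0, 200.0), (0.0, 0.0))


@dataclass(frozen=True)
class TransitionSet:
    """Per-(subgroup, management) disease transitions plus background mortality."""

    regimes: Dict[Tuple[Subgroup, Management], CancerTransitions]
    mortality: object = field(default_factory=GompertzMortality)

    def regime(self, subgroup: Subgroup, management: Management) -> CancerTransitions:
        if not subgroup.has_cancer:
            return NO_DISEASE
        try:
            return self.regimes[(subgroup, management)]
        except KeyError:
            raise KeyError(
                f"no transition regime for ({subgroup.value}, {management.value})"
            ) from None


@dataclass(frozen=True)
class EconomicSettings:
    discount_rate_costs: float = 0.035
    discount_rate_effects: float = 0.035
    cycle_length: float = 1.0  # years
    start_age: float = 65.0
    max_age: float = 100.0
    half_cycle_correction: bool = False
    price_year: int = 2015
    currency: str = "GBP"

    def __post_init__(self) -> None:
        if self.discount_rate_costs < 0 or self.discount_rate_effects < 0:
            raise ValueError("discount rates must be >= 0")
        if self.cycle_length <= 0:
            raise ValueError("cycle length must be > 0")


@dataclass(frozen=True)
class UtilityModel:
    """HRQoL weights: an age-declining baseline, a metastatic-state decrement,
    and a one-off decrement per TPMB. TRUSB carries no HRQoL impact."""

    baseline_at_start: float = 0.82
    decline_per_year: float = 0.004
    metastatic_decrement: float = 0.25
    tpmb_decrement: float = 0.005
    start_age: float = 65.0

    def baseline(self, age: float) -> float:
        u = self.baseline_at_start - self.decline_per_year * (age - self.start_age)
        return min(1.0, max(0.0, u))

    def metastatic(self, age: float) -> float:
        return max(0.0, self.baseline(age) - self.metastatic_decrement)


@dataclass(frozen=True)
class CostModel:
    """Management costs: one-off radical treatment (incl. complications),
    per-cycle surveillance, per-cycle metastatic disease."""

    radical_treatment: float = 7000.0
    surveillance_per_cycle: float = 300.0
    metastatic_per_cycle: float = 2000.0

    def __post_init__(self) -> None:
        if min(self.radical_treatment, self.surveillance_per_cycle, self.metastatic_per_cycle) < 0:
            raise ValueError("costs must be >= 0")


def discount_factor(t: float, rate: float) -> float:
    """Present-value factor (1 + rate)^(-t) for an amount accruing at year t."""
    if t < 0 or rate < 0:
        raise ValueError("t and rate must be >= 0")
    return (1.0 + rate) ** (-t)


@dataclass
class CohortResult:
    qalys: float
    costs: float
    trace: pd.DataFrame  # per-cycle occupancy, rows sum to 1
    life_years: float


def run_cohort(
    transitions: CancerTransitions,
    utilities: UtilityModel,
    costs: CostModel,
    econ: EconomicSettings,
    mortality=None,
    management: Management = Management.NONE,
    initial: Iterable[float] = (1.0, 0.0, 0.0),
) -> CohortResult:
    """Propagate a cohort through the three-state model cycle by cycle.

    Background mortality combines multiplicatively with disease-specific
    death within a cycle; survivors of the localised state then progress
    to metastatic disease with the configured probability. Accrual uses
    start-of-cycle occupancy unless half-cycle correction is enabled, in
    which case each cycle accrues the average of its start and end
    occupancies.
    """
    if mortality is None:
        mortality = ZERO_MORTALITY
    occ = np.asarray(list(initial), dtype=float)
    if occ.shape != (3,) or abs(occ.sum() - 1.0) > 1e-9 or (occ < 0).any():
        raise ValueError("initial occupancy must be a length-3 probability vector")
    p_lm, p_ld, p_md = transitions.as_tuple()
    cycle = econ.cycle_length
    n_cycles = int(math.ceil((econ.max_age - econ.start_age) / cycle))
    qalys = 0.0
    total_cost = 0.0
    life_years = 0.0
    rows = []

    under_surveillance = management is Management.SURVEILLANCE

    def accrue(occ_vec: np.ndarray, age: float, t: float, weight: float) -> None:
        nonlocal qalys, total_cost, life_years
        alive = occ_vec[HealthState.LOCALISED] + occ_vec[HealthState.METASTATIC]
        util = (
            occ_vec[HealthState.LOCALISED] * utilities.baseline(age)
            + occ_vec[HealthState.METASTATIC] * utilities.metastatic(age)
        )
        per_cycle_cost = occ_vec[HealthState.METASTATIC] * costs.metastatic_per_cycle
        if under_surveillance:
            per_cycle_cost += alive * costs.surveillance_per_cycle
        qalys += weight * cycle * util * discount_factor(t, econ.discount_rate_effects)
        total_cost += weight * per_cycle_cost * discount_factor(t, econ.discount_rate_costs)
        life_years += weight * cycle * alive

    for k in range(n_cycles):
        t = k * cycle
        age = econ.start_age + t
        rows.append({"cycle": k, "age": age, **{s.name.lower(): occ[s] for s in HealthState}})
        q = mortality.annual_probability(age)
        q_cycle = 1.0 - (1.0 - q) ** cycle
        d_loc = 1.0 - (1.0 - p_ld) * (1.0 - q_cycle)
        d_met = 1.0 - (1.0 - p_md) * (1.0 - q_cycle)
        nxt = np.empty(3)
        stay_loc = (1.0 - d_loc) * (1.0 - p_lm)
        to_met = (1.0 - d_loc) * p_lm
        nxt[HealthState.LOCALISED] = occ[HealthState.LOCALISED] * stay_loc
        nxt[HealthState.METASTATIC] = (
            occ[HealthState.LOCALISED] * to_met + occ[HealthState.METASTATIC] * (1.0 - d_met)
        )
        nxt[HealthState.DEAD] = (
            occ[HealthState.DEAD]
            + occ[HealthState.LOCALISED] * d_loc
            + occ[HealthState.METASTATIC] * d_met
        )
        if econ.half_cycle_correction:
            accrue(occ, age, t, 0.5)
            accrue(nxt, age + cycle, t + cycle, 0.5)
        else:
            accrue(occ, age, t, 1.0)
        occ = nxt
        if occ[HealthState.DEAD] > 1.0 - 1e-12:
            break
    trace = pd.DataFrame(rows)
    return CohortResult(qalys=qalys, costs=total_cost, trace=trace, life_years=life_years)


@dataclass
class LifetimeResult:
    """Discounted lifetime QALYs and costs per (subgroup, diagnosis) cell."""

    strategy_label: str
    per_cell: pd.DataFrame  # subgroup, diagnosis, probability, qalys, costs
    total_qalys: float
    total_costs: float
    testing_cost: float


def lifetime_outcomes(
    d: DiagnosisDistribution,
    transitions: TransitionSet,
    utilities: UtilityModel,
    costs: CostModel,
    econ: EconomicSettings,
    test_unit_costs: Optional[Dict[TestKind, float]] = None,
) -> LifetimeResult:
    """Attach lifetime QALYs/costs to a diagnosis distribution.

    Each (subgroup, diagnosis) cell maps to a management, whose cohort
    model yields discounted QALYs and long-term costs; radical treatment
    adds its one-off cost at diagnosis. The one-off TPMB HRQoL decrement
    is applied per expected TPMB administered, and testing costs are
    added when unit costs are supplied. The strategy total weights cells
    by prevalence and diagnosis probability.
    """
    cohort_cache: Dict[Tuple[Subgroup, Management], CohortResult] = {}

    def cohort(subgroup: Subgroup, mgmt: Management) -> CohortResult:
        key = (subgroup, mgmt)
        if key not in cohort_cache:
            cohort_cache[key] = run_cohort(
                transitions.regime(subgroup, mgmt),
                utilities,
                costs,
                econ,
                mortality=transitions.mortality,
                management=mgmt,
            )
        return cohort_cache[key]

    rows = []
    total_qalys = 0.0
    total_costs = 0.0
    prevalence = d.prevalence
    for subgroup, dist in d.cells.items():
        prev = prevalence[subgroup]
        for diagnosis in Diagnosis:
            p_dx = d.diagnosis_probability(subgroup, diagnosis)
            if p_dx == 0.0:
                continue
            mgmt = management_for(subgroup, diagnosis)
            res = cohort(subgroup, mgmt)
            cell_cost = res.costs
            if diagnosis is Diagnosis.CS_DX:
                cell_cost += costs.radical_treatment  # one-off at diagnosis (t=0)
            rows.append(
                {
                    "subgroup": subgroup.value,
                    "diagnosis": diagnosis.value,
                    "management": mgmt.value,
                    "probability": p_dx,
                    "qalys": res.qalys,
                    "costs": cell_cost,
                }
            )
            total_qalys += prev * p_dx * res.qalys
            total_costs += prev * p_dx * cell_cost
        # one-off TPMB HRQoL decrement, per expected TPMB in this subgroup
        tpmb_loss = utilities.tpmb_decrement * d.expected_counts(subgroup)[TestKind.TPMB]
        total_qalys -= prev * tpmb_loss
    testing = 0.0
    if test_unit_costs is not None:
        testing = d.expected_testing_cost(test_unit_costs)
        total_costs += testing
    return LifetimeResult(
        strategy_label=d.strategy_label,
        per_cell=pd.DataFrame(rows),
        total_qalys=total_qalys,
        total_costs=total_costs,
        testing_cost=testing,
    )
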