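"""Cohort Markov model: closed forms, conservation, lifetime aggregation."""

import dataclasses

import numpy as np
import pytest

from dxcea.core import Subgroup, SubgroupPrevalence, TestKind
from dxcea.engine import execute_strategy
from dxcea.markov import (
    CancerTransitions,
    CohortResult,
    CostModel,
    EconomicSettings,
    Management,
    TableMortality,
    TransitionSet,
    UtilityModel,
    ZERO_MORTALITY,
    discount_factor,
    lifetime_outcomes,
    management_for,
    run_cohort,
)
from dxcea.core import Diagnosis
from dxcea.strategies import parse_strategy_label

FLAT_UTILITY = UtilityModel(baseline_at_start=1.0, decline_per_year=0.0, tpmb_decrement=0.0)
NO_COSTS = CostModel(0.0, 0.0, 0.0)
LONG_ECON = EconomicSettings(
    discount_rate_costs=0.0, discount_rate_effects=0.0, start_age=0.0, max_age=300.0
)
CONST_Q10 = TableMortality((0.0, 300.0), (0.1, 0.1))


class TestDiscounting:
    def test_zero_rate_is_unity(self):
        assert discount_factor(7.3, 0.0) == 1.0

    def test_standard_rate_ten_years(self):
        assert discount_factor(10, 0.035) == pytest.approx(1.035**-10, abs=1e-12)
        assert discount_factor(10, 0.035) == pytest.approx(0.70892, abs=5e-6)

    def test_time_zero(self):
        assert discount_factor(0, 0.035) == 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.035)
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestCohortClosedForms:
    def test_geometric_life_expectancy(self):
        """Constant death probability p gives expected life years 1/p."""
        res = run_cohort(CancerTransitions(0, 0, 0), FLAT_UTILITY, NO_COSTS, LONG_ECON, CONST_Q10)
        assert res.qalys == pytest.approx(10.0, abs=1e-9)

    def test_discounted_geometric_life_expectancy(self):
        econ = dataclasses.replace(LONG_ECON, discount_rate_effects=0.035)
        res = run_cohort(CancerTransitions(0, 0, 0), FLAT_UTILITY, NO_COSTS, econ, CONST_Q10)
        assert res.qalys == pytest.approx(1.0 / (1.0 - 0.9 / 1.035), abs=1e-9)

    def test_initial_dead_accrues_nothing(self):
        res = run_cohort(
            CancerTransitions(0.1, 0.1, 0.3),
            FLAT_UTILITY,
            CostModel(),
            LONG_ECON,
            CONST_Q10,
            management=Management.SURVEILLANCE,
            initial=(0.0, 0.0, 1.0),
        )
        assert res.qalys == 0.0 and res.costs == 0.0

    def test_occupancy_conserved_and_death_absorbing(self):
        res = run_cohort(
            CancerTransitions(0.08, 0.02, 0.25),
            FLAT_UTILITY,
            CostModel(),
            EconomicSettings(start_age=65, max_age=100),
            management=Management.SURVEILLANCE,
        )
        occ = res.trace[["localised", "metastatic", "dead"]].to_numpy()
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        assert (np.diff(occ[:, 2]) >= -1e-12).all()

    def test_discounting_monotonicity(self):
        transitions = CancerTransitions(0.05, 0.01, 0.2)
        qalys = []
        for rate in (0.0, 0.015, 0.035, 0.06):
            econ = dataclasses.replace(LONG_ECON, discount_rate_effects=rate)
            qalys.append(
                run_cohort(transitions, FLAT_UTILITY, NO_COSTS, econ, CONST_Q10).qalys
            )
        assert all(a > b for a, b in zip(qalys, qalys[1:]))

    def test_half_cycle_correction_brackets_start_of_cycle(self):
        """Half-cycle accrual lies between start- and end-of-cycle accrual."""
        transitions = CancerTransitions(0, 0, 0)
        start = run_cohort(transitions, FLAT_UTILITY, NO_COSTS, LONG_ECON, CONST_Q10)
        half = run_cohort(
            transitions,
            FLAT_UTILITY,
            NO_COSTS,
            dataclasses.replace(LONG_ECON, half_cycle_correction=True),
            CONST_Q10,
        )
        assert half.qalys < start.qalys
        assert half.qalys == pytest.approx(10.0 - 0.5, abs=1e-6)  # trapezoid shifts by half a cycle

    def test_invalid_transition_row_rejected(self):
        with pytest.raises(ValueError):
            CancerTransitions(0.8, 0.5, 0.1)
        with pytest.raises(ValueError):
            CancerTransitions(-0.1, 0.0, 0.0)


class TestManagementRule:
    def test_mapping(self):
        assert management_for(Subgroup.HIGH_RISK, Diagnosis.CS_DX) is Management.RADICAL_TREATMENT
        assert management_for(Subgroup.INTERMEDIATE_RISK, Diagnosis.NO_CANCER_DX) is Management.SURVEILLANCE
        assert management_for(Subgroup.LOW_RISK, Diagnosis.NON_CS_DX) is Management.SURVEILLANCE
        assert management_for(Subgroup.NO_CANCER, Diagnosis.NO_CANCER_DX) is Management.NONE


class TestLifetimeOutcomes:
    def test_zero_utilities_zero_qalys(self, packaged, prevalence, bundle):
        utilities = UtilityModel(
            baseline_at_start=0.0, decline_per_year=0.0, metastatic_decrement=0.0, tpmb_decrement=0.0
        )
        d = execute_strategy(parse_strategy_label("P4 2"), packaged, prevalence)
        res = lifetime_outcomes(
            d, bundle.transitions, utilities, bundle.cost_model, bundle.econ
        )
        assert res.total_qalys == pytest.approx(0.0, abs=1e-12)

    def test_cancer_free_cohort_independent_of_routing(self, packaged, bundle):
        """With only cancer-free men, lifetime QALYs equal the two-state
        closed form less TPMB decrements, whatever the biopsy routing."""
        prev = SubgroupPrevalence(
            {
                Subgroup.NO_CANCER: 1.0,
                Subgroup.LOW_RISK: 0.0,
                Subgroup.INTERMEDIATE_RISK: 0.0,
                Subgroup.HIGH_RISK: 0.0,
            }
        )
        results = {}
        for label in ("M7 222", "T4 2", "P1 1"):
            d = execute_strategy(parse_strategy_label(label), packaged, prev)
            res = lifetime_outcomes(
                d, bundle.transitions, bundle.utility_model, bundle.cost_model, bundle.econ
            )
            results[label] = res.total_qalys
        assert results["M7 222"] == pytest.approx(results["T4 2"], abs=1e-9)
        assert results["P1 1"] == pytest.approx(
            results["M7 222"] - bundle.utility_model.tpmb_decrement, abs=1e-9
        )

    def test_missing_regime_raises(self, packaged, prevalence, bundle):
        broken = TransitionSet(
            {
                k: v
                for k, v in bundle.transitions.regimes.items()
                if k != (Subgroup.HIGH_RISK, Management.SURVEILLANCE)
            },
            bundle.transitions.mortality,
        )
        d = execute_strategy(parse_strategy_label("M1 115"), packaged, prevalence)
        with pytest.raises(KeyError, match="high_risk"):
            lifetime_outcomes(d, broken, bundle.utility_model, bundle.cost_model, bundle.econ)

    def test_higher_sensitivity_never_lowers_qalys(self, packaged, prevalence, bundle):
        """With radical treatment slowing progression and no TPMB decrement,
        replacing the final TRUSB by the perfect biopsy (M->N, T->P pairs)
        raises sensitivity and never lowers total QALYs."""
        utilities = dataclasses.replace(bundle.utility_model, tpmb_decrement=0.0)
        pairs = [("M1 122", "N1 122"), ("M7 222", "N7 222"), ("T4 2", "P4 2"), ("T7 223", "P7 223")]
        for weaker_label, stronger_label in pairs:
            outs = {}
            for label in (weaker_label, stronger_label):
                d = execute_strategy(parse_strategy_label(label), packaged, prevalence)
                outs[label] = (
                    d.sensitivity(),
                    lifetime_outcomes(
                        d, bundle.transitions, utilities, bundle.cost_model, bundle.econ
                    ).total_qalys,
                )
            assert outs[stronger_label][0] >= outs[weaker_label][0] - 1e-12
            assert outs[stronger_label][1] >= outs[weaker_label][1] - 1e-9
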