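"""Exact tree propagation and its microsimulation cross-check."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from dxcea.core import (
    Diagnosis,
    Subgroup,
    SubgroupPrevalence,
    TestClass,
    TestContext,
    TestKind,
)
from dxcea.engine import execute_strategy, microsim_oracle
from dxcea.perftable import TestPerformanceTable, tpmb_rows
from dxcea.strategies import (
    AnyBiopsyResultIs,
    Not,
    Stage,
    parse_strategy_label,
    undetected_terminate_in_tpmb,
)


def sensitivity_se(exact, prevalence, n_by_subgroup):
    """Standard error of the prevalence-weighted empirical sensitivity."""
    cs_prev = prevalence.cs_prevalence
    var = 0.0
    for s in (Subgroup.INTERMEDIATE_RISK, Subgroup.HIGH_RISK):
        p = exact.diagnosis_probability(s, Diagnosis.CS_DX)
        w = prevalence[s] / cs_prev
        var += w**2 * p * (1 - p) / n_by_subgroup[s]
    return math.sqrt(var)


class TestExactPropagation:
    def test_m7_222_referral_rates(self, packaged, prevalence):
        """MPMRI definition 2 at cut-off >=2 refers 98% of intermediate-risk,
        92% of low-risk and 93% of cancer-free men to targeted biopsy."""
        d = execute_strategy(parse_strategy_label("M7 222"), packaged, prevalence)
        rates = d.referral_rates()
        assert rates[Subgroup.INTERMEDIATE_RISK] == pytest.approx(0.98, abs=1e-12)
        assert rates[Subgroup.LOW_RISK] == pytest.approx(0.92, abs=1e-12)
        assert rates[Subgroup.NO_CANCER] == pytest.approx(0.93, abs=1e-12)
        assert rates[Subgroup.HIGH_RISK] == pytest.approx(1.0, abs=1e-12)

    def test_m7_222_intermediate_detection_hand_value(self, packaged, prevalence):
        """Hand propagation: referral x (first-biopsy CS + re-biopsy CS)."""
        d = execute_strategy(parse_strategy_label("M7 222"), packaged, prevalence)
        expected = 0.98 * (0.74 + 0.26 * 0.87)
        assert d.diagnosis_probability(
            Subgroup.INTERMEDIATE_RISK, Diagnosis.CS_DX
        ) == pytest.approx(expected, abs=1e-12)

    def test_tpmb_alone_is_identity(self, packaged, prevalence):
        d = execute_strategy(parse_strategy_label("P1 1"), packaged, prevalence)
        assert d.sensitivity() == 1.0
        assert d.specificity() == 1.0
        assert d.diagnosis_probability(Subgroup.LOW_RISK, Diagnosis.NON_CS_DX) == 1.0
        assert d.diagnosis_probability(Subgroup.NO_CANCER, Diagnosis.NO_CANCER_DX) == 1.0

    def test_high_risk_only_sensitivity_is_one(self, packaged):
        """Cut-off >=2 refers every high-risk man and the targeted biopsy
        detects high-risk CS cancer with certainty."""
        prev = SubgroupPrevalence(
            {
                Subgroup.NO_CANCER: 0.0,
                Subgroup.LOW_RISK: 0.0,
                Subgroup.INTERMEDIATE_RISK: 0.0,
                Subgroup.HIGH_RISK: 1.0,
            }
        )
        d = execute_strategy(parse_strategy_label("M7 222"), packaged, prev)
        assert d.sensitivity() == 1.0

    def test_conditional_distributions_normalise(self, packaged, prevalence, all_strategies):
        for s in all_strategies[::37]:
            d = execute_strategy(s, packaged, prevalence)
            for subgroup, cells in d.cells.items():
                assert sum(cells.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_sensitivity_with_degenerate_table(self, packaged, prevalence):
        """A table whose biopsies never return CS yields zero sensitivity."""
        blind = {
            key: np.array([1.0, 0.0, 0.0])
            for key in packaged.entries
            if key[0].test is TestKind.TRUSB
        }
        table = packaged.copy_with(blind)
        d = execute_strategy(parse_strategy_label("T4 1"), table, prevalence)
        assert d.sensitivity() == 0.0

    def test_sensitivity_requires_cs_prevalence(self, packaged):
        prev = SubgroupPrevalence(
            {
                Subgroup.NO_CANCER: 0.6,
                Subgroup.LOW_RISK: 0.4,
                Subgroup.INTERMEDIATE_RISK: 0.0,
                Subgroup.HIGH_RISK: 0.0,
            }
        )
        d = execute_strategy(parse_strategy_label("T1 1"), packaged, prev)
        with pytest.raises(ValueError, match="zero CS prevalence"):
            d.sensitivity()

    def test_unconditional_first_biopsy_refers_everyone(self, packaged, prevalence):
        d = execute_strategy(parse_strategy_label("T1 1"), packaged, prevalence)
        assert all(v == 1.0 for v in d.referral_rates().values())


class TestTestingCosts:
    def test_m7_222_cancer_free_cost_closed_form(self, packaged, prevalence):
        """Cancer-free men: one scan, 0.93 referral, first biopsy always NC,
        re-biopsy always triggered => cost m + 1.86 b."""
        d = execute_strategy(parse_strategy_label("M7 222"), packaged, prevalence)
        m, b = 353.0, 461.0
        costs = d.expected_testing_cost_by_subgroup(
            {TestKind.MPMRI: m, TestKind.TRUSB: b, TestKind.TPMB: 0.0}
        )
        assert costs[Subgroup.NO_CANCER] == pytest.approx(m + 1.86 * b, rel=1e-12)

    def test_zero_unit_costs(self, packaged, prevalence):
        d = execute_strategy(parse_strategy_label("M7 222"), packaged, prevalence)
        assert d.expected_testing_cost({k: 0.0 for k in TestKind}) == 0.0

    def test_tpmb_alone_costs_one_tpmb_everywhere(self, packaged, prevalence):
        d = execute_strategy(parse_strategy_label("P1 2"), packaged, prevalence)
        costs = d.expected_testing_cost_by_subgroup({TestKind.TPMB: 987.0})
        assert all(v == pytest.approx(987.0) for v in costs.values())

    def test_negative_cost_rejected(self, packaged, prevalence):
        d = execute_strategy(parse_strategy_label("P1 1"), packaged, prevalence)
        with pytest.raises(ValueError, match="negative"):
            d.expected_testing_cost({TestKind.TPMB: -1.0})


class TestStructuralProperties:
    def test_mpmri_cutoff_nesting_monotonicity(self, packaged, prevalence):
        """Raising the cut-off never increases biopsy referral (nested cut-offs)."""
        for combo_label in ("M7 2{d}{c}", "M2 1{d}{c}"):
            for definition in (1, 2):
                previous = None
                for cutoff in (2, 3, 4, 5):
                    s = parse_strategy_label(combo_label.format(d=definition, c=cutoff))
                    d = execute_strategy(s, packaged, prevalence)
                    rates = d.referral_rates()
                    if previous is not None:
                        for subgroup in Subgroup:
                            assert rates[subgroup] <= previous[subgroup] + 1e-12
                    previous = rates

    def test_appending_terminal_tpmb_dominates(self, packaged, prevalence):
        """A terminal TPMB for undetected men lifts sensitivity to exactly 1
        and never lowers any subgroup's detection probability."""
        catchall = Stage(Not(AnyBiopsyResultIs((TestClass.CS,))), TestKind.TPMB)
        for label in ("M1 122", "M2 215", "T2 1", "T4 2", "T1 1"):
            base = parse_strategy_label(label)
            extended = dataclasses.replace(base, stages=base.stages + (catchall,))
            d_base = execute_strategy(base, packaged, prevalence)
            d_ext = execute_strategy(extended, packaged, prevalence)
            assert d_ext.sensitivity() == 1.0
            for subgroup in Subgroup:
                assert (
                    d_ext.diagnosis_probability(subgroup, Diagnosis.CS_DX)
                    >= d_base.diagnosis_probability(subgroup, Diagnosis.CS_DX) - 1e-12
                )

    def test_tpmb_terminal_strategies_have_perfect_sensitivity(
        self, packaged, prevalence, all_strategies
    ):
        terminal = [s for s in all_strategies if undetected_terminate_in_tpmb(s)]
        assert terminal
        for s in terminal:
            d = execute_strategy(s, packaged, prevalence)
            assert d.sensitivity() == 1.0


class TestMicrosimOracle:
    def test_same_seed_reproduces(self, packaged, prevalence):
        s = parse_strategy_label("M7 222")
        a = microsim_oracle(s, packaged, prevalence, 20_000, seed=11)
        b = microsim_oracle(s, packaged, prevalence, 20_000, seed=11)
        assert a.cells == b.cells

    def test_degenerate_table_matches_exactly(self, packaged, prevalence):
        """TPMB alone is deterministic, so the empirical distribution equals
        the exact one at any n."""
        s = parse_strategy_label("P1 1")
        exact = execute_strategy(s, packaged, prevalence)
        sim = microsim_oracle(s, packaged, prevalence, 16, seed=0)
        for subgroup in Subgroup:
            for key, p in exact.cells[subgroup].items():
                assert sim.cells[subgroup].get(key, 0.0) == pytest.approx(p)

    def test_agreement_with_exact_engine(self, packaged, prevalence):
        s = parse_strategy_label("M7 222")
        exact = execute_strategy(s, packaged, prevalence)
        sim = microsim_oracle(s, packaged, prevalence, 100_000, seed=2024)
        se = sensitivity_se(exact, prevalence, sim.n_by_subgroup)
        assert abs(sim.sensitivity() - exact.sensitivity()) <= 3 * se

    def test_n_zero_rejected(self, packaged, prevalence):
        with pytest.raises(ValueError):
            microsim_oracle(parse_strategy_label("P1 1"), packaged, prevalence, 0, seed=0)


# hypothesis property: oracle equivalence on random performance tables
@st.composite
def random_tables(draw):
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    entries = dict(tpmb_rows())
    for trusb_type in (1, 2, 3, 4, 5):
        for hdef in (1, 2):
            ctx = TestContext(TestKind.TRUSB, trusb_type=trusb_type, histology_definition=hdef)
            entries[(ctx, Subgroup.NO_CANCER)] = np.array([1.0, 0.0, 0.0])
            for sg in (Subgroup.LOW_RISK, Subgroup.INTERMEDIATE_RISK, Subgroup.HIGH_RISK):
                entries[(ctx, sg)] = rng.dirichlet(np.ones(3))
    for cutoff in (2, 3, 4, 5):
        for mdef in (1, 2):
            ctx = TestContext(TestKind.MPMRI, mpmri_definition=mdef, mpmri_cutoff=cutoff)
            for sg in Subgroup:
                entries[(ctx, sg)] = rng.dirichlet(np.ones(3))
    return TestPerformanceTable(entries)


@settings(max_examples=15, deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow])
@given(
    table=random_tables(),
    label=st.sampled_from(["M7 222", "M4 115", "T7 223", "T4 1", "N7 212", "P9 122"]),
)
def test_oracle_equivalence_on_random_tables(table, label, prevalence):
    """Exact propagation agrees with the microsimulation within Monte-Carlo
    error on arbitrary row-stochastic tables, not just the packaged ones."""
    s = parse_strategy_label(label)
    exact = execute_strategy(s, table, prevalence)
    sim = microsim_oracle(s, table, prevalence, 20_000, seed=5)
    se = sensitivity_se(exact, prevalence, sim.n_by_subgroup)
    assert abs(sim.sensitivity() - exact.sensitivity()) <= max(4 * se, 1e-12)
    for subgroup in Subgroup:
        assert sum(sim.cells[subgroup].values()) == pytest.approx(1.0, abs=1e-9)
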