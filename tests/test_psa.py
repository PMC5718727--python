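"""Probabilistic sensitivity analysis: distributions, sampling, acceptability."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from dxcea.bundle import UncertaintySettings
from dxcea.core import Subgroup, TestClass, TestKind
from dxcea.engine import execute_strategy
from dxcea.psa import (
    PSASamples,
    assign_distributions,
    beta_from_mean_ci,
    beta_from_mean_ess,
    ceac_ceaf,
    evaluate_strategies,
    frontier_probability,
    gamma_from_mean_cv,
    run_psa,
    sample_bundle,
)
from dxcea.strategies import parse_strategy_label

LABELS = ["M7 222", "T7 223", "P4 2"]


@pytest.fixture(scope="module")
def strategies():
    return [parse_strategy_label(l) for l in LABELS]


class TestDistributionHelpers:
    def test_beta_moment_matching_from_ci(self):
        a, b = beta_from_mean_ci(0.9, 0.86, 0.94)
        assert a / (a + b) == pytest.approx(0.9, abs=1e-6)
        # implied sd matches the normal-approximation half-width
        sd = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        assert sd == pytest.approx(0.04 / stats.norm.ppf(0.975), rel=1e-6)

    def test_beta_from_ess_mean(self):
        a, b = beta_from_mean_ess(0.25, 80)
        assert a / (a + b) == pytest.approx(0.25, abs=1e-12)

    def test_gamma_mean_and_cv(self):
        shape, scale = gamma_from_mean_cv(450.0, 0.2)
        assert shape * scale == pytest.approx(450.0, rel=1e-12)
        assert math.sqrt(shape) * scale / 450.0 == pytest.approx(0.2, rel=1e-12)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            beta_from_mean_ess(0.5, 0)
        with pytest.raises(ValueError):
            beta_from_mean_ci(0.9, 0.95, 0.99)
        with pytest.raises(ValueError):
            gamma_from_mean_cv(100.0, 0.0)


class TestSampling:
    def test_structural_zeros_survive_draws(self, bundle):
        rng = np.random.default_rng(5)
        spec = assign_distributions(bundle)
        for _ in range(5):
            draw = sample_bundle(spec, rng)
            for (ctx, subgroup), row in draw.perf.entries.items():
                if ctx.test.is_biopsy and subgroup is Subgroup.NO_CANCER:
                    assert tuple(row) == (1.0, 0.0, 0.0)
                if ctx.test is TestKind.TRUSB and subgroup is Subgroup.LOW_RISK:
                    assert row[TestClass.CS] == 0.0
            d = execute_strategy(parse_strategy_label("M7 222"), draw.perf, draw.prevalence)
            assert d.specificity() == 1.0

    def test_rows_remain_stochastic(self, bundle):
        rng = np.random.default_rng(6)
        draw = sample_bundle(assign_distributions(bundle), rng)
        for row in draw.perf.entries.values():
            assert row.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_spec_returns_point_estimates(self, bundle):
        degen = dataclasses.replace(
            bundle, uncertainty=dataclasses.replace(bundle.uncertainty, degenerate=True)
        )
        rng = np.random.default_rng(7)
        assert sample_bundle(assign_distributions(degen), rng) is degen


class TestRunPsa:
    def test_reproducible_under_seed(self, bundle, strategies):
        a = run_psa(bundle, strategies, n=5, seed=21)
        b = run_psa(bundle, strategies, n=5, seed=21)
        assert np.array_equal(a.testing_cost, b.testing_cost)
        assert np.array_equal(a.qalys, b.qalys)

    def test_degenerate_equals_deterministic(self, bundle, strategies):
        degen = dataclasses.replace(
            bundle, uncertainty=dataclasses.replace(bundle.uncertainty, degenerate=True)
        )
        samples = run_psa(degen, strategies, n=3, seed=0)
        det = evaluate_strategies(bundle, strategies)
        for i in range(3):
            assert samples.testing_cost[i] == pytest.approx(det["testing_cost"].to_numpy())
            assert samples.qalys[i] == pytest.approx(det["qalys"].to_numpy())

    def test_mean_preservation_testing_cost(self, bundle, strategies):
        """Mean-preserving families: PSA means match the deterministic run
        within Monte-Carlo error."""
        n = 400
        samples = run_psa(bundle, strategies, n=n, seed=13)
        det = evaluate_strategies(bundle, strategies)["testing_cost"].to_numpy()
        mean = samples.testing_cost.mean(axis=0)
        se = samples.testing_cost.std(axis=0, ddof=1) / math.sqrt(n)
        assert (np.abs(mean - det) <= 3 * se).all()


class TestAcceptability:
    def test_single_strategy_always_cost_effective(self, bundle, strategies):
        samples = run_psa(bundle, strategies[:1], n=10, seed=3)
        table = ceac_ceaf(samples, [13_000.0, 20_000.0, 30_000.0])
        assert (table["ceac"] == 1.0).all()
        assert (table["on_ceaf"]).all()

    def test_ceac_columns_sum_to_one(self, bundle, strategies):
        samples = run_psa(bundle, strategies, n=40, seed=9)
        table = ceac_ceaf(samples, [13_000.0, 20_000.0, 30_000.0])
        sums = table.groupby("threshold")["ceac"].sum()
        assert np.allclose(sums, 1.0)
        # CEAF never exceeds the pointwise maximum CEAC
        for lam, grp in table.groupby("threshold"):
            ceaf = grp["ceaf"].dropna()
            assert len(ceaf) == 1
            assert float(ceaf.iloc[0]) <= grp["ceac"].max() + 1e-12

    def test_empty_threshold_set_rejected(self, bundle, strategies):
        samples = run_psa(bundle, strategies[:1], n=2, seed=0)
        with pytest.raises(ValueError, match="threshold"):
            ceac_ceaf(samples, [])

    def test_ceac_break_even_on_constructed_costs(self):
        """Two strategies with fixed effects and normal cost noise cross at
        the analytic break-even threshold (CEAC = 1/2)."""
        rng = np.random.default_rng(17)
        n = 4000
        e1, e2 = 10.0, 10.1
        c1 = 5000.0 + 200.0 * rng.standard_normal(n)
        c2 = 6000.0 + 200.0 * rng.standard_normal(n)
        samples = PSASamples(
            labels=["a", "b"],
            detection=np.zeros((n, 2)),
            testing_cost=np.zeros((n, 2)),
            qalys=np.column_stack([np.full(n, e1), np.full(n, e2)]),
            total_cost=np.column_stack([c1, c2]),
            n_simulations=n,
            seed=17,
        )
        break_even = (6000.0 - 5000.0) / (e2 - e1)  # 10 000 per QALY
        table = ceac_ceaf(samples, [break_even])
        ceac_b = float(table.loc[table["label"] == "b", "ceac"].iloc[0])
        assert ceac_b == pytest.approx(0.5, abs=3 * math.sqrt(0.25 / n))

    def test_frontier_probability_degenerate_matches_deterministic(self, bundle, strategies):
        from dxcea.economics import CEPoint, efficiency_frontier

        degen = dataclasses.replace(
            bundle, uncertainty=dataclasses.replace(bundle.uncertainty, degenerate=True)
        )
        samples = run_psa(degen, strategies, n=4, seed=1)
        probs = frontier_probability(samples, mode="qaly")
        det = evaluate_strategies(bundle, strategies)
        points = [
            CEPoint(r.label, float(r.qalys), float(r.total_cost)) for r in det.itertuples()
        ]
        on = set(efficiency_frontier(points).labels)
        for rec in probs.itertuples():
            assert rec.frontier_probability == (1.0 if rec.label in on else 0.0)

    def test_frontier_probability_nonempty_each_simulation(self, bundle, strategies):
        samples = run_psa(bundle, strategies, n=30, seed=8)
        probs = frontier_probability(samples, mode="detection")
        assert probs["frontier_probability"].max() > 0
        assert (probs["frontier_probability"] >= 0).all()
        assert (probs["frontier_probability"] <= 1).all()
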