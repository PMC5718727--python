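"""Probabilistic sensitivity analysis (PSA).

Parameter uncertainty is propagated by Monte Carlo: classification rows
and the prevalence vector get Dirichlet distributions (concentration =
point estimate x effective sample size, structural zeros frozen), costs
get gamma distributions (mean-preserving, configurable coefficient of
variation), and utility decrements and transition probabilities get beta
distributions. All families are mean-preserving, so the probabilistic
base case converges to the deterministic run as uncertainty shrinks.

``run_psa`` evaluates the full pipeline (decision tree + Markov model)
per draw and returns per-simulation cost/effect arrays, from which
cost-effectiveness acceptability curves (CEAC), the acceptability
frontier (CEAF) and frontier-membership probabilities are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import ModelBundle, UncertaintySettings
from .core import SUBGROUPS, Subgroup, SubgroupPrevalence, TestKind
from .engine import execute_strategy
from .markov import CancerTransitions, TransitionSet, lifetime_outcomes
from .perftable import TestPerformanceTable
from .strategies import Strategy


# ---------------------------------------------------------------------------
# Distribution helpers


def beta_from_mean_ess(mean: float, ess: float) -> Tuple[float, float]:
    """Beta parameters with the given mean and effective sample size."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0,1), got {mean}")
    if ess <= 0:
        raise ValueError("effective sample size must be > 0")
    return mean * ess, (1.0 - mean) * ess


def beta_from_mean_ci(mean: float, lower: float, upper: float, level: float = 0.95) -> Tuple[float, float]:
    """Moment-match beta parameters from a mean and a symmetric CI.

    The CI half-width is converted to a standard deviation via the normal
    approximation, then (alpha, beta) are solved from the beta moments.
    """
    if not lower < mean < upper:
        raise ValueError("need lower < mean < upper")
    z = stats.norm.ppf(0.5 + level / 2.0)
    sd = (upper - lower) / (2.0 * z)
    var = sd**2
    if var >= mean * (1.0 - mean):
        raise ValueError("variance too large for a beta distribution at this mean")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_cv(mean: float, cv: float) -> Tuple[float, float]:
    """Gamma (shape, scale) with the given mean and coefficient of variation."""
    if mean < 0 or cv < 0:
        raise ValueError("mean and cv must be >= 0")
    if cv == 0 or mean == 0:
        raise ValueError("degenerate gamma; handle as point mass")
    shape = 1.0 / cv**2
    return shape, mean * cv**2


@dataclass(frozen=True)
class DistributionSpec:
    """Families and hyper-parameters attached to every uncertain input."""

    bundle: ModelBundle
    degenerate: bool

    @property
    def uncertainty(self) -> UncertaintySettings:
        return self.bundle.uncertainty


def assign_distributions(bundle: ModelBundle) -> DistributionSpec:
    """Attach the configured uncertainty families to a bundle's point estimates.

    Means equal the point estimates by construction. Structural zeros in
    classification rows receive no Dirichlet mass, so properties such as
    perfect specificity survive the perturbation.
    """
    return DistributionSpec(bundle=bundle, degenerate=bundle.uncertainty.degenerate)


def _draw_dirichlet_row(row: np.ndarray, ess: float, rng: np.random.Generator) -> np.ndarray:
    support = row > 0.0
    if support.sum() <= 1:
        return row.copy()  # degenerate row: a single certain class
    draw = rng.dirichlet(row[support] * ess)
    out = np.zeros_like(row)
    out[support] = draw
    return out


def sample_bundle(spec: DistributionSpec, rng: np.random.Generator) -> ModelBundle:
    """One seeded parameter draw; degenerate specs return the point estimates."""
    bundle = spec.bundle
    if spec.degenerate:
        return bundle
    unc = spec.uncertainty

    perf_entries = {}
    for (ctx, subgroup), row in bundle.perf.entries.items():
        if ctx.test is TestKind.TPMB or (ctx.test.is_biopsy and subgroup is Subgroup.NO_CANCER):
            perf_entries[(ctx, subgroup)] = row.copy()  # structural, not a parameter
        else:
            perf_entries[(ctx, subgroup)] = _draw_dirichlet_row(row, unc.ess_performance, rng)
    perf = TestPerformanceTable(perf_entries)

    prev_point = np.array([bundle.prevalence[s] for s in SUBGROUPS])
    prev_draw = _draw_dirichlet_row(prev_point, unc.ess_prevalence, rng)
    prevalence = SubgroupPrevalence({s: float(p) for s, p in zip(SUBGROUPS, prev_draw)})

    def gamma_cost(mean: float) -> float:
        if mean == 0 or unc.cost_cv == 0:
            return mean
        shape, scale = gamma_from_mean_cv(mean, unc.cost_cv)
        return float(rng.gamma(shape, scale))

    test_costs = {k: gamma_cost(v) for k, v in bundle.test_costs.items()}
    cost_model = replace(
        bundle.cost_model,
        radical_treatment=gamma_cost(bundle.cost_model.radical_treatment),
        surveillance_per_cycle=gamma_cost(bundle.cost_model.surveillance_per_cycle),
        metastatic_per_cycle=gamma_cost(bundle.cost_model.metastatic_per_cycle),
    )

    def beta_prob(mean: float, ess: float) -> float:
        if mean <= 0.0 or mean >= 1.0:
            return mean
        a, b = beta_from_mean_ess(mean, ess)
        return float(rng.beta(a, b))

    utility_model = replace(
        bundle.utility_model,
        metastatic_decrement=beta_prob(bundle.utility_model.metastatic_decrement, unc.ess_utility),
        tpmb_decrement=beta_prob(bundle.utility_model.tpmb_decrement, unc.ess_utility),
    )

    regimes = {}
    for key, tr in bundle.transitions.regimes.items():
        regimes[key] = CancerTransitions(
            beta_prob(tr.p_localised_to_metastatic, unc.ess_transitions),
            beta_prob(tr.p_localised_to_death, unc.ess_transitions),
            beta_prob(tr.p_metastatic_to_death, unc.ess_transitions),
        )
    transitions = TransitionSet(regimes, bundle.transitions.mortality)

    return replace(
        bundle,
        perf=perf,
        prevalence=prevalence,
        test_costs=test_costs,
        cost_model=cost_model,
        utility_model=utility_model,
        transitions=transitions,
    )


# ---------------------------------------------------------------------------
# PSA runner


@dataclass
class PSASamples:
    """Per-simulation cost/effect arrays for a set of strategies.

    Arrays have shape (n_simulations, n_strategies), with strategy
    columns ordered by ``labels``.
    """

    labels: List[str]
    detection: np.ndarray  # CS cancers detected per man
    testing_cost: np.ndarray
    qalys: np.ndarray
    total_cost: np.ndarray
    n_simulations: int
    seed: int

    def means(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "detection": self.detection.mean(axis=0),
                "testing_cost": self.testing_cost.mean(axis=0),
                "qalys": self.qalys.mean(axis=0),
                "total_cost": self.total_cost.mean(axis=0),
            }
        )

    def plane(self, mode: str) -> Tuple[np.ndarray, np.ndarray]:
        if mode == "detection":
            return self.testing_cost, self.detection
        if mode == "qaly":
            return self.total_cost, self.qalys
        raise ValueError(f"unknown mode {mode!r}")


def evaluate_strategies(
    bundle: ModelBundle, strategies: Sequence[Strategy]
) -> pd.DataFrame:
    """Deterministic evaluation of each strategy under one parameter set."""
    rows = []
    for strategy in strategies:
        d = execute_strategy(strategy, bundle.perf, bundle.prevalence)
        life = lifetime_outcomes(
            d,
            bundle.transitions,
            bundle.utility_model,
            bundle.cost_model,
            bundle.econ,
            test_unit_costs=bundle.test_costs,
        )
        rows.append(
            {
                "label": strategy.label,
                "sensitivity": d.sensitivity(),
                "specificity": d.specificity(),
                "detection": d.cs_detected_per_man(),
                "testing_cost": d.expected_testing_cost(bundle.test_costs),
                "qalys": life.total_qalys,
                "total_cost": life.total_costs,
            }
        )
    return pd.DataFrame(rows)


def run_psa(
    bundle: ModelBundle,
    strategies: Sequence[Strategy],
    n: int = 1000,
    seed: int = 0,
) -> PSASamples:
    """Monte Carlo propagation of parameter uncertainty through the pipeline."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = assign_distributions(bundle)
    rng = np.random.default_rng(seed)
    labels = [s.label for s in strategies]
    shape = (n, len(strategies))
    detection = np.empty(shape)
    testing_cost = np.empty(shape)
    qalys = np.empty(shape)
    total_cost = np.empty(shape)
    for i in range(n):
        draw = sample_bundle(spec, rng)
        res = evaluate_strategies(draw, strategies)
        detection[i] = res["detection"].to_numpy()
        testing_cost[i] = res["testing_cost"].to_numpy()
        qalys[i] = res["qalys"].to_numpy()
        total_cost[i] = res["total_cost"].to_numpy()
    return PSASamples(
        labels=labels,
        detection=detection,
        testing_cost=testing_cost,
        qalys=qalys,
        total_cost=total_cost,
        n_simulations=n,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Acceptability


def ceac_ceaf(samples: PSASamples, thresholds: Sequence[float]) -> pd.DataFrame:
    """CEAC per strategy and threshold, plus the acceptability frontier.

    The CEAC at a threshold is the fraction of simulations in which the
    strategy maximises net monetary benefit (ties keep the first label in
    sort order). The CEAF value is the CEAC of the strategy with the
    highest expected net benefit at that threshold.
    """
    if len(thresholds) == 0:
        raise ValueError("empty threshold set")
    if samples.n_simulations < 1:
        raise ValueError("need at least one simulation")
    order = np.argsort(np.asarray(samples.labels, dtype=object))
    labels = [samples.labels[i] for i in order]
    cost = samples.total_cost[:, order]
    eff = samples.qalys[:, order]
    rows = []
    for lam in thresholds:
        nb = lam * eff - cost
        winner = nb.argmax(axis=1)  # argmax keeps first of equals: label order
        counts = np.bincount(winner, minlength=len(labels))
        ceac = counts / samples.n_simulations
        best_expected = int(nb.mean(axis=0).argmax())
        for j, label in enumerate(labels):
            rows.append(
                {
                    "threshold": lam,
                    "label": label,
                    "ceac": ceac[j],
                    "on_ceaf": j == best_expected,
                    "ceaf": ceac[best_expected] if j == best_expected else np.nan,
                }
            )
    return pd.DataFrame(rows)


def frontier_probability(samples: PSASamples, mode: str = "qaly") -> pd.DataFrame:
    """Per-strategy probability of lying on the efficiency frontier.

    The fraction of simulations in which the strategy is a frontier
    member in the chosen plane (``"qaly"``: lifetime cost vs QALYs;
    ``"detection"``: testing cost vs CS cancers detected). Together with
    the mean frontier this supports the three-way classification of
    strategies: on the mean frontier, off it but with non-zero frontier
    probability, or never on the frontier.
    """
    from .economics import CEPoint, efficiency_frontier

    cost, eff = samples.plane(mode)
    hits = np.zeros(len(samples.labels))
    for i in range(samples.n_simulations):
        points = [
            CEPoint(label, float(eff[i, j]), float(max(cost[i, j], 0.0)))
            for j, label in enumerate(samples.labels)
        ]
        on = set(efficiency_frontier(points).labels)
        for j, label in enumerate(samples.labels):
            if label in on:
                hits[j] += 1
    return pd.DataFrame(
        {"label": samples.labels, "frontier_probability": hits / samples.n_simulations}
    )
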