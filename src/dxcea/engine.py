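"""Exact evaluation of diagnostic strategies, plus a microsimulation oracle.

``execute_strategy`` propagates each true-status subgroup through the
strategy's stages by exact enumeration of all branches: a stage whose
predicate matches the current history multiplies the branch probability
by the subgroup-conditional classification probabilities of its test.
Successive test results are conditionally independent given the subgroup
and the test context; history dependence enters only through context
selection (the five TRUSB types).

``microsim_oracle`` routes individual simulated men through the same
stage logic with sampled test results; it is used as an independent
check on the exact engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .core import (
    CS_SUBGROUPS,
    Diagnosis,
    DIAGNOSIS_BY_SEVERITY,
    SUBGROUPS,
    Subgroup,
    SubgroupPrevalence,
    TestClass,
    TestContext,
    TestKind,
)
from .perftable import TestPerformanceTable
from .strategies import PathState, Strategy, resolve_trusb_type

#: cell key: (diagnosis, (n_mpmri, n_trusb, n_tpmb))
CellKey = Tuple[Diagnosis, Tuple[int, int, int]]


@dataclass
class DiagnosisDistribution:
    """Joint distribution over diagnosis and tests administered, by subgroup.

    ``cells[subgroup]`` is a distribution over (final diagnosis, count of
    each test kind), conditional on the subgroup; each sums to 1. The
    prevalence used for marginal summaries is carried alongside.
    """

    strategy_label: str
    cells: Dict[Subgroup, Dict[CellKey, float]]
    prevalence: SubgroupPrevalence
    #: per-subgroup sample sizes when the distribution is empirical
    n_by_subgroup: Optional[Dict[Subgroup, int]] = None

    def __post_init__(self) -> None:
        for subgroup, dist in self.cells.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"cells for {subgroup.value} sum to {total}, not 1 (strategy {self.strategy_label})"
                )

    # -- diagnosis margins ---------------------------------------------------

    def diagnosis_probability(self, subgroup: Subgroup, diagnosis: Diagnosis) -> float:
        return sum(p for (dx, _), p in self.cells[subgroup].items() if dx is diagnosis)

    def sensitivity(self) -> float:
        """P(CS diagnosis | clinically significant cancer), prevalence-weighted."""
        cs_prev = self.prevalence.cs_prevalence
        if cs_prev <= 0.0:
            raise ValueError("sensitivity undefined: zero CS prevalence")
        num = sum(
            self.prevalence[s] * self.diagnosis_probability(s, Diagnosis.CS_DX)
            for s in CS_SUBGROUPS
        )
        return num / cs_prev

    def specificity(self) -> float:
        """1 - P(CS diagnosis | no cancer or low-risk), prevalence-weighted."""
        non_cs = (Subgroup.NO_CANCER, Subgroup.LOW_RISK)
        prev = sum(self.prevalence[s] for s in non_cs)
        if prev <= 0.0:
            raise ValueError("specificity undefined: zero non-CS prevalence")
        num = sum(
            self.prevalence[s] * self.diagnosis_probability(s, Diagnosis.CS_DX) for s in non_cs
        )
        return 1.0 - num / prev

    def cs_detected_per_man(self) -> float:
        """Expected CS cancers correctly diagnosed per man referred."""
        return sum(
            self.prevalence[s] * self.diagnosis_probability(s, Diagnosis.CS_DX)
            for s in CS_SUBGROUPS
        )

    # -- testing margins -------------------------------------------------------

    def biopsy_referral(self, subgroup: Subgroup) -> float:
        """P(at least one biopsy | subgroup)."""
        return sum(
            p for (_, counts), p in self.cells[subgroup].items() if counts[1] + counts[2] >= 1
        )

    def referral_rates(self) -> Dict[Subgroup, float]:
        return {s: self.biopsy_referral(s) for s in self.cells}

    def expected_counts(self, subgroup: Subgroup) -> Dict[TestKind, float]:
        out = {k: 0.0 for k in TestKind}
        for (_, counts), p in self.cells[subgroup].items():
            out[TestKind.MPMRI] += p * counts[0]
            out[TestKind.TRUSB] += p * counts[1]
            out[TestKind.TPMB] += p * counts[2]
        return out

    def expected_counts_per_man(self) -> Dict[TestKind, float]:
        out = {k: 0.0 for k in TestKind}
        for s in self.cells:
            counts = self.expected_counts(s)
            for k in TestKind:
                out[k] += self.prevalence[s] * counts[k]
        return out

    def expected_testing_cost(self, unit_costs: Mapping[TestKind, float]) -> float:
        """Prevalence-weighted expected cost of the tests administered."""
        for kind, c in unit_costs.items():
            if c < 0:
                raise ValueError(f"negative unit cost for {kind}")
        counts = self.expected_counts_per_man()
        return sum(counts[k] * float(unit_costs.get(k, 0.0)) for k in TestKind)

    def expected_testing_cost_by_subgroup(
        self, unit_costs: Mapping[TestKind, float]
    ) -> Dict[Subgroup, float]:
        out = {}
        for s in self.cells:
            counts = self.expected_counts(s)
            out[s] = sum(counts[k] * float(unit_costs.get(k, 0.0)) for k in TestKind)
        return out


# ---------------------------------------------------------------------------
# Exact propagation


def execute_strategy(
    strategy: Strategy,
    perf: TestPerformanceTable,
    prevalence: SubgroupPrevalence,
) -> DiagnosisDistribution:
    """Exactly propagate each subgroup through the strategy's decision tree."""
    cells: Dict[Subgroup, Dict[CellKey, float]] = {}
    for subgroup in SUBGROUPS:
        dist: Dict[CellKey, float] = {}

        def walk(stage_idx: int, state: PathState, prob: float, used: frozenset) -> None:
            if prob == 0.0:
                return
            if stage_idx == len(strategy.stages):
                key = (state.diagnosis, state.counts)
                dist[key] = dist.get(key, 0.0) + prob
                return
            stage = strategy.stages[stage_idx]
            if not stage.predicate(state):
                walk(stage_idx + 1, state, prob, used)
                return
            ctx = strategy.context_for(stage, state)
            if ctx in used:
                raise ValueError(
                    f"strategy {strategy.label} repeats context {ctx} on one path"
                )
            row = perf.row(ctx, subgroup)
            for result in TestClass:
                walk(
                    stage_idx + 1,
                    state.after(ctx, result),
                    prob * float(row[result]),
                    used | {ctx},
                )

        walk(0, PathState(), 1.0, frozenset())
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise RuntimeError(f"propagation lost probability mass: {total}")
        cells[subgroup] = dist
    return DiagnosisDistribution(strategy.label, cells, prevalence)


# ---------------------------------------------------------------------------
# Microsimulation oracle


@dataclass
class StateVectors:
    """Vectorised path state for a batch of simulated men (one subgroup)."""

    size: int
    mpmri: np.ndarray = field(default=None)  # -1 = not done, else TestClass value
    last_biopsy: np.ndarray = field(default=None)
    n_mpmri: np.ndarray = field(default=None)
    n_trusb: np.ndarray = field(default=None)
    n_tpmb: np.ndarray = field(default=None)
    max_biopsy: np.ndarray = field(default=None)
    seen: np.ndarray = field(default=None)  # (size, 3) bool

    def __post_init__(self) -> None:
        n = self.size
        self.mpmri = np.full(n, -1, dtype=np.int8)
        self.last_biopsy = np.full(n, -1, dtype=np.int8)
        self.n_mpmri = np.zeros(n, dtype=np.int8)
        self.n_trusb = np.zeros(n, dtype=np.int8)
        self.n_tpmb = np.zeros(n, dtype=np.int8)
        self.max_biopsy = np.full(n, -1, dtype=np.int8)
        self.seen = np.zeros((n, 3), dtype=bool)


def _allocate_counts(n: int, prevalence: SubgroupPrevalence) -> Dict[Subgroup, int]:
    """Deterministic largest-remainder allocation of n men to subgroups."""
    raw = {s: n * prevalence[s] for s in SUBGROUPS}
    base = {s: int(np.floor(raw[s])) for s in SUBGROUPS}
    short = n - sum(base.values())
    order = sorted(SUBGROUPS, key=lambda s: raw[s] - base[s], reverse=True)
    for s in order[:short]:
        base[s] += 1
    return base


def _sample_classes(row: np.ndarray, u: np.ndarray) -> np.ndarray:
    cum = np.cumsum(row)
    cum[-1] = 1.0  # guard against rounding
    return np.searchsorted(cum, u, side="right").astype(np.int8)


def microsim_oracle(
    strategy: Strategy,
    perf: TestPerformanceTable,
    prevalence: SubgroupPrevalence,
    n: int,
    seed: int,
) -> DiagnosisDistribution:
    """Simulate n men through the routing rules; empirical margins converge
    to those of :func:`execute_strategy`.

    Men are allocated to subgroups deterministically in proportion to the
    prevalence (largest remainder), so the per-subgroup conditional
    estimates are plain binomial proportions at known sample sizes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    alloc = _allocate_counts(n, prevalence)
    cells: Dict[Subgroup, Dict[CellKey, float]] = {}
    for subgroup in SUBGROUPS:
        n_sg = alloc[subgroup]
        if n_sg == 0:
            cells[subgroup] = {(Diagnosis.NO_CANCER_DX, (0, 0, 0)): 1.0}
            continue
        sv = StateVectors(n_sg)
        for stage in strategy.stages:
            mask = stage.predicate.mask(sv)
            idx = np.nonzero(mask)[0]
            if idx.size == 0:
                continue
            if stage.test is TestKind.MPMRI:
                ctx = TestContext(
                    TestKind.MPMRI,
                    mpmri_definition=strategy.mpmri_definition,
                    mpmri_cutoff=strategy.mpmri_cutoff,
                )
                res = _sample_classes(perf.row(ctx, subgroup), rng.random(idx.size))
                sv.mpmri[idx] = res
                sv.n_mpmri[idx] += 1
                continue
            if stage.test is TestKind.TPMB:
                ctx = TestContext(TestKind.TPMB, histology_definition=strategy.histology_definition)
                res = _sample_classes(perf.row(ctx, subgroup), rng.random(idx.size))
                sv.n_tpmb[idx] += 1
            else:
                # TRUSB context varies per man with his history
                types = np.empty(idx.size, dtype=np.int8)
                no_scan = sv.mpmri[idx] < 0
                none_yet = (sv.n_trusb[idx] + sv.n_tpmb[idx]) == 0
                types[no_scan & none_yet] = 1
                types[no_scan & ~none_yet & (sv.last_biopsy[idx] == 0)] = 2
                types[no_scan & ~none_yet & (sv.last_biopsy[idx] == 1)] = 3
                types[~no_scan & none_yet] = 4
                types[~no_scan & ~none_yet] = 5
                res = np.empty(idx.size, dtype=np.int8)
                for t in np.unique(types):
                    ctx = TestContext(
                        TestKind.TRUSB,
                        trusb_type=int(t),
                        histology_definition=strategy.histology_definition,
                    )
                    sel = types == t
                    res[sel] = _sample_classes(perf.row(ctx, subgroup), rng.random(int(sel.sum())))
                sv.n_trusb[idx] += 1
            sv.last_biopsy[idx] = res
            sv.max_biopsy[idx] = np.maximum(sv.max_biopsy[idx], res)
            sv.seen[idx, res] = True
        packed = (
            (sv.max_biopsy.astype(np.int64) + 1)
            + 10 * sv.n_mpmri.astype(np.int64)
            + 100 * sv.n_trusb.astype(np.int64)
            + 1000 * sv.n_tpmb.astype(np.int64)
        )
        keys, counts = np.unique(packed, return_counts=True)
        dist: Dict[CellKey, float] = {}
        for key, count in zip(keys, counts):
            max_b = int(key % 10) - 1
            dx = Diagnosis.NO_CANCER_DX if max_b < 0 else DIAGNOSIS_BY_SEVERITY[TestClass(max_b)]
            counts_vec = (int(key // 10 % 10), int(key // 100 % 10), int(key // 1000 % 10))
            cell = (dx, counts_vec)
            dist[cell] = dist.get(cell, 0.0) + count / n_sg
        cells[subgroup] = dist
    return DiagnosisDistribution(strategy.label, cells, prevalence, n_by_subgroup=alloc)
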