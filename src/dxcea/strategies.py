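"""Diagnostic strategies: routing predicates, combinations, and labels.

A strategy is an ordered list of up to three stages. Each stage pairs a
routing predicate over the man's test history with a test to administer.
Strategies are labelled by their combination code (M1-M7, N1-N7, T1-T9,
P1-P9) followed by the variant digits: biopsy histology definition, then
— when the combination uses MPMRI — the MPMRI definition and Likert
cut-off. For example ``"M1 125"`` is combination M1 with histology
definition 1, MPMRI definition 2 and cut-off =5, and ``"P4 2"`` is
combination P4 with histology definition 2 (no MPMRI in the pathway).

Combination families:

* **M**: MPMRI first; MRI-targeted TRUSB in men whose scan is suspicious;
  M3-M7 re-biopsy on various first-biopsy results (non-CS detected, no
  cancer detected, or CS not detected), restricted to men with a
  suspicion of CS cancer on the scan.
* **T**: TRUSB first; T2-T4 repeat the TRUSB on various results; T5-T9
  scan men after a non-diagnostic TRUSB and re-biopsy on suspicion.
* **N** / **P**: as M / T but the final biopsy stage is a template
  mapping biopsy (TPMB, the perfect reference test) instead of a TRUSB.
  P1 is TPMB alone.

The five TRUSB performance contexts (first biopsy, repeat after NC,
repeat after non-CS, MRI-targeted, MRI-targeted repeat) are resolved
automatically from the history, so a single ``TRUSB`` stage declaration
picks the correct performance row wherever it sits in a pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence, Tuple

from .core import Diagnosis, DIAGNOSIS_BY_SEVERITY, TestClass, TestContext, TestKind

#: Total printed for this pathway family after feasibility pruning; the
#: pruning rules themselves are not public, so the default grid is larger.
REPORTED_PRUNED_TOTAL = 383


class StrategyLabelError(ValueError):
    """Raised when a strategy label does not match the grammar."""


# ---------------------------------------------------------------------------
# Path state and predicates


@dataclass
class PathState:
    """Summary of a man's test history along one branch of the tree."""

    mpmri_result: Optional[TestClass] = None
    last_biopsy: Optional[TestClass] = None
    max_biopsy: Optional[TestClass] = None
    seen_biopsy: frozenset = frozenset()
    n_mpmri: int = 0
    n_trusb: int = 0
    n_tpmb: int = 0

    @property
    def n_biopsy(self) -> int:
        return self.n_trusb + self.n_tpmb

    def after(self, ctx: TestContext, result: TestClass) -> "PathState":
        if ctx.test is TestKind.MPMRI:
            return replace(self, mpmri_result=result, n_mpmri=self.n_mpmri + 1)
        max_b = result if self.max_biopsy is None else max(self.max_biopsy, result)
        kwargs = dict(
            last_biopsy=result,
            max_biopsy=max_b,
            seen_biopsy=self.seen_biopsy | {result},
        )
        if ctx.test is TestKind.TRUSB:
            kwargs["n_trusb"] = self.n_trusb + 1
        else:
            kwargs["n_tpmb"] = self.n_tpmb + 1
        return replace(self, **kwargs)

    @property
    def diagnosis(self) -> Diagnosis:
        """Most severe biopsy result on the path; no biopsy means no cancer."""
        if self.max_biopsy is None:
            return Diagnosis.NO_CANCER_DX
        return DIAGNOSIS_BY_SEVERITY[self.max_biopsy]

    @property
    def counts(self) -> Tuple[int, int, int]:
        return (self.n_mpmri, self.n_trusb, self.n_tpmb)


class Predicate:
    """Routing predicate over a :class:`PathState`.

    Subclasses implement :meth:`__call__` for the exact engine and
    :meth:`mask` (vectorised over state arrays) for the microsimulation.
    """

    name: str = "predicate"

    def __call__(self, state: PathState) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def mask(self, sv):  # pragma: no cover - abstract
        raise NotImplementedError

    def describe(self) -> str:
        return self.name


@dataclass(frozen=True)
class Always(Predicate):
    def __call__(self, state: PathState) -> bool:
        return True

    def mask(self, sv):
        import numpy as np

        return np.ones(sv.size, dtype=bool)

    def describe(self) -> str:
        return "always"


@dataclass(frozen=True)
class MpmriSuspicionIs(Predicate):
    """True when the (single) MPMRI result is one of the given classes."""

    classes: Tuple[TestClass, ...]

    def __call__(self, state: PathState) -> bool:
        return state.mpmri_result is not None and state.mpmri_result in self.classes

    def mask(self, sv):
        import numpy as np

        out = np.zeros(sv.size, dtype=bool)
        for cls in self.classes:
            out |= sv.mpmri == int(cls)
        return out

    def describe(self) -> str:
        return "mpmri-suspicion-is " + "/".join(c.name for c in self.classes)


@dataclass(frozen=True)
class LastBiopsyResultIs(Predicate):
    classes: Tuple[TestClass, ...]

    def __call__(self, state: PathState) -> bool:
        return state.last_biopsy is not None and state.last_biopsy in self.classes

    def mask(self, sv):
        import numpy as np

        out = np.zeros(sv.size, dtype=bool)
        for cls in self.classes:
            out |= sv.last_biopsy == int(cls)
        return out

    def describe(self) -> str:
        return "last-result-is " + "/".join(c.name for c in self.classes)


@dataclass(frozen=True)
class AnyBiopsyResultIs(Predicate):
    classes: Tuple[TestClass, ...]

    def __call__(self, state: PathState) -> bool:
        return any(c in state.seen_biopsy for c in self.classes)

    def mask(self, sv):
        import numpy as np

        out = np.zeros(sv.size, dtype=bool)
        for cls in self.classes:
            out |= sv.seen[:, int(cls)]
        return out

    def describe(self) -> str:
        return "any-biopsy-result-is " + "/".join(c.name for c in self.classes)


@dataclass(frozen=True)
class TestCountOf(Predicate):
    """True when the count of a given test kind satisfies min/max bounds."""

    kind: TestKind
    at_least: int = 0
    at_most: Optional[int] = None

    def _count(self, state: PathState) -> int:
        return {
            TestKind.MPMRI: state.n_mpmri,
            TestKind.TRUSB: state.n_trusb,
            TestKind.TPMB: state.n_tpmb,
        }[self.kind]

    def __call__(self, state: PathState) -> bool:
        c = self._count(state)
        return c >= self.at_least and (self.at_most is None or c <= self.at_most)

    def mask(self, sv):
        c = {TestKind.MPMRI: sv.n_mpmri, TestKind.TRUSB: sv.n_trusb, TestKind.TPMB: sv.n_tpmb}[self.kind]
        out = c >= self.at_least
        if self.at_most is not None:
            out &= c <= self.at_most
        return out

    def describe(self) -> str:
        hi = "inf" if self.at_most is None else self.at_most
        return f"test-count-of {self.kind.value} in [{self.at_least},{hi}]"


@dataclass(frozen=True)
class All(Predicate):
    parts: Tuple[Predicate, ...]

    def __call__(self, state: PathState) -> bool:
        return all(p(state) for p in self.parts)

    def mask(self, sv):
        out = self.parts[0].mask(sv)
        for p in self.parts[1:]:
            out &= p.mask(sv)
        return out

    def describe(self) -> str:
        return "(" + " and ".join(p.describe() for p in self.parts) + ")"


@dataclass(frozen=True)
class Not(Predicate):
    part: Predicate

    def __call__(self, state: PathState) -> bool:
        return not self.part(state)

    def mask(self, sv):
        return ~self.part.mask(sv)

    def describe(self) -> str:
        return "not " + self.part.describe()


# ---------------------------------------------------------------------------
# Stages and strategies


@dataclass(frozen=True)
class Stage:
    predicate: Predicate
    test: TestKind


def resolve_trusb_type(state: PathState) -> int:
    """Select the TRUSB performance context implied by the history."""
    if state.mpmri_result is None:
        if state.n_biopsy == 0:
            return 1
        if state.last_biopsy is TestClass.NC:
            return 2
        if state.last_biopsy is TestClass.NON_CS:
            return 3
        raise ValueError("repeat TRUSB after a CS-detecting biopsy is not a defined context")
    return 4 if state.n_biopsy == 0 else 5


@dataclass(frozen=True)
class Strategy:
    """A labelled, fully routed diagnostic strategy."""

    label: str
    combination: str
    histology_definition: int
    mpmri_definition: Optional[int]
    mpmri_cutoff: Optional[int]
    stages: Tuple[Stage, ...]

    def __post_init__(self) -> None:
        n_tests = len(self.stages)
        if not 1 <= n_tests <= 3:
            raise ValueError("a strategy administers between one and three tests per man")

    def context_for(self, stage: Stage, state: PathState) -> TestContext:
        if stage.test is TestKind.MPMRI:
            return TestContext(
                TestKind.MPMRI,
                mpmri_definition=self.mpmri_definition,
                mpmri_cutoff=self.mpmri_cutoff,
            )
        if stage.test is TestKind.TPMB:
            return TestContext(TestKind.TPMB, histology_definition=self.histology_definition)
        return TestContext(
            TestKind.TRUSB,
            trusb_type=resolve_trusb_type(state),
            histology_definition=self.histology_definition,
        )

    @property
    def uses_mpmri(self) -> bool:
        return any(s.test is TestKind.MPMRI for s in self.stages)

    def describe(self) -> str:
        parts = [f"{st.predicate.describe()} -> {st.test.value}" for st in self.stages]
        return f"{self.label}: " + "; ".join(parts)


# ---------------------------------------------------------------------------
# Combination grid

_SUSP = {"cs": (TestClass.CS,), "any": (TestClass.NON_CS, TestClass.CS)}
_BIOPSY_TRIGGER = {
    "nc": (TestClass.NC,),
    "noncs": (TestClass.NON_CS,),
    "not_cs": (TestClass.NC, TestClass.NON_CS),
}

# M/N combos: (first-biopsy suspicion trigger, re-biopsy trigger on the
# first biopsy result; None = no re-biopsy). Re-biopsy is restricted to
# men with a suspicion of CS cancer on the scan.
_M_GRID = {
    "1": ("cs", None),
    "2": ("any", None),
    "3": ("cs", "noncs"),
    "4": ("any", "noncs"),
    "5": ("cs", "nc"),
    "6": ("any", "nc"),
    "7": ("cs", "not_cs"),
}

# T/P combos: (repeat-TRUSB trigger, MPMRI trigger on the first biopsy
# result, second-biopsy suspicion trigger). Exactly one of the repeat /
# MPMRI routes is active per combo; T1 (and P-counterpart roles) use none.
_T_GRID = {
    "1": (None, None, None),
    "2": ("nc", None, None),
    "3": ("noncs", None, None),
    "4": ("not_cs", None, None),
    "5": (None, "nc", "cs"),
    "6": (None, "noncs", "cs"),
    "7": (None, "not_cs", "cs"),
    "8": (None, "nc", "any"),
    "9": (None, "not_cs", "any"),
}

COMBINATIONS: Tuple[str, ...] = tuple(
    [f"M{i}" for i in range(1, 8)]
    + [f"N{i}" for i in range(1, 8)]
    + [f"T{i}" for i in range(1, 10)]
    + [f"P{i}" for i in range(1, 10)]
)


def combination_uses_mpmri(combination: str) -> bool:
    family, digit = combination[0], combination[1:]
    if family in ("M", "N"):
        return True
    return _T_GRID[digit][1] is not None  # T5-T9 / P5-P9


def _build_stages(combination: str) -> Tuple[Stage, ...]:
    family, digit = combination[0], combination[1:]
    if family in ("M", "N"):
        first_trigger, rebiopsy = _M_GRID[digit]
        tpmb_last = family == "N"
        stages = [Stage(Always(), TestKind.MPMRI)]
        first_kind = TestKind.TPMB if (tpmb_last and rebiopsy is None) else TestKind.TRUSB
        stages.append(Stage(MpmriSuspicionIs(_SUSP[first_trigger]), first_kind))
        if rebiopsy is not None:
            pred = All(
                (
                    MpmriSuspicionIs(_SUSP["cs"]),
                    LastBiopsyResultIs(_BIOPSY_TRIGGER[rebiopsy]),
                )
            )
            stages.append(Stage(pred, TestKind.TPMB if tpmb_last else TestKind.TRUSB))
        return tuple(stages)

    # T / P families
    if combination == "P1":
        return (Stage(Always(), TestKind.TPMB),)
    repeat, mpmri_trigger, second = _T_GRID[digit]
    tpmb_last = family == "P"
    stages = [Stage(Always(), TestKind.TRUSB)]
    if repeat is not None:
        kind = TestKind.TPMB if tpmb_last else TestKind.TRUSB
        stages.append(Stage(LastBiopsyResultIs(_BIOPSY_TRIGGER[repeat]), kind))
    elif mpmri_trigger is not None:
        stages.append(Stage(LastBiopsyResultIs(_BIOPSY_TRIGGER[mpmri_trigger]), TestKind.MPMRI))
        pred = All(
            (
                MpmriSuspicionIs(_SUSP[second]),
                LastBiopsyResultIs(_BIOPSY_TRIGGER["not_cs"]),
            )
        )
        stages.append(Stage(pred, TestKind.TPMB if tpmb_last else TestKind.TRUSB))
    return tuple(stages)


def build_strategy(
    combination: str,
    histology_definition: int,
    mpmri_definition: Optional[int] = None,
    mpmri_cutoff: Optional[int] = None,
) -> Strategy:
    if combination not in COMBINATIONS:
        raise StrategyLabelError(f"unknown combination code {combination!r}")
    if histology_definition not in (1, 2):
        raise StrategyLabelError(f"histology definition must be 1 or 2, got {histology_definition}")
    if combination_uses_mpmri(combination):
        if mpmri_definition not in (1, 2):
            raise StrategyLabelError(
                f"{combination} uses MPMRI: mpmri_definition must be 1 or 2, got {mpmri_definition}"
            )
        if mpmri_cutoff not in (2, 3, 4, 5):
            raise StrategyLabelError(
                f"{combination} uses MPMRI: cut-off must be between 2 and 5, got {mpmri_cutoff}"
            )
        label = f"{combination} {histology_definition}{mpmri_definition}{mpmri_cutoff}"
    else:
        if mpmri_definition is not None or mpmri_cutoff is not None:
            raise StrategyLabelError(f"{combination} does not use MPMRI; no definition/cut-off allowed")
        label = f"{combination} {histology_definition}"
    return Strategy(
        label=label,
        combination=combination,
        histology_definition=histology_definition,
        mpmri_definition=mpmri_definition if combination_uses_mpmri(combination) else None,
        mpmri_cutoff=mpmri_cutoff if combination_uses_mpmri(combination) else None,
        stages=_build_stages(combination),
    )


def parse_strategy_label(label: str) -> Strategy:
    """Parse a label such as ``"M1 125"`` or ``"P4 2"`` into a Strategy."""
    parts = label.strip().split()
    if len(parts) != 2:
        raise StrategyLabelError(f"label {label!r} must be '<combination> <digits>'")
    combination, digits = parts
    if combination not in COMBINATIONS:
        raise StrategyLabelError(f"unknown combination code {combination!r}")
    if not digits.isdigit():
        raise StrategyLabelError(f"variant digits {digits!r} must be numeric")
    if combination_uses_mpmri(combination):
        if len(digits) != 3:
            raise StrategyLabelError(
                f"{combination} uses MPMRI and takes 3 digits (histology, definition, cut-off), got {digits!r}"
            )
        hdef, mdef, cutoff = (int(d) for d in digits)
        return build_strategy(combination, hdef, mdef, cutoff)
    if len(digits) != 1:
        raise StrategyLabelError(f"{combination} takes a single histology-definition digit, got {digits!r}")
    return build_strategy(combination, int(digits))


# ---------------------------------------------------------------------------
# Enumeration


@dataclass(frozen=True)
class EnumerationConfig:
    combinations: Sequence[str] = COMBINATIONS
    histology_definitions: Sequence[int] = (1, 2)
    mpmri_definitions: Sequence[int] = (1, 2)
    cutoffs: Sequence[int] = (2, 3, 4, 5)
    #: feasibility-pruning hooks: a strategy is dropped if any returns True
    exclusions: Sequence[Callable[[Strategy], bool]] = ()
    warn_on_count_mismatch: bool = True


def enumerate_strategies(config: EnumerationConfig | None = None) -> list[Strategy]:
    """Enumerate all labelled strategy variants in the configured grid.

    The default grid (two histology definitions, two MPMRI definitions,
    four cut-offs) yields 400 labelled variants over the 32 combinations;
    the originally reported total of 383 reflects unpublished feasibility
    pruning, so a mismatch is flagged with a warning rather than silently
    reconciled. Exclusion hooks allow callers to apply their own pruning.
    """
    config = config or EnumerationConfig()
    if not config.combinations:
        raise ValueError("no combinations to enumerate")
    if not config.histology_definitions:
        raise ValueError("empty histology-definition set")
    strategies: list[Strategy] = []
    for combination in config.combinations:
        if combination not in COMBINATIONS:
            raise StrategyLabelError(f"unknown combination code {combination!r}")
        if combination_uses_mpmri(combination):
            if not config.mpmri_definitions or not config.cutoffs:
                raise ValueError("empty MPMRI definition or cut-off set")
            for hdef in config.histology_definitions:
                for mdef in config.mpmri_definitions:
                    for cutoff in config.cutoffs:
                        strategies.append(build_strategy(combination, hdef, mdef, cutoff))
        else:
            for hdef in config.histology_definitions:
                strategies.append(build_strategy(combination, hdef))
    strategies = [s for s in strategies if not any(rule(s) for rule in config.exclusions)]
    labels = [s.label for s in strategies]
    if len(labels) != len(set(labels)):
        raise RuntimeError("duplicate strategy labels generated")
    if (
        config.warn_on_count_mismatch
        and set(config.combinations) == set(COMBINATIONS)
        and len(strategies) != REPORTED_PRUNED_TOTAL
    ):
        warnings.warn(
            f"enumerated {len(strategies)} strategy variants; the reference analysis reports "
            f"{REPORTED_PRUNED_TOTAL} after feasibility pruning whose rules are not public — "
            "supply EnumerationConfig.exclusions to prune",
            stacklevel=2,
        )
    return strategies


# ---------------------------------------------------------------------------
# Structural analysis


def _structural_paths(strategy: Strategy):
    """All structurally possible (state, path-of-tests) leaves of a strategy."""
    leaves = []

    def walk(stage_idx: int, state: PathState, tests: tuple):
        if stage_idx == len(strategy.stages):
            leaves.append((state, tests))
            return
        stage = strategy.stages[stage_idx]
        if not stage.predicate(state):
            walk(stage_idx + 1, state, tests)
            return
        ctx = strategy.context_for(stage, state)
        for result in TestClass:
            walk(stage_idx + 1, state.after(ctx, result), tests + (ctx.test,))

    walk(0, PathState(), ())
    return leaves


def undetected_terminate_in_tpmb(strategy: Strategy) -> bool:
    """True when every path without a CS diagnosis ends with a TPMB.

    For such strategies sensitivity is exactly 1 under any performance
    table in which TPMB is the perfect reference standard: a clinically
    significant cancer either yields a CS biopsy result along the way or
    reaches the terminal TPMB, which detects it with certainty.
    """
    for state, tests in _structural_paths(strategy):
        if state.diagnosis is not Diagnosis.CS_DX:
            if not tests or tests[-1] is not TestKind.TPMB:
                return False
    return True
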