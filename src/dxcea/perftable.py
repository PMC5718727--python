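"""Subgroup-conditional test-performance tables.

A :class:`TestPerformanceTable` maps ``(TestContext, Subgroup)`` to a
probability vector over the three test classes (NC, non-CS, CS). The
packaged tables transcribe the published point estimates for the five
TRUSB contexts (by histology definition) and for MPMRI (by radiological
definition and Likert cut-off). Structural rows are added on load:

* biopsies in cancer-free men always return NC (a biopsy cannot detect
  cancer that is absent), and
* TPMB maps truth to class exactly (reference standard): no cancer -> NC,
  low-risk -> non-CS, intermediate/high-risk -> CS.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

from .core import SUBGROUPS, Subgroup, TestClass, TestContext, TestKind

Row = np.ndarray  # length-3 probability vector indexed by TestClass

#: Verbatim transcriptions of published point estimates may carry 2-dp
#: rounding error; rows off by at most this much are renormalised on load.
_ROUNDING_SLACK = 0.02

_TPMB_TRUTH_CLASS = {
    Subgroup.NO_CANCER: TestClass.NC,
    Subgroup.LOW_RISK: TestClass.NON_CS,
    Subgroup.INTERMEDIATE_RISK: TestClass.CS,
    Subgroup.HIGH_RISK: TestClass.CS,
}


class TestPerformanceTable:
    """Mapping (TestContext, Subgroup) -> P(result class)."""

    def __init__(self, entries: Mapping[Tuple[TestContext, Subgroup], Iterable[float]]):
        self.entries: Dict[Tuple[TestContext, Subgroup], Row] = {}
        for key, row in entries.items():
            ctx, subgroup = key
            vec = np.asarray(list(row), dtype=float)
            if vec.shape != (3,):
                raise ValueError(f"row for {key} must have 3 entries")
            if (vec < -1e-12).any() or (vec > 1 + 1e-12).any():
                raise ValueError(f"row for {key} has entries outside [0,1]: {vec}")
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"row for {key} does not sum to 1: {vec} (sum {vec.sum()})")
            self.entries[(ctx, subgroup)] = np.clip(vec, 0.0, 1.0)
        self._validate_structure()

    def _validate_structure(self) -> None:
        for (ctx, subgroup), row in self.entries.items():
            if ctx.test.is_biopsy and subgroup is Subgroup.NO_CANCER:
                if not (row[0] == 1.0 and row[1] == 0.0 and row[2] == 0.0):
                    raise ValueError(
                        f"biopsy row for cancer-free men must be (1,0,0), got {row} for {ctx}"
                    )
            if ctx.test is TestKind.TPMB:
                expected = np.zeros(3)
                expected[_TPMB_TRUTH_CLASS[subgroup]] = 1.0
                if not np.array_equal(row, expected):
                    raise ValueError(f"TPMB row for {subgroup.value} must be identity, got {row}")

    def row(self, ctx: TestContext, subgroup: Subgroup) -> Row:
        try:
            return self.entries[(ctx, subgroup)]
        except KeyError:
            raise KeyError(f"no performance row for {ctx} / {subgroup}") from None

    def prob(self, ctx: TestContext, subgroup: Subgroup, result: TestClass) -> float:
        return float(self.row(ctx, subgroup)[result])

    def contexts(self) -> set:
        return {ctx for ctx, _ in self.entries}

    def copy_with(self, replacements: Mapping[Tuple[TestContext, Subgroup], Iterable[float]]) -> "TestPerformanceTable":
        entries = {k: v.copy() for k, v in self.entries.items()}
        entries.update({k: np.asarray(list(v), float) for k, v in replacements.items()})
        return TestPerformanceTable(entries)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for (ctx, subgroup), row in sorted(
            self.entries.items(),
            key=lambda kv: (
                kv[0][0].test.value,
                kv[0][0].trusb_type or 0,
                kv[0][0].mpmri_cutoff or 0,
                kv[0][0].mpmri_definition or 0,
                kv[0][0].histology_definition or 0,
                kv[0][1].value,
            ),
        ):
            records.append(
                {
                    "test": ctx.test.value,
                    "trusb_type": ctx.trusb_type,
                    "mpmri_definition": ctx.mpmri_definition,
                    "mpmri_cutoff": ctx.mpmri_cutoff,
                    "histology_definition": ctx.histology_definition,
                    "subgroup": subgroup.value,
                    "p_nc": row[0],
                    "p_noncs": row[1],
                    "p_cs": row[2],
                }
            )
        return pd.DataFrame.from_records(records)


def _clean_row(vec: np.ndarray, label: str) -> np.ndarray:
    total = vec.sum()
    if abs(total - 1.0) <= 1e-9:
        return vec
    if abs(total - 1.0) <= _ROUNDING_SLACK:
        warnings.warn(
            f"performance row {label} sums to {total:.4f}; renormalising "
            "(2-dp rounding in the transcribed point estimates)",
            stacklevel=3,
        )
        return vec / total
    raise ValueError(f"performance row {label} sums to {total}, outside rounding slack")


def tpmb_rows(histology_definitions: Iterable[int] = (1, 2)) -> Dict[Tuple[TestContext, Subgroup], np.ndarray]:
    """Reference-standard rows: TPMB classifies truth exactly."""
    rows = {}
    for hdef in histology_definitions:
        ctx = TestContext(TestKind.TPMB, histology_definition=hdef)
        for subgroup in SUBGROUPS:
            vec = np.zeros(3)
            vec[_TPMB_TRUTH_CLASS[subgroup]] = 1.0
            rows[(ctx, subgroup)] = vec
    return rows


def load_packaged_tables() -> TestPerformanceTable:
    """Load the packaged TRUSB and MPMRI point-estimate tables.

    Returns a single table covering TRUSB types 1-5 (histology definitions
    1-2), MPMRI definitions 1-2 at cut-offs >=2, >=3, >=4 and =5, and the
    TPMB reference standard, with the structural cancer-free biopsy rows
    filled in.
    """
    entries: Dict[Tuple[TestContext, Subgroup], np.ndarray] = {}

    data = resources.files("dxcea").joinpath("data")
    trusb = pd.read_csv(str(data.joinpath("trusb_performance.csv")))
    for rec in trusb.itertuples(index=False):
        ctx = TestContext(
            TestKind.TRUSB,
            trusb_type=int(rec.trusb_type),
            histology_definition=int(rec.histology_definition),
        )
        vec = np.array([rec.p_nc, rec.p_noncs, rec.p_cs], dtype=float)
        label = f"TRUSB type {rec.trusb_type} def {rec.histology_definition} {rec.subgroup}"
        entries[(ctx, Subgroup(rec.subgroup))] = _clean_row(vec, label)
    # a biopsy cannot detect cancer in cancer-free men
    for (ctx, _sg) in list(entries):
        entries[(ctx, Subgroup.NO_CANCER)] = np.array([1.0, 0.0, 0.0])

    mpmri = pd.read_csv(str(data.joinpath("mpmri_performance.csv")))
    for rec in mpmri.itertuples(index=False):
        ctx = TestContext(
            TestKind.MPMRI,
            mpmri_definition=int(rec.mpmri_definition),
            mpmri_cutoff=int(rec.mpmri_cutoff),
        )
        vec = np.array([rec.p_nc, rec.p_noncs, rec.p_cs], dtype=float)
        label = f"MPMRI cutoff {rec.mpmri_cutoff} def {rec.mpmri_definition} {rec.subgroup}"
        entries[(ctx, Subgroup(rec.subgroup))] = _clean_row(vec, label)

    entries.update(tpmb_rows())
    return TestPerformanceTable(entries)
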