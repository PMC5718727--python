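"""Core domain types for the diagnostic pathway model.

The model classifies each man's true disease status into four subgroups
(no cancer, low-risk, intermediate-risk, high-risk); intermediate- and
high-risk disease jointly constitute clinically significant (CS) cancer.
Each test classifies a man as NC (no cancer / no suspicion), non-CS, or
CS; for MPMRI these are suspicion levels after applying a Likert cut-off,
for biopsies they are histological results.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping


class Subgroup(enum.Enum):
    """True disease status, defined against the TPMB reference standard."""

    NO_CANCER = "no_cancer"
    LOW_RISK = "low_risk"
    INTERMEDIATE_RISK = "intermediate_risk"
    HIGH_RISK = "high_risk"

    @property
    def has_cancer(self) -> bool:
        return self is not Subgroup.NO_CANCER

    @property
    def is_cs(self) -> bool:
        """Clinically significant cancer (intermediate- or high-risk)."""
        return self in (Subgroup.INTERMEDIATE_RISK, Subgroup.HIGH_RISK)


SUBGROUPS = tuple(Subgroup)
CS_SUBGROUPS = (Subgroup.INTERMEDIATE_RISK, Subgroup.HIGH_RISK)


class TestClass(enum.IntEnum):
    """Result of a single test, ordered by severity."""

    NC = 0
    NON_CS = 1
    CS = 2


TEST_CLASSES = tuple(TestClass)


class TestKind(enum.Enum):
    MPMRI = "mpmri"
    TRUSB = "trusb"
    TPMB = "tpmb"

    @property
    def is_biopsy(self) -> bool:
        return self is not TestKind.MPMRI


class Diagnosis(enum.Enum):
    """Final diagnosis at the end of a man's pathway.

    A CS diagnosis requires a biopsy result of CS; MPMRI suspicion alone
    never yields a cancer diagnosis.
    """

    NO_CANCER_DX = "no_cancer_dx"
    NON_CS_DX = "noncs_dx"
    CS_DX = "cs_dx"


DIAGNOSES = tuple(Diagnosis)

#: Diagnosis implied by the most severe biopsy result on a path.
DIAGNOSIS_BY_SEVERITY = {
    TestClass.NC: Diagnosis.NO_CANCER_DX,
    TestClass.NON_CS: Diagnosis.NON_CS_DX,
    TestClass.CS: Diagnosis.CS_DX,
}


@dataclass(frozen=True)
class TestContext:
    """A test together with the information that selects its performance row.

    ``trusb_type`` follows the five TRUSB contexts: 1 first TRUSB before
    any MPMRI; 2 repeat after a TRUSB that found no cancer; 3 repeat after
    a TRUSB that found non-CS cancer; 4 first TRUSB after a suspicious
    MPMRI (MRI-targeted); 5 TRUSB after a non-CS-detecting TRUSB and a
    suspicious MPMRI.
    """

    test: TestKind
    trusb_type: int | None = None
    mpmri_definition: int | None = None
    mpmri_cutoff: int | None = None
    histology_definition: int | None = None

    def __post_init__(self) -> None:
        if self.test is TestKind.TRUSB:
            if self.trusb_type not in (1, 2, 3, 4, 5):
                raise ValueError(f"TRUSB context needs trusb_type 1-5, got {self.trusb_type}")
            if self.histology_definition not in (1, 2):
                raise ValueError("TRUSB context needs histology_definition 1 or 2")
            if self.mpmri_definition is not None or self.mpmri_cutoff is not None:
                raise ValueError("MPMRI fields not allowed on a TRUSB context")
        elif self.test is TestKind.MPMRI:
            if self.mpmri_definition not in (1, 2):
                raise ValueError("MPMRI context needs mpmri_definition 1 or 2")
            if self.mpmri_cutoff not in (2, 3, 4, 5):
                raise ValueError(f"MPMRI cut-off must be 2-5, got {self.mpmri_cutoff}")
            if self.trusb_type is not None or self.histology_definition is not None:
                raise ValueError("biopsy fields not allowed on an MPMRI context")
        else:  # TPMB
            if self.histology_definition not in (1, 2):
                raise ValueError("TPMB context needs histology_definition 1 or 2")
            if self.trusb_type is not None or self.mpmri_definition is not None or self.mpmri_cutoff is not None:
                raise ValueError("only histology_definition allowed on a TPMB context")


@dataclass(frozen=True)
class SubgroupPrevalence:
    """Prevalence of the four true-status subgroups among men referred."""

    probabilities: Mapping[Subgroup, float]

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        missing = set(SUBGROUPS) - set(probs)
        if missing:
            raise ValueError(f"prevalence missing subgroups: {sorted(s.value for s in missing)}")
        for s, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {s.value} outside [0,1]: {p}")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError(f"prevalence does not sum to 1: {sum(probs.values())}")
        object.__setattr__(self, "probabilities", probs)

    def __getitem__(self, s: Subgroup) -> float:
        return self.probabilities[s]

    @property
    def cs_prevalence(self) -> float:
        return sum(self.probabilities[s] for s in CS_SUBGROUPS)
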