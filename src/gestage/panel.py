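"""Newborn-screening analyte panel definition.

The default panel mirrors a typical tandem-MS newborn-screening run: 12
amino acids, 31 acylcarnitines, two endocrine markers (TSH, 17-OHP),
immunoreactive trypsinogen, and the fetal/adult hemoglobin ratio derived
from HPLC hemoglobin fractions -- 47 quantities in total.  The exact panel
is configurable; nothing downstream hard-codes these names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = (
    "ALA", "ARG", "ASA", "CIT", "GLY", "LEU", "MET",
    "ORN", "PHE", "PRO", "TYR", "VAL",
)

ACYLCARNITINES = (
    "C0", "C2", "C3", "C4", "C4DC", "C5", "C5:1", "C5DC", "C5OH",
    "C6", "C6DC", "C8", "C8:1", "C10", "C10:1", "C10:2",
    "C12", "C12:1", "C14", "C14:1", "C14:2", "C14OH",
    "C16", "C16:1", "C16OH", "C16:1OH",
    "C18", "C18:1", "C18:2", "C18OH", "C18:1OH",
)

ENDOCRINE = ("TSH", "OHP17")
HEMOGLOBIN = ("HBFA_RATIO",)  # fetal/adult hemoglobin ratio
OTHER = ("IRT",)

#: Analytes the source models identified as the strongest individual
#: predictors of gestational age (plus birthweight on the clinical side).
STRONG_PREDICTORS = ("ALA", "C4DC", "C5", "HBFA_RATIO", "OHP17", "TSH", "TYR")

GROUPS = ("amino_acid", "acylcarnitine", "endocrine", "enzyme", "hemoglobin", "other")


@dataclass(frozen=True)
class AnalytePanel:
    """Ordered collection of analyte names with a group label per name."""

    names: tuple[str, ...]
    groups: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("analyte names must be unique")
        missing = [n for n in self.names if n not in self.groups]
        if missing:
            raise ValueError(f"no group assigned for analytes: {missing}")
        bad = {g for g in self.groups.values()} - set(GROUPS)
        if bad:
            raise ValueError(f"unknown analyte groups: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def group(self, name: str) -> str:
        return self.groups[name]


def default_panel() -> AnalytePanel:
    """The 47-analyte default panel."""
    groups: dict[str, str] = {}
    groups.update({a: "amino_acid" for a in AMINO_ACIDS})
    groups.update({a: "acylcarnitine" for a in ACYLCARNITINES})
    groups.update({a: "endocrine" for a in ENDOCRINE})
    groups.update({a: "hemoglobin" for a in HEMOGLOBIN})
    groups.update({a: "other" for a in OTHER})
    names = AMINO_ACIDS + ACYLCARNITINES + ENDOCRINE + HEMOGLOBIN + OTHER
    assert len(names) == 47
    return AnalytePanel(names=names, groups=groups)
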