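"""Error flag vocabulary shared by the detectors and the glycan graph."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = ["ErrorCategory", "ErrorFlag"]


class ErrorCategory(str, Enum):
    """The six stereochemical error classes detected per sugar unit."""

    CHIRALITY = "CHIRALITY"
    DOUBLE_BOND = "DOUBLE_BOND"
    PLANAR_RING = "PLANAR_RING"
    AROMATIC_RING = "AROMATIC_RING"
    IMPROPER = "IMPROPER"
    MISSING_ATOM = "MISSING_ATOM"


#: Fixed reporting order of the categories.
CATEGORY_ORDER = tuple(ErrorCategory)


@dataclass(frozen=True)
class ErrorFlag:
    """One detected violation.

    ``magnitude`` is category-specific: |V| of the offending chiral volume
    (CHIRALITY), observed bond length in Angstrom (DOUBLE_BOND), puckering
    amplitude Q in Angstrom (PLANAR_RING / AROMATIC_RING), worst deviation
    (IMPROPER), and 0 for MISSING_ATOM.
    """

    category: ErrorCategory
    unit_id: str
    ccd_code: str
    atoms: tuple[str, ...]
    magnitude: float
    detail: str = ""

    def to_dict(self) -> dict:
        return {
            "category": self.category.value,
            "unit": self.unit_id,
            "ccd_code": self.ccd_code,
            "atoms": list(self.atoms),
            "magnitude": round(self.magnitude, 4),
            "detail": self.detail,
        }
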