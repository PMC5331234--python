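"""Closed-form assay computations.

Small, exact formulas used around the sequencing analysis: relative gene
expression by the ddCt method (ideal amplification efficiency of 2),
TTC-section infarct mass, and percent-positive cell tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class QPCRMeasurement:
    """Cycle thresholds for one sample: target gene and reference gene.

    The reference gene is a housekeeping control (e.g. HPRT or U6); the
    method is agnostic to which.
    """

    sample_id: str
    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        if self.target_ct <= 0 or self.reference_ct <= 0:
            raise ValueError("Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


@dataclass(frozen=True)
class InfarctMeasurement:
    """One TTC-stained heart section: infarct and LV areas plus weight (mg)."""

    infarct_area: float
    lv_area: float
    section_weight: float

    def __post_init__(self) -> None:
        if not (0 <= self.infarct_area <= self.lv_area):
            raise ValueError("need 0 <= infarct_area <= lv_area")
        if self.section_weight < 0:
            raise ValueError("section weight must be non-negative")


def relative_expression_ddct(
    test: QPCRMeasurement, control: QPCRMeasurement
) -> float:
    """Fold change 2^(-ddCt) of test vs control.

    dCt = target Ct - reference Ct per sample; ddCt = dCt_test - dCt_control.
    One fewer cycle to threshold means a doubling of starting template.
    """
    ddct = test.delta_ct - control.delta_ct
    return 2.0 ** (-ddct)


def infarct_mass(sections: Sequence[InfarctMeasurement]) -> float:
    """Total infarct mass: sum over sections of (infarct/LV area) x weight."""
    total = 0.0
    for i, sec in enumerate(sections):
        if sec.lv_area == 0:
            raise ValueError(f"section {i}: LV area must be positive")
        total += (sec.infarct_area / sec.lv_area) * sec.section_weight
    return total


def percent_positive(positive: int, total: int) -> float:
    """Percentage of marker-positive cells in a counted field."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= positive <= total):
        raise ValueError("need 0 <= positive <= total")
    return 100.0 * positive / total
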