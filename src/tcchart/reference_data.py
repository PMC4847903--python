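"""Published worked-example inputs: cell-line chamber counts and biopsy cases.

These are the printed per-sample measurements that accompany the method
(cell-line digital PCR and DISH counts, and the eleven representative
gastric-cancer biopsy cases), carried as plain constants so examples,
tests and the reproduction script can run them through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dish_ihc import DishCount, IhcScore
from .dpcr_quant import PanelCount

__all__ = ["CellLine", "BiopsyCase", "CELL_LINES", "BIOPSY_CASES"]


@dataclass(frozen=True)
class CellLine:
    """Cell-line control: dPCR chamber counts and DISH counts over 20 cells."""

    name: str
    dpcr_target: PanelCount    # HER2 assay
    dpcr_reference: PanelCount  # CEP17 assay
    dish: DishCount


#: LCL is the diploid lymphoblastoid control; H522 carries a modest HER2
#: gain; SK-BR-3 is highly amplified (clustered DISH signals undercount B).
CELL_LINES = {
    "LCL": CellLine("LCL", PanelCount(383, 770), PanelCount(398, 770),
                    DishCount(40, 40, 20)),
    "H522": CellLine("H522", PanelCount(513, 770), PanelCount(310, 770),
                     DishCount(85, 41, 20)),
    "SK-BR-3": CellLine("SK-BR-3", PanelCount(639, 770), PanelCount(206, 770),
                        DishCount(381, 83, 20)),
}


@dataclass(frozen=True)
class BiopsyCase:
    """One representative biopsy: measured (r, x), DISH counts, IHC score."""

    case: str
    x: float
    r: float
    area: str  # published TC-chart call
    ihc: IhcScore
    dish: DishCount


BIOPSY_CASES = [
    BiopsyCase("#1", 0.341, 1.39, "EQUIVOCAL", IhcScore.EQUIVOCAL, DishCount(261, 57)),
    BiopsyCase("#44", 0.264, 1.49, "EQUIVOCAL", IhcScore.POSITIVE, DishCount(158, 60)),
    BiopsyCase("#8", 0.087, 1.10, "EQUIVOCAL", IhcScore.EQUIVOCAL, DishCount(106, 79)),
    BiopsyCase("#15", 0.330, 1.36, "EQUIVOCAL", IhcScore.WEAK, DishCount(102, 55)),
    BiopsyCase("#32", 0.297, 1.35, "EQUIVOCAL", IhcScore.EQUIVOCAL, DishCount(64, 52)),
    BiopsyCase("#41", 0.305, 1.55, "EQUIVOCAL", IhcScore.EQUIVOCAL, DishCount(132, 87)),
    BiopsyCase("#33", 0.531, 1.95, "POSITIVE", IhcScore.EQUIVOCAL, DishCount(65, 62)),
    BiopsyCase("#29", 0.517, 2.38, "POSITIVE", IhcScore.EQUIVOCAL, DishCount(111, 48)),
    BiopsyCase("#25", 0.414, 28.25, "POSITIVE", IhcScore.POSITIVE, DishCount(420, 64)),
    BiopsyCase("#26", 0.390, 19.99, "POSITIVE", IhcScore.POSITIVE, DishCount(420, 63)),
    BiopsyCase("#42", 0.283, 24.00, "POSITIVE", IhcScore.POSITIVE, DishCount(420, 59)),
]
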