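"""Dual-probe in situ hybridization (DISH) scoring and IHC concordance.

DISH counts HER2 and CEP17 signals over a fixed set of scored cancer
nuclei (20 by convention).  The derived metrics are the HER2/CEP17 signal
ratio and the per-cell averages; the CEP17 average is the measured A that
feeds the TC-chart inversion.  Classification follows the ASCO/CAP
dual-probe rules: positive when ratio >= 2.0 and/or average HER2 >= 6.0
signals/cell; equivocal when the average is in [4.0, 6.0); negative
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .errors import UndefinedRatioError, ValidationError
from .tc_chart import TCClassification, TCLabel

__all__ = [
    "DishCount",
    "DishMetrics",
    "IhcScore",
    "DishLabel",
    "dish_metrics",
    "classify_dish",
    "cluster_adjusted_signals",
    "concordance_table",
]

#: ASCO/CAP dual-probe thresholds (ratio; HER2 signals/cell).
RATIO_POSITIVE = 2.0
AVG_HER2_POSITIVE = 6.0
AVG_HER2_EQUIVOCAL = 4.0

#: Cap applied to an uncountable HER2 cluster, by its size class.
CLUSTER_CAPS = {"small": 7, "medium": 14, "large": 21}


@dataclass(frozen=True)
class DishCount:
    """Total HER2/CEP17 signal counts over n scored cancer nuclei."""

    her2_signals: int
    cep17_signals: int
    n_cells: int = 20

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.her2_signals < 0 or self.cep17_signals < 0:
            raise ValidationError("signal counts must be non-negative")


@dataclass(frozen=True)
class DishMetrics:
    """HER2/CEP17 ratio and per-cell averages; avg_cep17 is the measured A."""

    ratio: float
    avg_her2: float
    avg_cep17: float


class IhcScore(str, Enum):
    """Dako four-level membrane-staining score."""

    NONE = "0"
    WEAK = "1+"
    EQUIVOCAL = "2+"
    POSITIVE = "3+"

    @classmethod
    def parse(cls, text: str | int) -> "IhcScore":
        s = str(text).strip()
        for member in cls:
            if member.value == s:
                return member
        raise ValidationError(f"IHC score must be one of 0/1+/2+/3+, got {text!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class DishLabel(str, Enum):
    POSITIVE = "POSITIVE"
    EQUIVOCAL = "EQUIVOCAL"
    NEGATIVE = "NEGATIVE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def dish_metrics(count: DishCount) -> DishMetrics:
    """Signal ratio and per-cell averages; full precision, no rounding."""
    if count.cep17_signals == 0:
        raise UndefinedRatioError("CEP17 signal count is zero; ratio undefined")
    return DishMetrics(
        ratio=count.her2_signals / count.cep17_signals,
        avg_her2=count.her2_signals / count.n_cells,
        avg_cep17=count.cep17_signals / count.n_cells,
    )


def classify_dish(metrics: DishMetrics) -> DishLabel:
    """ASCO/CAP dual-probe call; 'and/or' is an inclusive or."""
    if metrics.ratio >= RATIO_POSITIVE or metrics.avg_her2 >= AVG_HER2_POSITIVE:
        return DishLabel.POSITIVE
    if AVG_HER2_EQUIVOCAL <= metrics.avg_her2 < AVG_HER2_POSITIVE:
        return DishLabel.EQUIVOCAL
    return DishLabel.NEGATIVE


def cluster_adjusted_signals(
    per_nucleus: Sequence[tuple[int, str | None]],
) -> int:
    """Total HER2 signals with uncountable clusters capped by size class.

    Each entry is (discrete_dots, cluster_size_class) where the class is
    one of 'small'/'medium'/'large' (adding 7/14/21 signals) or None for
    a nucleus with discrete dots only.
    """
    total = 0
    for dots, size_class in per_nucleus:
        if dots < 0:
            raise ValidationError(f"discrete dot count must be >= 0, got {dots}")
        total += dots
        if size_class is not None:
            try:
                total += CLUSTER_CAPS[size_class]
            except KeyError:
                raise ValidationError(
                    f"cluster size class must be one of {sorted(CLUSTER_CAPS)}, "
                    f"got {size_class!r}"
                ) from None
    return total


def concordance_table(
    ihc: Sequence[IhcScore],
    tc: Sequence[TCClassification | TCLabel],
    dish: Sequence[DishLabel] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate IHC (and optionally DISH) rows against TC-chart areas.

    Returns a DataFrame whose rows are the IHC levels (plus DISH levels
    when given, below them) and whose columns are the chart areas; cell
    sums per block equal the number of samples.
    """
    if len(ihc) != len(tc) or (dish is not None and len(dish) != len(ihc)):
        raise ValidationError("ihc, tc (and dish) lists must have equal length")
    tc_labels = [t.label if isinstance(t, TCClassification) else t for t in tc]
    areas = [l.value for l in TCLabel]
    table = pd.DataFrame(
        0, index=[s.value for s in IhcScore], columns=areas, dtype=int
    )
    for score, area in zip(ihc, tc_labels):
        table.loc[score.value, area.value] += 1
    if dish is not None:
        dish_tab = pd.DataFrame(
            0, index=[s.value for s in DishLabel], columns=areas, dtype=int
        )
        for label, area in zip(dish, tc_labels):
            dish_tab.loc[label.value, area.value] += 1
        table = pd.concat([table, dish_tab], keys=["IHC", "DISH"])
    return table
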