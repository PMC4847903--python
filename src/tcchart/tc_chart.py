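"""The tumor-content (TC) chart: mixture model, boundaries, classification.

A bulk specimen is a mixture of cancer cells (fraction ``x``, the tumor
content ratio) carrying ``A`` CEP17 and ``B`` HER2 copies per cell, and
diploid stroma (2 copies of each locus).  The bulk HER2/CEP17 ratio is

    r = (B x + 2 (1 - x)) / (A x + 2 (1 - x))

Amplification is defined per-cell as B/A >= 2.  The iso-curve of B/A = 2
at CEP17 copy number A,

    r(x; A) = 2 - 2 (1 - x) / ((A - 2) x + 2),

is increasing in A, so with A constrained to [a_min, a_max] (clinically
2..8) the curve at a_min is a sufficient condition for non-amplification
(r below it => B/A < 2 for every admissible A) and the curve at a_max a
sufficient condition for amplification.  Points between the two curves
are equivocal: the call depends on the unknown A.  All curves pass
through (0, 1) (pure stroma) and (1, 2) (pure tumor at B/A = 2).

Knowing A (e.g. from DISH CEP17 counts) the model inverts in closed form:

    B/A = r + 2 (r - 1) (1 - x) / (A x)

and at the pure-tumor convention x = 1 the per-cell HER2 copy number is
B' = r * A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import DomainError, UndefinedRatioError, ValidationError

__all__ = [
    "SamplePoint",
    "TumorCellParams",
    "TCChartConfig",
    "TCLabel",
    "TCClassification",
    "forward_ratio",
    "boundary_ratio",
    "classify",
    "estimate_ba_ratio",
    "estimate_b_prime",
    "chart_curves",
    "ChartCurves",
]

#: Copies of each locus per non-cancerous (diploid) cell; the boundary
#: derivations hard-code this value.
NORMAL_COPY = 2.0


@dataclass(frozen=True)
class SamplePoint:
    """Coordinates of one specimen on the TC chart: ratio r, tumor content x."""

    r: float
    x: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValidationError(f"ratio r must be positive, got {self.r}")
        if not 0.0 <= self.x <= 1.0:
            raise ValidationError(f"tumor content x must be in [0, 1], got {self.x}")


@dataclass(frozen=True)
class TumorCellParams:
    """Per-cancer-cell copy numbers: A for CEP17, B for HER2."""

    A: float
    B: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValidationError("copy numbers A and B must be non-negative")

    @property
    def ba_ratio(self) -> float:
        return self.B / self.A


@dataclass(frozen=True)
class TCChartConfig:
    """Chart geometry: the admissible CEP17 range and the low-x guard.

    ``a_min``/``a_max`` bound the per-cell CEP17 copy number assumed
    possible in tumors (defaults 2 and 8, the clinical range with a
    safety margin).  Below ``x_floor`` the equivocal band collapses
    toward the stroma point (0, 1) and calls are refused.
    """

    a_min: float = 2.0
    a_max: float = 8.0
    x_floor: float = 0.05

    def __post_init__(self) -> None:
        if not 2.0 <= self.a_min < self.a_max:
            raise ValidationError(
                f"need 2 <= a_min < a_max, got a_min={self.a_min}, a_max={self.a_max}"
            )
        if not 0.0 <= self.x_floor < 1.0:
            raise ValidationError(f"x_floor must be in [0, 1), got {self.x_floor}")


class TCLabel(str, Enum):
    POSITIVE = "POSITIVE"
    EQUIVOCAL = "EQUIVOCAL"
    NEGATIVE = "NEGATIVE"
    UNDETERMINED = "UNDETERMINED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TCClassification:
    """A chart call plus the two boundary values evaluated at the sample's x."""

    label: TCLabel
    negative_boundary: float
    positive_boundary: float
    point: SamplePoint


def forward_ratio(params: TumorCellParams, x: float) -> float:
    """Bulk HER2/CEP17 ratio of a tumor/stroma mixture at tumor content x."""
    if not 0.0 <= x <= 1.0:
        raise ValidationError(f"tumor content x must be in [0, 1], got {x}")
    denom = params.A * x + NORMAL_COPY * (1.0 - x)
    if denom <= 0.0:
        raise UndefinedRatioError(
            f"mixture CEP17 content is zero at x={x} with A={params.A}"
        )
    return (params.B * x + NORMAL_COPY * (1.0 - x)) / denom


def boundary_ratio(x: float, A: float) -> float:
    """The B/A = 2 iso-curve r(x; A) = 2 - 2(1-x)/((A-2)x + 2).

    Reduces to ``x + 1`` at A = 2 and to ``(7x+1)/(3x+1)`` at A = 8.
    Only defined for A >= 2 (the derivation's range).
    """
    if A < 2.0:
        raise DomainError(f"boundary is derived for A >= 2, got A={A}")
    if not 0.0 <= x <= 1.0:
        raise ValidationError(f"tumor content x must be in [0, 1], got {x}")
    return 2.0 - 2.0 * (1.0 - x) / ((A - 2.0) * x + 2.0)


def classify(point: SamplePoint, config: TCChartConfig | None = None) -> TCClassification:
    """Three-way amplification call for a (r, x) point.

    NEGATIVE iff r < r(x; a_min); POSITIVE iff r >= r(x; a_max);
    EQUIVOCAL in the half-open band between them.  When x < x_floor the
    band has collapsed and UNDETERMINED is returned with a warning.
    """
    config = config or TCChartConfig()
    lo = boundary_ratio(point.x, config.a_min)
    hi = boundary_ratio(point.x, config.a_max)
    if point.x < config.x_floor:
        warnings.warn(
            f"tumor content x={point.x:.3f} below floor {config.x_floor}: "
            "boundaries collapse toward (0, 1); call withheld",
            stacklevel=2,
        )
        return TCClassification(TCLabel.UNDETERMINED, lo, hi, point)
    if point.r < lo:
        label = TCLabel.NEGATIVE
    elif point.r >= hi:
        label = TCLabel.POSITIVE
    else:
        label = TCLabel.EQUIVOCAL
    return TCClassification(label, lo, hi, point)


def estimate_ba_ratio(point: SamplePoint, A: float) -> float:
    """Closed-form B/A from a measured (r, x) and a known CEP17 copy number A.

    Exact algebraic inverse of :func:`forward_ratio`:
    B/A = r + 2 (r - 1) (1 - x) / (A x).
    """
    if point.x <= 0.0:
        raise UndefinedRatioError("cannot invert at x = 0: no tumor signal")
    if A <= 0.0:
        raise ValidationError(f"CEP17 copy number A must be positive, got {A}")
    r, x = point.r, point.x
    return r + NORMAL_COPY * (r - 1.0) * (1.0 - x) / (A * x)


def estimate_b_prime(r: float, A: float) -> float:
    """Per-cell HER2 copy number under the pure-tumor convention: B' = r * A."""
    if r <= 0.0:
        raise ValidationError(f"ratio r must be positive, got {r}")
    if A <= 0.0:
        raise ValidationError(f"CEP17 copy number A must be positive, got {A}")
    return r * A


@dataclass(frozen=True)
class ChartCurves:
    """Sampled boundary polylines for rendering or tabular export."""

    x: np.ndarray
    curves: dict[str, np.ndarray]
    negative_boundary: np.ndarray
    positive_boundary: np.ndarray

    def to_table(self):
        """Long-format (x, r, curve_label) DataFrame."""
        import pandas as pd

        frames = []
        named = dict(self.curves)
        named.setdefault("negative_boundary", self.negative_boundary)
        named.setdefault("positive_boundary", self.positive_boundary)
        for label, r in named.items():
            frames.append(pd.DataFrame({"x": self.x, "r": r, "curve_label": label}))
        return pd.concat(frames, ignore_index=True)


def chart_curves(
    config: TCChartConfig | None = None,
    a_values: Sequence[float] = (),
    n_points: int = 101,
) -> ChartCurves:
    """Sample the B/A = 2 iso-curves plus the two decision boundaries."""
    config = config or TCChartConfig()
    if n_points < 2:
        raise ValidationError(f"n_points must be >= 2, got {n_points}")
    for a in a_values:
        if a < 2.0:
            raise DomainError(f"curve requested at A={a} < 2")
    x = np.linspace(0.0, 1.0, n_points)
    vec = np.vectorize(boundary_ratio)
    curves = {f"A={a:g}": vec(x, a) for a in a_values}
    return ChartCurves(
        x=x,
        curves=curves,
        negative_boundary=vec(x, config.a_min),
        positive_boundary=vec(x, config.a_max),
    )
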