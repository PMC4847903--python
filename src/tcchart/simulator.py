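"""Seeded synthetic digital-PCR data from a known tumor/stroma truth.

The generator fixes a ground truth (per-cell copy numbers A and B,
tumor content x, mean genome equivalents per chamber m) and samples
chamber counts under the standard occupancy model: molecules per chamber
are Poisson with mean

    lam_reference = m (A x + 2 (1 - x)),   lam_target = m (B x + 2 (1 - x)),

a chamber is positive iff it holds at least one molecule, and chambers
are independent — so positive counts are Binomial(N, 1 - exp(-lam)).
The expected-lambda ratio is exactly the mixture forward ratio, which
makes every upstream estimator testable against known truth.

Also covered: the stepwise DNA-mixing design (a dilution series of a
tumor line into a diploid lymphoblastoid line) and least-squares
recovery of the per-cell HER2 copy number B from such a series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dpcr_quant import DEFAULT_TOTAL_CHAMBERS, PanelCount
from .errors import ValidationError
from .tc_chart import NORMAL_COPY, TumorCellParams, forward_ratio

__all__ = [
    "SimulationConfig",
    "MixtureStep",
    "expected_lambdas",
    "simulate_panel",
    "mixture_series",
    "fit_b_prime_series",
    "PAPER_MIXING_FRACTIONS",
]

#: Tumor-line DNA fractions of the eight-step mixing series (8:2 .. 1:9).
PAPER_MIXING_FRACTIONS = (0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)

_SATURATION_P = 0.999


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and array geometry for one synthetic assay pair.

    ``cells_per_chamber`` is the mean cell-genome equivalents loaded per
    chamber (m); the default 0.25 puts reference occupancy near the
    0-1 molecule/chamber operating range of the array.
    """

    params: TumorCellParams
    x: float
    cells_per_chamber: float = 0.25
    total_chambers: int = DEFAULT_TOTAL_CHAMBERS
    n_panels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise ValidationError(f"tumor content x must be in [0, 1], got {self.x}")
        if self.cells_per_chamber <= 0:
            raise ValidationError("cells_per_chamber must be positive")
        if self.total_chambers < 1 or self.n_panels < 1:
            raise ValidationError("need total_chambers >= 1 and n_panels >= 1")


@dataclass(frozen=True)
class MixtureStep:
    """One step of a DNA-mixing series: tumor mass fraction and model ratio."""

    tumor_fraction: float
    expected_r: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValidationError("tumor_fraction must be in [0, 1]")


def expected_lambdas(config: SimulationConfig) -> tuple[float, float]:
    """Mean copies per chamber (target, reference) implied by the truth."""
    a, b, x, m = config.params.A, config.params.B, config.x, config.cells_per_chamber
    stroma = NORMAL_COPY * (1.0 - x)
    return m * (b * x + stroma), m * (a * x + stroma)


def simulate_panel(config: SimulationConfig) -> tuple[PanelCount, PanelCount]:
    """Draw pooled positive-chamber counts for the target/reference pair.

    Counts are Binomial(N * n_panels, 1 - exp(-lam)) from a stream seeded
    by ``config.seed``; identical configs give identical counts.
    """
    lam_t, lam_r = expected_lambdas(config)
    n = config.total_chambers * config.n_panels
    rng = np.random.default_rng(config.seed)
    counts = []
    for lam, name in ((lam_t, "target"), (lam_r, "reference")):
        p = -np.expm1(-lam)
        if p > _SATURATION_P:
            warnings.warn(
                f"{name} occupancy probability {p:.4f} near saturation; "
                "downstream quantification will likely fail",
                stacklevel=2,
            )
        counts.append(PanelCount(int(rng.binomial(n, p)), n, label=name))
    return counts[0], counts[1]


def mixture_series(
    params: TumorCellParams,
    fractions: Sequence[float] = PAPER_MIXING_FRACTIONS,
) -> list[MixtureStep]:
    """Model ratios along a DNA-mixing series, mass fraction read as x."""
    return [
        MixtureStep(float(f), forward_ratio(params, float(f))) for f in fractions
    ]


def fit_b_prime_series(
    observations: Sequence[tuple[float, float]],
    A: float,
) -> float:
    """Least-squares per-cell HER2 copy number from a mixture series.

    The forward model linearizes as
    r (A x + 2 (1 - x)) - 2 (1 - x) = B x, so the 1-D least-squares
    solution is B = sum(x_i y_i) / sum(x_i^2) with
    y_i = r_i (A x_i + 2 (1 - x_i)) - 2 (1 - x_i).
    """
    if A < 2.0:
        raise ValidationError(f"CEP17 copy number A must be >= 2, got {A}")
    obs = [(float(x), float(r)) for x, r in observations]
    positive = [o for o in obs if o[0] > 0.0]
    if len({x for x, _ in obs}) < 2 and len(obs) > 1:
        raise ValidationError("observations must span distinct fractions")
    if not positive:
        raise ValidationError(
            "all fractions are zero: per-cell copy number unidentifiable"
        )
    xs = np.array([x for x, _ in positive])
    rs = np.array([r for _, r in positive])
    y = rs * (A * xs + NORMAL_COPY * (1.0 - xs)) - NORMAL_COPY * (1.0 - xs)
    return float(xs @ y / (xs @ xs))
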