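"""Chamber-count quantification for partitioned digital PCR.

A digital-array panel splits the reaction into ``N`` nanoliter chambers
(770 on the 48.770 integrated fluidic circuit) at limiting dilution, so a
chamber is positive iff it received at least one template molecule.  Under
the standard occupancy model (molecules per chamber ~ Poisson(lam),
chambers independent), the mean copies per chamber are recovered from the
positive-chamber count ``k`` by

    lam = -ln(1 - k/N)

and the target/reference copy-number ratio is the ratio of the two
corrected concentrations.  Confidence intervals use the delta method:
Var(lam_hat) ~= p / (N (1-p)) with p = k/N, and the ratio interval is
built on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .errors import SaturationError, UndefinedRatioError, ValidationError

__all__ = [
    "PanelCount",
    "ConcentrationEstimate",
    "DualCountRatio",
    "poisson_lambda",
    "dpcr_ratio",
    "aggregate_panels",
]

#: Chambers per panel on the digital array used throughout.
DEFAULT_TOTAL_CHAMBERS = 770

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class PanelCount:
    """Positive/total chamber counts for one assay on one panel (or pool)."""

    positive_chambers: int
    total_chambers: int = DEFAULT_TOTAL_CHAMBERS
    label: str = ""

    def __post_init__(self) -> None:
        k, n = self.positive_chambers, self.total_chambers
        if n <= 0:
            raise ValidationError(f"total_chambers must be positive, got {n}")
        if k < 0 or k > n:
            raise ValidationError(
                f"positive_chambers must satisfy 0 <= k <= {n}, got {k}"
            )

    @property
    def occupancy(self) -> float:
        """Fraction of positive chambers, k/N."""
        return self.positive_chambers / self.total_chambers


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Mean copies per chamber with a 95% delta-method interval."""

    lam: float
    ci_low: float
    ci_high: float
    source: PanelCount

    def __post_init__(self) -> None:
        if self.lam < 0 or not (self.ci_low <= self.lam <= self.ci_high):
            raise ValidationError("interval must bracket a non-negative lam")


@dataclass(frozen=True)
class DualCountRatio:
    """Target/reference concentration ratio with a 95% interval."""

    r: float
    ci_low: float
    ci_high: float
    target: ConcentrationEstimate
    reference: ConcentrationEstimate

    def __post_init__(self) -> None:
        if self.r <= 0 or not (self.ci_low <= self.r <= self.ci_high):
            raise ValidationError("interval must bracket a positive ratio")


def poisson_lambda(count: PanelCount) -> ConcentrationEstimate:
    """Poisson-occupancy-corrected concentration from a chamber count.

    Raises
    ------
    SaturationError
        If every chamber is positive (k == N): lam is unbounded.
    """
    k, n = count.positive_chambers, count.total_chambers
    if k == n:
        name = count.label or f"{k}/{n}"
        raise SaturationError(
            f"panel {name!r} saturated: all {n} chambers positive, "
            "concentration cannot be estimated"
        )
    p = k / n
    lam = -math.log1p(-p)
    if k == 0:
        return ConcentrationEstimate(0.0, 0.0, 0.0, count)
    se = math.sqrt(p / (n * (1.0 - p)))
    return ConcentrationEstimate(
        lam, max(0.0, lam - _Z95 * se), lam + _Z95 * se, count
    )


def dpcr_ratio(target: PanelCount, reference: PanelCount) -> DualCountRatio:
    """Target/reference copy-number ratio from two chamber counts.

    The 95% interval is delta-method on log r: the squared coefficients of
    variation of the two corrected concentrations add.

    Raises
    ------
    UndefinedRatioError
        If the reference has no positive chambers (lam = 0).
    SaturationError
        If either side is saturated.
    """
    est_t = poisson_lambda(target)
    est_r = poisson_lambda(reference)
    if est_r.lam == 0.0:
        raise UndefinedRatioError(
            "reference assay has zero positive chambers; ratio undefined"
        )
    r = est_t.lam / est_r.lam
    if est_t.lam == 0.0:
        # k_target = 0: r = 0 is outside the model (r > 0); treat as invalid.
        raise UndefinedRatioError(
            "target assay has zero positive chambers; ratio is zero and "
            "outside the model domain"
        )
    var_log = _log_lambda_variance(target) + _log_lambda_variance(reference)
    half = _Z95 * math.sqrt(var_log)
    return DualCountRatio(
        r, r * math.exp(-half), r * math.exp(half), est_t, est_r
    )


def _log_lambda_variance(count: PanelCount) -> float:
    k, n = count.positive_chambers, count.total_chambers
    p = k / n
    lam = -math.log1p(-p)
    return p / (n * (1.0 - p)) / lam**2


def aggregate_panels(counts: Sequence[PanelCount] | Iterable[PanelCount]) -> PanelCount:
    """Pool panels of one assay by summing k and N (chambers exchangeable)."""
    counts = list(counts)
    if not counts:
        raise ValidationError("cannot aggregate an empty list of panels")
    k = sum(c.positive_chambers for c in counts)
    n = sum(c.total_chambers for c in counts)
    return PanelCount(k, n, label=counts[0].label)
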