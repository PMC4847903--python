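"""Tumor content ratio (TCR) from nucleus counts.

The tumor content x of a specimen is the fraction of nucleated cells
that are cancer cells.  In routine practice it is read off an H&E image
by separating cancerous from non-cancerous nuclei; cancer nuclei are
enlarged, so a size threshold on a tabulated nucleus-size feature is a
faithful minimal classifier.  The AUTO threshold is Otsu's two-class
variance maximization on the size distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ValidationError

__all__ = [
    "NucleusRecord",
    "TcrEstimate",
    "tcr_from_counts",
    "classify_nuclei",
    "AUTO",
]

AUTO = "auto"

_MIN_AUTO_RECORDS = 10


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus: its size measure and an optional class label."""

    size: float
    label: Literal["cancer", "non_cancer", None] = None

    def __post_init__(self) -> None:
        if not self.size > 0:
            raise ValidationError(f"nucleus size must be positive, got {self.size}")


@dataclass(frozen=True)
class TcrEstimate:
    """Tumor content x = n_cancer / n_total."""

    x: float
    n_cancer: int
    n_total: int


def tcr_from_counts(n_cancer: int, n_total: int) -> TcrEstimate:
    """Tumor content from cancer / total nucleus counts (exact fraction)."""
    if n_total < 1:
        raise ValidationError(f"n_total must be >= 1, got {n_total}")
    if not 0 <= n_cancer <= n_total:
        raise ValidationError(
            f"need 0 <= n_cancer <= n_total, got {n_cancer}/{n_total}"
        )
    return TcrEstimate(n_cancer / n_total, n_cancer, n_total)


def classify_nuclei(
    records: Sequence[NucleusRecord],
    threshold: float | str = AUTO,
) -> tuple[list[NucleusRecord], TcrEstimate]:
    """Label nuclei as cancer iff size >= threshold; derive the TCR.

    ``threshold=AUTO`` picks the cut by Otsu's method on the observed
    sizes (needs at least 10 records); a manual numeric threshold is
    always accepted.
    """
    if not records:
        raise ValidationError("cannot classify an empty nucleus list")
    sizes = np.asarray([rec.size for rec in records], dtype=float)
    if threshold == AUTO:
        if len(records) < _MIN_AUTO_RECORDS:
            raise ValidationError(
                f"AUTO thresholding needs >= {_MIN_AUTO_RECORDS} records, "
                f"got {len(records)}"
            )
        cut = float(threshold_otsu(sizes))
    else:
        cut = float(threshold)
    labels = sizes >= cut
    labelled = [
        replace(rec, label="cancer" if is_cancer else "non_cancer")
        for rec, is_cancer in zip(records, labels)
    ]
    return labelled, tcr_from_counts(int(labels.sum()), len(records))
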