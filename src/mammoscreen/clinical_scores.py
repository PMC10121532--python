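"""Deterministic clinical scoring rules.

Two independent scoring systems live here:

* Categorisation of the continuous AI malignancy raw score (0.0-10.0) into
  the ten-level "AI score" used throughout the evaluation, where 10 marks
  the highest suspicion of malignancy.
* The Nottingham Prognostic Index (NPI) for invasive breast tumours,
  ``NPI = 0.2 * diameter_cm + node_stage + histologic_grade``, with the
  standard four-level prognostic categorisation
  (Excellent <= 2.4 < Good <= 3.4 < Moderate <= 5.4 < Poor).

All functions are pure; missing inputs propagate as ``None``.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Optional

__all__ = [
    "NPI_BOUNDARIES",
    "NpiCategory",
    "bin_ai_score",
    "node_stage",
    "compute_npi",
    "categorize_npi",
]

#: NPI category upper boundaries (inclusive) for excellent / good / moderate;
#: anything above the last cut is "poor".
NPI_BOUNDARIES: tuple[float, float, float] = (2.4, 3.4, 5.4)


class NpiCategory(str, Enum):
    """Four-level NPI prognostic group (boundary values belong to the lower group)."""

    EXCELLENT = "excellent"
    GOOD = "good"
    MODERATE = "moderate"
    POOR = "poor"


def bin_ai_score(ai_raw: float) -> int:
    """Map a continuous AI raw score in [0.0, 10.0] to the integer AI score 1-10.

    Bin ``k`` covers the half-open interval ``(k-1, k]``; a raw score of
    exactly 0.0 falls in bin 1.  The vendor does not publish its bin edges,
    so unit intervals closed above are used: this is the convention under
    which "AI score 10" contains the maximal raw scores.

    Parameters
    ----------
    ai_raw : float
        Exam-level malignancy raw score, ``0.0 <= ai_raw <= 10.0``.

    Returns
    -------
    int
        AI score in 1..10, monotone non-decreasing in ``ai_raw``.
    """
    if not (0.0 <= ai_raw <= 10.0) or math.isnan(ai_raw):
        raise ValueError(f"AI raw score must lie in [0.0, 10.0], got {ai_raw!r}")
    return max(1, math.ceil(ai_raw))


def node_stage(n_positive_nodes: int) -> int:
    """NPI nodal stage from the count of positive axillary lymph nodes.

    0 nodes -> stage 1; 1-3 nodes -> stage 2; 4 or more -> stage 3.
    """
    if n_positive_nodes < 0:
        raise ValueError(f"node count must be non-negative, got {n_positive_nodes}")
    if n_positive_nodes == 0:
        return 1
    if n_positive_nodes <= 3:
        return 2
    return 3


def compute_npi(
    diameter_mm: Optional[float],
    grade: Optional[int],
    n_positive_nodes: Optional[int],
) -> Optional[float]:
    """Nottingham Prognostic Index for an invasive tumour.

    ``0.2 * (diameter in cm) + nodal stage (1-3) + histologic grade (1-3)``,
    computed at full floating precision (no rounding before categorisation).
    Returns ``None`` if any input is missing, mirroring how pathology
    variables recorded as "information not available" propagate.
    """
    if diameter_mm is None or grade is None or n_positive_nodes is None:
        return None
    if diameter_mm <= 0:
        raise ValueError(f"tumour diameter must be positive, got {diameter_mm}")
    if grade not in (1, 2, 3):
        raise ValueError(f"histologic grade must be 1, 2 or 3, got {grade}")
    return 0.2 * (diameter_mm / 10.0) + node_stage(n_positive_nodes) + grade


def categorize_npi(npi: Optional[float]) -> Optional[NpiCategory]:
    """Assign the four-level NPI prognostic category.

    Boundaries are inclusive on the lower category: 2.4 is still
    "excellent", 3.4 still "good", 5.4 still "moderate".
    """
    if npi is None:
        return None
    if npi <= 0:
        raise ValueError(f"NPI must be positive, got {npi}")
    lo, mid, hi = NPI_BOUNDARIES
    if npi <= lo:
        return NpiCategory.EXCELLENT
    if npi <= mid:
        return NpiCategory.GOOD
    if npi <= hi:
        return NpiCategory.MODERATE
    return NpiCategory.POOR
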