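"""Connor-Davidson Resilience Scale (CD-RISC 25) scoring.

The scale has 25 items rated 0-4; the total ranges 0-100 and higher means
more resilient. Mean imputation is applied for up to 6 missing items; a
response with more than 6 missing items is excluded from analysis.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

N_ITEMS = 25
MAX_MISSING = 6


class CdRiscExcludedError(ValueError):
    """Raised when a response has too many missing items to score."""


def score_cdrisc(item_scores: Sequence[Optional[float]]) -> float:
    """Score a 25-item CD-RISC response.

    Missing items (``None`` or NaN) are mean-imputed from the observed items
    when at most 6 are missing; the possibly fractional total is returned.

    Raises
    ------
    CdRiscExcludedError
        If more than 6 items are missing.
    ValueError
        If the response does not have 25 item slots or any observed item is
        outside the integer range 0-4.
    """
    items = list(item_scores)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item slots, got {len(items)}")
    observed = []
    n_missing = 0
    for v in items:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_missing += 1
            continue
        fv = float(v)
        if fv != int(fv) or not (0 <= fv <= 4):
            raise ValueError(f"item score {v!r} not an integer in [0, 4]")
        observed.append(fv)
    if n_missing > MAX_MISSING:
        raise CdRiscExcludedError(
            f"{n_missing} of {N_ITEMS} items missing (more than {MAX_MISSING}): "
            "response excluded"
        )
    mean = sum(observed) / len(observed)
    return sum(observed) + n_missing * mean
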