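"""High-pass indexing of ring-width series.

Cross-dating statistics must compare year-to-year variation, not the age
trend or the vigor of individual stems, so raw widths are first converted to
a dimensionless index.  Two classical high-pass methods are provided:

``moving_ratio``
    index[t] = width[t] / centred moving average (default window 5).  The
    (window-1)/2 edge positions on each end are marked invalid.  Nominal
    centre of the index is 1.0.

``log_diff``
    index[t] = ln(width[t]) - ln(width[t-1]), widths clamped below by
    ``zero_replacement`` before the log.  Position 0 is invalid.  Nominal
    centre is 0.0.

Missing rings (width 0) participate via ``zero_replacement`` and are marked
invalid, as are ``log_diff`` positions whose predecessor is missing.  Invalid
positions are excluded from all downstream statistics, never imputed:
fabricating agreement at series ends — exactly where dating is weakest — is
worse than losing a few years of overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IndexedSeries, RingFlag, RingSeries, ValidationError

__all__ = ["IndexingMethod", "MOVING_RATIO", "LOG_DIFF", "index_series"]


@dataclass(frozen=True)
class IndexingMethod:
    """High-pass indexing configuration.

    ``zero_replacement`` defaults to 0.005 mm — half the smallest positive
    width measurable in the hundredths-mm dialect — bounding the log
    transform at missing rings.
    """

    kind: str = "moving_ratio"  # "moving_ratio" | "log_diff"
    window: int = 5
    zero_replacement: float = 0.005

    def __post_init__(self) -> None:
        if self.kind not in ("moving_ratio", "log_diff"):
            raise ValidationError(f"unknown indexing method {self.kind!r}")
        if self.kind == "moving_ratio" and (self.window < 3 or self.window % 2 == 0):
            raise ValidationError("moving_ratio window must be an odd integer >= 3")
        if self.zero_replacement <= 0:
            raise ValidationError("zero_replacement must be positive")


MOVING_RATIO = IndexingMethod("moving_ratio", 5)
LOG_DIFF = IndexingMethod("log_diff")


def index_series(series: RingSeries, method: IndexingMethod = MOVING_RATIO) -> IndexedSeries:
    """Convert a ring-width series to its dimensionless high-pass index."""
    n = len(series)
    missing = series.ring_flags == RingFlag.MISSING_INSERTED
    w = np.where(missing, method.zero_replacement, series.widths)

    if method.kind == "moving_ratio":
        k = method.window
        if n <= k:
            raise ValidationError(
                f"series of length {n} too short for moving_ratio window {k}"
            )
        half = k // 2
        # moving average over measured rings only: an inserted zero must not
        # distort the index of its neighbours (it is invalid itself anyway)
        meas = (~missing).astype(float)
        num = np.convolve(series.widths * meas, np.ones(k), mode="same")
        den = np.convolve(meas, np.ones(k), mode="same")
        ma = np.where(den > 0, num / np.maximum(den, 1), method.zero_replacement)
        index = w / ma
        valid = np.ones(n, dtype=bool)
        valid[:half] = False
        valid[n - half :] = False
        valid[missing] = False
    else:  # log_diff
        if n <= 1:
            raise ValidationError("series too short for log_diff (needs length > 1)")
        lw = np.log(np.maximum(w, method.zero_replacement))
        index = np.zeros(n)
        index[1:] = np.diff(lw)
        valid = np.ones(n, dtype=bool)
        valid[0] = False
        valid[missing] = False
        valid[1:][missing[:-1]] = False  # diff contaminated by a missing predecessor

    return IndexedSeries(
        source_id=series.series_id,
        index=index,
        valid=valid,
        first_year=series.first_year,
    )
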