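"""Cross-dating statistics and sliding calendar dating.

Three classical statistics are computed over the overlap of two series:

* GLK (Gleichlaeufigkeit): the fraction of years in which the two series'
  first differences share the same sign (a tie — either difference exactly
  zero — scores 1/2).
* Pearson correlation r over the jointly valid overlap of the high-pass
  indices, reported with the overlap length n.
* the t-value, t = r * sqrt(n - 2) / sqrt(1 - r**2): the correlation
  transformed to a t statistic on n - 2 degrees of freedom, the classical
  dating score because it integrates overlap length.

:func:`slide_date` scans every admissible calendar placement of an undated
series against a dated reference and ranks the placements by t-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .core import (
    Chronology,
    CrossdateResult,
    IndexedSeries,
    RingFlag,
    RingSeries,
    ValidationError,
)
from .standardize import MOVING_RATIO, IndexingMethod, index_series

__all__ = [
    "SlideConfig",
    "glk",
    "overlap_corr",
    "bp_tvalue",
    "slide_date",
    "T_SENTINEL",
]

#: Returned (signed) by :func:`bp_tvalue` when |r| >= 1 would overflow the
#: closed form; large enough to outrank any attainable finite t.
T_SENTINEL = 1.0e6


@dataclass(frozen=True)
class SlideConfig:
    """Sliding-date configuration.

    ``accept_t`` / ``accept_glk`` are conventional screening thresholds for
    flagging a placement significant; both are reported in output so users
    can state the criteria actually applied.  Negative-t placements are never
    significant: an inverted match is physically meaningless for
    same-hemisphere ring series.
    """

    min_overlap: int = 50
    offset_range: Optional[tuple[int, int]] = None  # inclusive candidate first years
    accept_t: float = 3.5
    accept_glk: float = 0.60
    indexing: IndexingMethod = field(default_factory=lambda: MOVING_RATIO)

    def __post_init__(self) -> None:
        if self.min_overlap < 10:
            raise ValidationError("min_overlap must be >= 10")


def _series_arrays(obj: Union[RingSeries, IndexedSeries]) -> tuple[np.ndarray, np.ndarray]:
    """(values, valid) for statistics: raw widths for RingSeries (measured
    rings valid), index/valid for IndexedSeries."""
    if isinstance(obj, RingSeries):
        return obj.widths, obj.ring_flags == RingFlag.MEASURED
    return obj.index, obj.valid


def _aligned(xa, va, xb, vb, offset):
    """Overlap windows where a[i] is matched to b[i + offset]."""
    lo = max(0, -offset)
    hi = min(len(xa), len(xb) - offset)
    if hi <= lo:
        z = np.empty(0)
        return z, z.astype(bool), z, z.astype(bool)
    sa = slice(lo, hi)
    sb = slice(lo + offset, hi + offset)
    return xa[sa], va[sa], xb[sb], vb[sb]


def glk(
    a: Union[RingSeries, IndexedSeries],
    b: Union[RingSeries, IndexedSeries],
    offset: int = 0,
    min_pairs: int = 1,
) -> Optional[float]:
    """Sign-agreement statistic over the overlap (a[i] vs b[i + offset]).

    Returns a value in [0, 1], or ``None`` when fewer than ``min_pairs``
    difference pairs are jointly valid (an undefined result, not a number).
    GLK is symmetric: ``glk(a, b, k) == glk(b, a, -k)``.
    """
    xa, va, xb, vb = _aligned(*_series_arrays(a), *_series_arrays(b), offset)
    if len(xa) < 2:
        return None
    da = np.sign(np.diff(xa))
    db = np.sign(np.diff(xb))
    ok = va[:-1] & va[1:] & vb[:-1] & vb[1:]
    if int(ok.sum()) < max(min_pairs, 1):
        return None
    da, db = da[ok], db[ok]
    score = np.where((da == 0) | (db == 0), 0.5, (da == db).astype(float))
    return float(score.mean())


def overlap_corr(
    a: Union[RingSeries, IndexedSeries],
    b: Union[RingSeries, IndexedSeries],
    offset: int = 0,
    min_overlap: int = 50,
) -> tuple[Optional[float], int]:
    """Pearson r over the jointly valid overlap, with the overlap length n.

    Returns ``(None, n)`` when n < ``min_overlap`` or either window has zero
    variance.
    """
    xa, va, xb, vb = _aligned(*_series_arrays(a), *_series_arrays(b), offset)
    ok = va & vb
    n = int(ok.sum())
    if n < min_overlap:
        return None, n
    x, y = xa[ok], xb[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None, n
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r, n


def bp_tvalue(r: float, n: int) -> float:
    """t = r * sqrt(n - 2) / sqrt(1 - r**2); signed (callers rank on t).

    |r| >= 1 returns the signed :data:`T_SENTINEL` with a warning rather than
    overflowing; n <= 2 is an error.
    """
    if n <= 2:
        raise ValidationError("t-value requires overlap n > 2")
    if abs(r) >= 1.0:
        warnings.warn(
            f"|r| = {abs(r):g} >= 1: returning sentinel t = {T_SENTINEL:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.sign(r) or 1.0) * T_SENTINEL
    return float(r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r))


def _as_reference(reference: Union[IndexedSeries, Chronology]) -> IndexedSeries:
    ref = reference.to_indexed() if isinstance(reference, Chronology) else reference
    if ref.first_year is None:
        raise ValidationError("reference must be dated")
    return ref


def slide_date(
    undated: Union[RingSeries, IndexedSeries],
    reference: Union[IndexedSeries, Chronology],
    cfg: SlideConfig = SlideConfig(),
) -> list[CrossdateResult]:
    """Rank every candidate calendar placement of a series on a reference.

    Each candidate first year with overlap >= ``cfg.min_overlap`` yields one
    :class:`CrossdateResult`; results are sorted rank 1 first (maximal t,
    ties broken by larger GLK, larger overlap, then smaller
    ``abs(candidate_first_year)``).  An empty list means no candidate reached
    the minimum overlap.
    """
    ref = _as_reference(reference)
    if isinstance(undated, RingSeries):
        undated = index_series(undated, cfg.indexing)
    la, lr = len(undated), len(ref)

    lo = ref.first_year - la + cfg.min_overlap
    hi = ref.first_year + lr - cfg.min_overlap
    if cfg.offset_range is not None:
        lo = max(lo, cfg.offset_range[0])
        hi = min(hi, cfg.offset_range[1])

    results: list[CrossdateResult] = []
    for fy in range(lo, hi + 1):
        offset = fy - ref.first_year  # undated[i] ~ ref[i + offset]
        r, n = overlap_corr(undated, ref, offset, cfg.min_overlap)
        if r is None:
            continue
        g = glk(undated, ref, offset)
        t = bp_tvalue(r, n) if n > 2 else 0.0
        sig = (t >= cfg.accept_t) and (g is not None and g >= cfg.accept_glk)
        results.append(
            CrossdateResult(
                candidate_first_year=fy,
                overlap_n=n,
                glk=g,
                corr=r,
                tvalue=t,
                significant=sig,
            )
        )
    results.sort(
        key=lambda c: (
            -c.tvalue,
            -(c.glk if c.glk is not None else -1.0),
            -c.overlap_n,
            abs(c.candidate_first_year),
        )
    )
    for i, c in enumerate(results, start=1):
        c.rank = i
    return results
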