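"""Site-level mean chronology and chronology-quality diagnostics.

The dating reference is a year-indexed robust mean of many indexed series.
Per year the value is the Tukey biweight robust mean (tuning constant 9)
of the contributing valid indices when sample depth >= 4, and the
arithmetic mean at lower depth where the biweight is unstable.  Chronologies
are always built on indexed series, never raw widths: depth and age-trend
differences between individuals would otherwise dominate the mean.

Quality diagnostics follow standard dendro practice: rbar is the mean
pairwise Pearson correlation over a stated common window, and the expressed
population signal EPS = n*rbar / (n*rbar + (1 - rbar)) with n the mean
sample depth in the window.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .core import Chronology, IndexedSeries, ValidationError

__all__ = ["tbrm", "build_chronology", "rbar_eps"]

#: Depth below which the robust mean falls back to the arithmetic mean.
ROBUST_MIN_DEPTH = 4


def tbrm(x: np.ndarray, c: float = 9.0) -> float:
    """Tukey biweight robust mean (one-pass, median/MAD centred).

    Values further than ``c`` median-absolute-deviations from the median get
    zero weight; the rest are weighted by (1 - u**2)**2.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    s = np.median(np.abs(x - med))
    u = (x - med) / (c * s + 1e-8)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    if w.sum() == 0:
        return float(med)
    return float(np.sum(w * x) / np.sum(w))


def build_chronology(
    indexed: Sequence[IndexedSeries],
    robust: bool = True,
) -> Chronology:
    """Collapse dated indexed series into a mean chronology with depth.

    Years where no series contributes are absent from the ends; interior
    zero-depth years (possible with disjoint series) hold NaN.
    """
    indexed = list(indexed)
    if not indexed:
        raise ValidationError("cannot build a chronology from zero series")
    for s in indexed:
        if s.first_year is None:
            raise ValidationError(f"series {s.source_id!r} is undated")

    first = min(s.first_year for s in indexed)
    last = max(s.first_year + len(s) - 1 for s in indexed)
    n_years = last - first + 1
    buckets: list[list[float]] = [[] for _ in range(n_years)]
    for s in indexed:
        off = s.first_year - first
        for i in np.flatnonzero(s.valid):
            buckets[off + i].append(float(s.index[i]))

    values = np.full(n_years, np.nan)
    depth = np.zeros(n_years, dtype=int)
    for t, vals in enumerate(buckets):
        depth[t] = len(vals)
        if not vals:
            continue
        arr = np.array(vals)
        if robust and len(vals) >= ROBUST_MIN_DEPTH:
            values[t] = tbrm(arr)
        else:
            values[t] = arr.mean()

    # trim leading/trailing zero-depth years
    nz = np.flatnonzero(depth > 0)
    lo, hi = nz[0], nz[-1] + 1
    chron = Chronology(first_year=first + int(lo), values=values[lo:hi], depth=depth[lo:hi])
    rbar, _, _ = rbar_eps(indexed)
    chron.rbar = rbar
    return chron


def rbar_eps(
    indexed: Sequence[IndexedSeries],
    window: Optional[tuple[int, int]] = None,
    min_pair_overlap: int = 30,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(rbar, EPS, mean depth) over a common window.

    ``window`` is an inclusive (first_year, last_year) range; ``None`` uses
    the full union of the series spans.  Pairs with fewer than
    ``min_pair_overlap`` jointly valid years are skipped; with no usable
    pair the result is (None, None, None).
    """
    indexed = [s for s in indexed if s.first_year is not None]
    if len(indexed) < 2:
        return None, None, None
    if window is None:
        window = (
            min(s.first_year for s in indexed),
            max(s.first_year + len(s) - 1 for s in indexed),
        )
    y0, y1 = window

    def clipped(s: IndexedSeries) -> tuple[np.ndarray, np.ndarray, int]:
        lo = max(s.first_year, y0)
        hi = min(s.first_year + len(s) - 1, y1)
        a, b = lo - s.first_year, hi - s.first_year + 1
        return s.index[a:b], s.valid[a:b], lo

    rs = []
    for i in range(len(indexed)):
        xi, vi, fi = clipped(indexed[i])
        for j in range(i + 1, len(indexed)):
            xj, vj, fj = clipped(indexed[j])
            lo = max(fi, fj)
            hi = min(fi + len(xi), fj + len(xj))
            if hi - lo < min_pair_overlap:
                continue
            a = slice(lo - fi, hi - fi)
            b = slice(lo - fj, hi - fj)
            ok = vi[a] & vj[b]
            if int(ok.sum()) < min_pair_overlap:
                continue
            x, y = xi[a][ok], xj[b][ok]
            if x.std() == 0 or y.std() == 0:
                continue
            rs.append(float(np.corrcoef(x, y)[0, 1]))
    if not rs:
        return None, None, None
    rbar = float(np.mean(rs))

    depth = np.zeros(y1 - y0 + 1)
    for s in indexed:
        xi, vi, fi = clipped(s)
        depth[fi - y0 : fi - y0 + len(xi)] += vi
    n = float(depth[depth > 0].mean()) if np.any(depth > 0) else 0.0
    eps = n * rbar / (n * rbar + (1.0 - rbar)) if (n * rbar + (1.0 - rbar)) != 0 else None
    return rbar, eps, n
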