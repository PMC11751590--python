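"""Shared data model and calendar conventions for ring-width cross-dating.

Conventions used throughout the package:

* ring index 0 is the innermost (oldest) ring; the ring at index ``i`` of a
  dated series formed in calendar year ``first_year + i`` (year-of-formation
  convention, no sub-annual resolution);
* widths are stored in millimetres as floats — format-specific scaling
  (hundredths vs thousandths of a mm) lives entirely in :mod:`dendrodate.tucson`;
* a missing ring (a year with no detectable ring on the measured radius) is
  represented in-band as width 0.0 plus the ``MISSING_INSERTED`` flag, never
  as a gap, so positional year arithmetic stays trivial and matches the
  de-facto zero convention of the Tucson format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DendroError",
    "ValidationError",
    "ParseError",
    "DatingError",
    "RingFlag",
    "Status",
    "RingSeries",
    "IndexedSeries",
    "CrossdateResult",
    "AgeReport",
    "Chronology",
    "AGE_CAVEAT",
    "make_series",
    "calendar_span",
]


class DendroError(Exception):
    """Base class for all package errors."""


class ValidationError(DendroError, ValueError):
    """Invalid in-memory data (bad widths, inconsistent flags, ...)."""


class ParseError(DendroError, ValueError):
    """Malformed input file."""


class DatingError(DendroError, RuntimeError):
    """A dating step could not be completed (irreconcilable radii, ...)."""


class RingFlag(IntEnum):
    MEASURED = 0
    MISSING_INSERTED = 1


class Status(str, Enum):
    LIVING = "living"
    DEAD = "dead"
    UNKNOWN = "unknown"


#: Fixed caveat attached to every age report: the reported age is the
#: cross-dated ring count at the sampling point, with no allowance for pith
#: offset or unmeasured inner wood, so the plant's true age exceeds it.
AGE_CAVEAT = (
    "Age is the cross-dated ring count at the sampling point; no years were "
    "added for pith offset or any unmeasured inner portion, so the true age "
    "of the individual exceeds the reported age."
)


@dataclass
class RingSeries:
    """One measured radius, or a sample/site mean series.

    Parameters
    ----------
    series_id
        Unique identifier of this measurement series.
    widths
        Ring widths in mm, innermost ring first.  A width of exactly 0.0 is
        reserved for inserted missing rings and must carry the matching flag.
    ring_flags
        Per-ring :class:`RingFlag`, same length as ``widths``.
    first_year
        Calendar year of the innermost ring, or ``None`` while undated.
    """

    series_id: str
    widths: np.ndarray
    ring_flags: np.ndarray
    first_year: Optional[int] = None
    sample_id: str = ""
    site_id: str = ""
    radius_no: int = 1
    status: Status = Status.UNKNOWN

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        self.ring_flags = np.asarray(self.ring_flags, dtype=np.int8)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValidationError("a ring series needs at least one ring")
        if self.widths.shape != self.ring_flags.shape:
            raise ValidationError("widths and ring_flags must have equal length")
        if np.any(self.widths < 0):
            raise ValidationError("negative ring width")
        missing = self.ring_flags == RingFlag.MISSING_INSERTED
        if np.any((self.widths == 0) != missing):
            raise ValidationError(
                "width 0.0 is reserved for missing rings: every zero width must "
                "carry the MISSING_INSERTED flag and vice versa"
            )
        if self.radius_no < 1:
            raise ValidationError("radius_no must be >= 1")
        if not self.sample_id:
            self.sample_id = self.series_id
        self.status = Status(self.status)

    def __len__(self) -> int:
        return int(self.widths.size)

    @property
    def dated(self) -> bool:
        return self.first_year is not None

    @property
    def last_year(self) -> Optional[int]:
        return None if self.first_year is None else self.first_year + len(self) - 1

    @property
    def n_measured(self) -> int:
        return int(np.sum(self.ring_flags == RingFlag.MEASURED))

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.ring_flags == RingFlag.MISSING_INSERTED))

    @property
    def measured_mask(self) -> np.ndarray:
        return self.ring_flags == RingFlag.MEASURED

    def dated_at(self, first_year: Optional[int]) -> "RingSeries":
        """Copy of this series anchored at ``first_year`` (or undated)."""
        return replace(self, first_year=first_year)


@dataclass
class IndexedSeries:
    """Dimensionless high-pass index of a :class:`RingSeries`.

    ``valid`` marks positions usable by cross-dating statistics; edge
    positions lost to the moving window and missing rings are invalid.
    """

    source_id: str
    index: np.ndarray
    valid: np.ndarray
    first_year: Optional[int] = None

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.index.shape != self.valid.shape:
            raise ValidationError("index and valid must have equal length")

    def __len__(self) -> int:
        return int(self.index.size)

    @property
    def dated(self) -> bool:
        return self.first_year is not None

    def dated_at(self, first_year: Optional[int]) -> "IndexedSeries":
        return replace(self, first_year=first_year)


@dataclass
class CrossdateResult:
    """One candidate calendar placement of an undated series.

    ``tvalue`` follows t = r * sqrt(n - 2) / sqrt(1 - r**2) on the Pearson
    correlation r over the ``overlap_n`` jointly valid years.  Rank 1 is the
    maximal t (ties broken by larger GLK, then larger overlap, then smaller
    ``abs(candidate_first_year)``).
    """

    candidate_first_year: int
    overlap_n: int
    glk: Optional[float]
    corr: float
    tvalue: float
    rank: int = 0
    significant: bool = False


@dataclass
class AgeReport:
    """Per-sample age determination.

    ``age_years == n_measured + n_missing`` always; ``pith_offset_applied``
    is always False — an optional informational range may be carried but is
    never added to the age.
    """

    sample_id: str
    n_measured: int
    n_missing: int
    age_years: Optional[int]
    first_year: Optional[int]
    last_year: Optional[int]
    dated: bool = True
    status: Status = Status.UNKNOWN
    site_id: str = ""
    pith_offset_applied: bool = False
    pith_offset_info: Optional[str] = None
    caveat: str = AGE_CAVEAT

    def __post_init__(self) -> None:
        if self.dated:
            if self.age_years != self.n_measured + self.n_missing:
                raise ValidationError("age_years must equal n_measured + n_missing")
            if self.last_year != self.first_year + self.age_years - 1:
                raise ValidationError("last_year inconsistent with first_year + age")
        if self.pith_offset_applied:
            raise ValidationError("pith offset is never applied to ages")


@dataclass
class Chronology:
    """Year-indexed robust mean index with per-year sample depth."""

    first_year: int
    values: np.ndarray
    depth: np.ndarray
    rbar: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depth = np.asarray(self.depth, dtype=int)
        if self.values.shape != self.depth.shape:
            raise ValidationError("values and depth must have equal length")
        if np.any(self.depth < 0):
            raise ValidationError("negative sample depth")
        if np.any(np.isfinite(self.values) & (self.depth == 0)):
            raise ValidationError("chronology value defined where depth == 0")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self) - 1

    def to_indexed(self) -> IndexedSeries:
        """View of the chronology as a dated indexed series for sliding."""
        valid = (self.depth >= 1) & np.isfinite(self.values)
        vals = np.where(valid, self.values, 0.0)
        return IndexedSeries(
            source_id="chronology",
            index=vals,
            valid=valid,
            first_year=self.first_year,
        )


def make_series(
    series_id: str,
    widths: Sequence[float],
    first_year: Optional[int] = None,
    *,
    sample_id: str = "",
    site_id: str = "",
    radius_no: int = 1,
    status: Status | str = Status.UNKNOWN,
) -> RingSeries:
    """Construct a series of freshly measured rings (all flags MEASURED).

    Zero widths are rejected here: in this data model a zero width means an
    *inserted* missing ring, which only :func:`dendrodate.missing.apply_missing`
    creates.  If a measured radius truly has locally absent rings, measure the
    visible rings and let missing-ring insertion place the absent years.
    """
    w = np.asarray(list(widths), dtype=float)
    if w.size == 0:
        raise ValidationError("widths must be non-empty")
    if np.any(w < 0):
        raise ValidationError("negative ring width")
    if np.any(w == 0):
        raise ValidationError(
            "zero width in measured input: 0.0 is reserved for inserted missing "
            "rings — remove the zero and use missing-ring insertion instead"
        )
    flags = np.zeros(w.size, dtype=np.int8)
    return RingSeries(
        series_id=series_id,
        widths=w,
        ring_flags=flags,
        first_year=first_year,
        sample_id=sample_id,
        site_id=site_id,
        radius_no=radius_no,
        status=Status(status),
    )


def calendar_span(series: RingSeries) -> Optional[tuple[int, int]]:
    """(first_year, last_year) of a dated series; ``None`` when undated."""
    if series.first_year is None:
        return None
    return series.first_year, series.first_year + len(series) - 1
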