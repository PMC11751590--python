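"""Tucson decadal (.rwl) and long-format table I/O.

Two Tucson dialects are supported and auto-detected on read via the
end-of-series stop marker: ``999`` means values are hundredths of a mm,
``-9999`` means thousandths.  Zero values are missing rings (read with the
``MISSING_INSERTED`` flag).  The optional 3-line site header is consumed and
ignored on read and never written.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ParseError, RingFlag, RingSeries, Status, ValidationError

__all__ = [
    "TucsonDialect",
    "HUNDREDTHS",
    "THOUSANDTHS",
    "read_tucson",
    "write_tucson",
    "read_long_table",
    "write_long_table",
]


@dataclass(frozen=True)
class TucsonDialect:
    """Units and stop marker of one .rwl flavour."""

    units: str  # "hundredths_mm" | "thousandths_mm"
    stop_marker: int
    id_width: int = 8

    @property
    def scale(self) -> float:
        return 0.01 if self.units == "hundredths_mm" else 0.001

    def __post_init__(self) -> None:
        ok = (self.units, self.stop_marker) in {
            ("hundredths_mm", 999),
            ("thousandths_mm", -9999),
        }
        if not ok:
            raise ValidationError("stop marker inconsistent with units")


HUNDREDTHS = TucsonDialect("hundredths_mm", 999)
THOUSANDTHS = TucsonDialect("thousandths_mm", -9999)


def _as_text_lines(stream: IO[str] | str) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream.read().splitlines()


def _parse_line(line: str, lineno: int) -> tuple[str, int, list[int]]:
    sid = line[:8].strip()
    rest = line[8:].split()
    if not sid or len(rest) < 2:
        raise ParseError(f"line {lineno}: not a Tucson data line: {line!r}")
    try:
        year = int(rest[0])
        values = [int(v) for v in rest[1:]]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer field: {line!r}") from exc
    return sid, year, values


def _looks_like_data(line: str) -> bool:
    try:
        _parse_line(line, 0)
        return True
    except ParseError:
        return False


def read_tucson(stream: IO[str] | str) -> list[RingSeries]:
    """Read all series from a Tucson decadal stream (dialect auto-detected).

    Raises :class:`ParseError` on decade-arithmetic gaps or overlaps within a
    series, a missing stop marker, or mixed dialects in one file.
    """
    lines = _as_text_lines(stream)
    # Optionally skip up to 3 non-data header lines at the top of the file.
    start = 0
    while start < min(3, len(lines)) and lines[start].strip() and not _looks_like_data(lines[start]):
        start += 1

    series: list[RingSeries] = []
    dialect: Optional[TucsonDialect] = None
    cur_id: Optional[str] = None
    cur_first: Optional[int] = None
    next_year: Optional[int] = None
    counts: list[int] = []

    def finish(lineno: int, terminated: bool) -> None:
        nonlocal cur_id, cur_first, next_year, counts
        if cur_id is None:
            return
        if not terminated:
            raise ParseError(
                f"line {lineno}: series {cur_id!r} ended without a stop marker"
            )
        assert dialect is not None and cur_first is not None
        widths = np.array(counts, dtype=float) * dialect.scale
        flags = np.where(np.array(counts) == 0, RingFlag.MISSING_INSERTED, RingFlag.MEASURED)
        series.append(
            RingSeries(
                series_id=cur_id,
                widths=widths,
                ring_flags=flags.astype(np.int8),
                first_year=cur_first,
            )
        )
        cur_id, cur_first, next_year, counts = None, None, None, []

    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip():
            continue
        sid, year, values = _parse_line(raw, lineno)
        if cur_id is not None and sid != cur_id:
            finish(lineno, terminated=False)
        if cur_id is None:
            cur_id, cur_first, next_year = sid, year, year
        if year != next_year:
            raise ParseError(
                f"line {lineno}: decade year {year} does not follow ring count "
                f"(expected {next_year}) in series {sid!r}"
            )
        stopped = False
        for v in values:
            if v in (999, -9999):
                marker = HUNDREDTHS if v == 999 else THOUSANDTHS
                if dialect is None:
                    dialect = marker
                elif dialect != marker:
                    raise ParseError(
                        f"line {lineno}: mixed Tucson dialects in one file"
                    )
                stopped = True
                break
            if v < 0:
                raise ParseError(f"line {lineno}: negative ring value {v}")
            counts.append(v)
        next_year = cur_first + len(counts)
        if stopped:
            finish(lineno, terminated=True)
    finish(len(lines), terminated=False)
    return series


def _quantize(width_mm: float, dialect: TucsonDialect) -> int:
    """Width in dialect counts; positive widths never quantize to 0."""
    q = int(round(width_mm / dialect.scale))
    if width_mm > 0 and q == 0:
        q = 1  # 0 is semantically "missing ring" in this format
    return q


def write_tucson(
    series: Iterable[RingSeries], dialect: TucsonDialect = HUNDREDTHS
) -> str:
    """Serialize dated series to Tucson decadal text.

    Undated series are rejected (date them first, or use the long-format
    writer which supports ring indices).  Series ids longer than 8 characters
    are truncated deterministically; a resulting collision is an error.
    """
    out = io.StringIO()
    seen: dict[str, str] = {}
    for s in series:
        if s.first_year is None:
            raise ValidationError(
                f"series {s.series_id!r} is undated: Tucson output requires "
                "calendar years — date the series or write a long-format table"
            )
        sid = s.series_id[: dialect.id_width]
        if sid in seen and seen[sid] != s.series_id:
            raise ValidationError(
                f"series id collision after truncation to {dialect.id_width} "
                f"characters: {seen[sid]!r} and {s.series_id!r} both map to {sid!r}"
            )
        seen[sid] = s.series_id
        counts = [_quantize(w, dialect) for w in s.widths]
        counts.append(dialect.stop_marker)
        year = s.first_year
        pos = 0
        while pos < len(counts):
            # each line holds values up to the end of the current decade
            row_len = 10 - (year % 10) if pos == 0 else 10
            chunk = counts[pos : pos + row_len]
            fields = "".join(f"{c:6d}" for c in chunk)
            out.write(f"{sid:<8s}{year:6d}{fields}\n")
            year += len(chunk)
            pos += len(chunk)
    return out.getvalue()


_LONG_COLUMNS = {
    "series": "series_id",
    "series_id": "series_id",
    "year": "year",
    "ring": "year",
    "ring_index": "year",
    "width": "width_mm",
    "width_mm": "width_mm",
    "flag": "flag",
    "site": "site_id",
    "site_id": "site_id",
    "sample": "sample_id",
    "sample_id": "sample_id",
    "status": "status",
    "radius": "radius_no",
    "radius_no": "radius_no",
}


def read_long_table(
    stream: IO[str] | str,
    column_map: Optional[dict[str, str]] = None,
    dated: Optional[bool] = None,
) -> list[RingSeries]:
    """Read series from a delimited long table (comma or tab, header row).

    Expected columns (synonyms accepted): series id, year *or* ring index,
    width in mm; optional flag (``measured``/``missing``), site, sample,
    status, radius.  ``dated=None`` auto-detects: a ``ring_index`` column (or
    explicit mapping) means undated.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep=None, engine="python")
    orig_cols = {str(c).lower() for c in df.columns}
    rename = dict(_LONG_COLUMNS)
    if column_map:
        # canonical name -> actual column; invert for renaming
        rename.update({str(v).lower(): k for k, v in column_map.items()})
    df = df.rename(columns={c: rename.get(str(c).lower(), c) for c in df.columns})
    for col in ("series_id", "year", "width_mm"):
        if col not in df.columns:
            raise ParseError(f"long table is missing required column {col!r}")
    if dated is None:
        # a ring-index column (instead of calendar years) means undated
        dated = not ({"ring", "ring_index"} & orig_cols)
    out: list[RingSeries] = []
    for sid, grp in df.groupby("series_id", sort=False):
        years = grp["year"].to_numpy(dtype=int)
        if len(np.unique(years)) != len(years):
            raise ParseError(f"duplicate (series, year) rows in series {sid!r}")
        if np.any(np.diff(years) <= 0):
            raise ParseError(f"non-monotone years in series {sid!r}")
        if np.any(np.diff(years) != 1):
            raise ParseError(f"year gaps in series {sid!r}: fill missing rings explicitly")
        widths = grp["width_mm"].to_numpy(dtype=float)
        if "flag" in grp.columns:
            flags = np.where(
                grp["flag"].astype(str).str.lower().str.startswith("missing"),
                RingFlag.MISSING_INSERTED,
                RingFlag.MEASURED,
            ).astype(np.int8)
        else:
            flags = np.where(widths == 0, RingFlag.MISSING_INSERTED, RingFlag.MEASURED).astype(np.int8)
        meta = grp.iloc[0]
        out.append(
            RingSeries(
                series_id=str(sid),
                widths=widths,
                ring_flags=flags,
                first_year=int(years[0]) if dated else None,
                sample_id=str(meta["sample_id"]) if "sample_id" in grp.columns else "",
                site_id=str(meta["site_id"]) if "site_id" in grp.columns else "",
                radius_no=int(meta["radius_no"]) if "radius_no" in grp.columns else 1,
                status=Status(str(meta["status"])) if "status" in grp.columns else Status.UNKNOWN,
            )
        )
    return out


def write_long_table(series: Iterable[RingSeries]) -> str:
    """Serialize series (dated or undated) to a comma-delimited long table."""
    rows = []
    for s in series:
        for i in range(len(s)):
            rows.append(
                {
                    "series_id": s.series_id,
                    "year": (s.first_year + i) if s.first_year is not None else i,
                    "width_mm": s.widths[i],
                    "flag": "missing_inserted"
                    if s.ring_flags[i] == RingFlag.MISSING_INSERTED
                    else "measured",
                    "sample_id": s.sample_id,
                    "site_id": s.site_id,
                    "radius_no": s.radius_no,
                    "status": s.status.value,
                }
            )
    return pd.DataFrame(rows).to_csv(index=False)
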