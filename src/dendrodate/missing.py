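"""Detection and insertion of locally absent (missing) rings.

A missing ring — a year in which the cambium produced no detectable ring on
the measured radius — manifests downstream as a one-year lag shift: every
ring after the absent year correlates best with the reference one year later
than its assigned date.  The detector is purely statistical (segmented lag
scan plus greedy insertion) and makes no climatic assumption, since locally
absent rings in junipers are not tied solely to extreme years.

Position convention: insertion positions index the *result* series — they
are the slots that hold width-0 ``MISSING_INSERTED`` rings after insertion.
This keeps positions strictly increasing and unique even when two missing
rings are adjacent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .core import (
    Chronology,
    IndexedSeries,
    RingFlag,
    RingSeries,
    ValidationError,
)
from .crossdate import _as_reference, bp_tvalue, overlap_corr
from .standardize import MOVING_RATIO, IndexingMethod, index_series

__all__ = [
    "MissingRingConfig",
    "SegmentDiagnostic",
    "MissingRingHypothesis",
    "segment_lag_scan",
    "propose_missing",
    "apply_missing",
    "exhaustive_missing_search",
]


@dataclass(frozen=True)
class MissingRingConfig:
    """Tuning of the segmented lag scan and the greedy insertion search."""

    segment_len: int = 50
    step: int = 25
    max_lag: int = 3
    lag_margin: float = 0.10  # best-lag r must beat lag-0 r by this much
    epsilon_t: float = 0.05  # accepted hypotheses must gain at least this in t
    epsilon_r: float = 0.05  # per-step gain floor on the local window r
    end_epsilon_t: float = 0.6  # stricter gate for end-zone trial insertions
    pair_min_r: float = 0.45  # best-lag r needed to spend a joint pair trial
    insertion_penalty: float = 0.5  # whole-series t each insertion must pay for
    scan_step: int = 5  # denser internal scan used by the greedy search
    min_overlap: int = 10  # internal overlap floor for whole-series t
    indexing: IndexingMethod = field(default_factory=lambda: MOVING_RATIO)


@dataclass
class SegmentDiagnostic:
    start: int  # ring index of segment start (inclusive)
    end: int  # ring index past segment end (exclusive)
    lag_corr: dict[int, Optional[float]]
    best_lag: Optional[int]
    flagged: bool


@dataclass
class MissingRingHypothesis:
    """Audit trail of a missing-ring proposal.

    ``positions`` follow the result-series convention above;
    ``apply_missing(original, positions)`` reproduces the accepted series.
    """

    positions: list[int]
    score_before: float
    score_after: float
    segments: list[SegmentDiagnostic]
    steps: list[dict] = field(default_factory=list)
    anchor_shift: int = 0  # net first_year correction found during the scan


def apply_missing(series: RingSeries, positions: Sequence[int]) -> RingSeries:
    """Insert missing rings (width 0, flag MISSING_INSERTED) at ``positions``.

    Positions index the result series; duplicates are an error.  Measured
    widths are never altered, so ``n_measured`` is conserved and the total
    length grows by ``len(positions)``.
    """
    pos = sorted(int(p) for p in positions)
    if len(set(pos)) != len(pos):
        raise ValidationError("duplicate insertion positions")
    n_new = len(series) + len(pos)
    if pos and (pos[0] < 0 or pos[-1] >= n_new):
        raise ValidationError(f"insertion position out of range [0, {n_new})")
    widths = np.zeros(n_new)
    flags = np.full(n_new, RingFlag.MISSING_INSERTED, dtype=np.int8)
    keep = np.ones(n_new, dtype=bool)
    keep[pos] = False
    widths[keep] = series.widths
    flags[keep] = series.ring_flags
    return replace(series, widths=widths, ring_flags=flags)


def _whole_series_t(
    series: RingSeries,
    ref: IndexedSeries,
    cfg: MissingRingConfig,
) -> float:
    idx = index_series(series, cfg.indexing)
    r, n = overlap_corr(idx, ref, series.first_year - ref.first_year, cfg.min_overlap)
    if r is None or n <= 2:
        return -np.inf
    return bp_tvalue(r, n)


def segment_lag_scan(
    series: Union[RingSeries, IndexedSeries],
    reference: Union[IndexedSeries, Chronology],
    segment_len: int = 50,
    step: int = 25,
    max_lag: int = 3,
    lag_margin: float = 0.10,
    indexing: IndexingMethod = MOVING_RATIO,
) -> list[SegmentDiagnostic]:
    """Correlate fixed-length segments against the reference at small lags.

    For each segment the correlation at every lag in [-max_lag, +max_lag] is
    computed (lag L compares the segment's assigned years y with reference
    years y + L).  A segment is flagged when its best lag is nonzero and its
    best-lag r exceeds the lag-0 r by at least ``lag_margin`` — the signature
    of a dating shift, e.g. a missing ring earlier in the series.
    """
    ref = _as_reference(reference)
    if isinstance(series, RingSeries):
        series = index_series(series, indexing)
    if series.first_year is None:
        raise ValidationError("series must be provisionally dated")
    n = len(series)
    if n < segment_len:
        warnings.warn(
            f"series of length {n} shorter than one segment ({segment_len}): "
            "scanning it as a single whole-series segment",
            RuntimeWarning,
            stacklevel=2,
        )
        starts = [0]
        segment_len = n
    else:
        starts = list(range(0, n - segment_len + 1, step))
        if starts[-1] + segment_len < n:  # cover the tail
            starts.append(n - segment_len)

    base_off = series.first_year - ref.first_year
    min_seg = max(10, segment_len // 3)
    # two window scales: full-length windows keep the false-flag rate low,
    # half-length windows resolve transitions near the ends and deletions
    # closer together than a full window (which dilute the lag contrast)
    half = max(20, segment_len // 2)
    windows = [(s0, s0 + segment_len) for s0 in starts]
    if n >= 2 * half:
        h_starts = list(range(0, n - half + 1, step))
        if h_starts[-1] + half < n:
            h_starts.append(n - half)
        windows += [(s0, s0 + half) for s0 in h_starts]
    windows = sorted(set(windows))
    out: list[SegmentDiagnostic] = []
    for s, e in windows:
        seg = IndexedSeries("seg", series.index[s:e], series.valid[s:e])
        lag_corr: dict[int, Optional[float]] = {}
        for lag in range(-max_lag, max_lag + 1):
            r, _ = overlap_corr(seg, ref, base_off + s + lag, min_seg)
            lag_corr[lag] = r
        defined = {k: v for k, v in lag_corr.items() if v is not None}
        if not defined:
            out.append(SegmentDiagnostic(s, e, lag_corr, None, False))
            continue
        best = max(defined, key=lambda k: (defined[k], -abs(k)))
        r0 = defined.get(0)
        flagged = best != 0 and (r0 is None or defined[best] - r0 >= lag_margin)
        out.append(SegmentDiagnostic(s, e, lag_corr, best, flagged))
    return out


def _local_r(
    series: RingSeries,
    ref: IndexedSeries,
    lo: int,
    hi: int,
    cfg: MissingRingConfig,
) -> Optional[float]:
    """Lag-0 correlation of positions [lo, hi) against the reference."""
    idx = index_series(series, cfg.indexing)
    hi = min(hi, len(idx))
    seg = IndexedSeries("w", idx.index[lo:hi], idx.valid[lo:hi])
    r, _ = overlap_corr(seg, ref, series.first_year - ref.first_year + lo, 10)
    return r


def propose_missing(
    series: RingSeries,
    reference: Union[IndexedSeries, Chronology],
    max_missing: int = 5,
    cfg: MissingRingConfig = MissingRingConfig(),
) -> MissingRingHypothesis:
    """Greedy missing-ring search against a dated reference.

    A missing ring produces a step in the series' lag profile: every ring
    after the absent year matches the reference one year late.  The search
    repairs the profile left to right, one transition per step, up to
    ``max_missing`` times:

    1. scan segments (length ``cfg.segment_len``, dense step
       ``cfg.scan_step``) and find the earliest segment whose best lag is a
       positive shift by at least ``cfg.lag_margin`` in r;
    2. trial an insertion at every position between the last well-dated
       segment and the end of the flagged one, scoring each trial by the
       lag-0 correlation of that *local window* (the whole-series t-value is
       too flat in the insertion position, and with clustered missing rings
       a single correct insertion can even lower it transiently);
    3. keep the best trial (ties toward the earlier position) if it gains at
       least ``cfg.epsilon_r`` locally, else stop.

    If the earliest segment itself sits at a nonzero lag the series is
    re-anchored (its provisional ``first_year`` shifted) rather than edited.
    The hypothesis is accepted only if the whole-series t-value did not
    deteriorate (``score_after >= score_before``); otherwise the proposal is
    discarded and the audit trail returned with no positions.  Deterministic
    given its inputs.
    """
    if max_missing < 0:
        raise ValidationError("max_missing must be >= 0")
    ref = _as_reference(reference)
    if series.first_year is None:
        raise ValidationError("series must be provisionally dated against the reference")

    current = series
    positions: list[int] = []
    steps: list[dict] = []
    score_before = _whole_series_t(series, ref, cfg)
    first_segments: Optional[list[SegmentDiagnostic]] = None

    reanchors = 0
    reanchor_ok = True
    pair_attempts = 0
    sweep = max(20, cfg.segment_len // 2)
    # an end-sweep insertion changes the alignment the flag scan sees, so
    # the two stages alternate until a pass adds nothing
    for _pass in range(3):
        added_this_pass = 0
        tried: set[tuple[int, int]] = set()  # flagged windows that failed a trial
        while len(positions) < max_missing:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                diags = segment_lag_scan(
                    current,
                    ref,
                    cfg.segment_len,
                    cfg.scan_step,
                    cfg.max_lag,
                    cfg.lag_margin,
                    cfg.indexing,
                )
            if first_segments is None:
                first_segments = diags
            # Deletions make the lag profile non-decreasing from an aligned
            # anchor, so a negative lag is meaningful only at the very start
            # (the anchor overshot); mid-series negative flags are noise.
            target = next(
                (
                    d
                    for d in diags
                    if d.flagged
                    and d.best_lag is not None
                    and (d.start, d.end) not in tried
                    and (
                        d.best_lag > 0
                        or (d.best_lag < 0 and d.start == 0 and reanchor_ok)
                    )
                ),
                None,
            )
            if target is None:
                break
            if target.best_lag < 0:
                # judged on the flagged window itself (the same local
                # criterion as insertions): a shift driven by one or two
                # stray rings fails this and re-anchoring is disabled
                shift = target.best_lag
                reanchors += 1
                if reanchors > 2 * cfg.max_lag:
                    break
                shifted = current.dated_at(current.first_year + shift)
                base = _local_r(current, ref, target.start, target.end, cfg)
                after = _local_r(shifted, ref, target.start, target.end, cfg)
                if base is not None and (after is None or after - base < cfg.epsilon_r):
                    reanchor_ok = False
                    continue
                current = shifted
                steps.append({"reanchor": shift})
                continue
            prev_ok = [
                d.start
                for d in diags
                if d.start < target.start and d.best_lag == 0 and not d.flagged
            ]
            lo = max(prev_ok) if prev_ok else 0
            hi = min(target.end, len(current))
            base_r = _local_r(current, ref, lo, hi, cfg)
            best_r, best_p = -np.inf, None
            for p in range(lo, hi + 1):
                trial = apply_missing(current, [p])
                r = _local_r(trial, ref, lo, hi + 1, cfg)
                if r is not None and r > best_r:  # ties keep earlier position
                    best_r, best_p = r, p
            if best_p is None or (base_r is not None and best_r - base_r < cfg.epsilon_r):
                # a lag >= 2 window can be two missing rings so close
                # together that one insertion barely moves the local fit:
                # trial a joint pair before dismissing the flag as noise.
                # Pair trials are quadratic, so they are rationed and only
                # spent on strong flags (a genuine cluster shows a high
                # best-lag correlation; spurious flags rarely do)
                best_lag_r = target.lag_corr.get(target.best_lag)
                if (
                    target.best_lag >= 2
                    and len(positions) + 2 <= max_missing
                    and pair_attempts < 3
                    and best_lag_r is not None
                    and best_lag_r >= cfg.pair_min_r
                ):
                    pair_attempts += 1
                    pair_r, pair = -np.inf, None
                    for p1 in range(lo, hi + 1):
                        for p2 in range(p1 + 1, hi + 2):
                            trial = apply_missing(current, [p1, p2])
                            r = _local_r(trial, ref, lo, hi + 2, cfg)
                            if r is not None and r > pair_r:
                                pair_r, pair = r, (p1, p2)
                    # two free positions fit noise twice as easily: demand
                    # twice the single-insertion local gain
                    if pair is not None and (
                        base_r is None or pair_r - base_r >= 2 * cfg.epsilon_r
                    ):
                        for p in pair:
                            positions = [q + 1 if q >= p else q for q in positions]
                            positions.append(p)
                            positions.sort()
                        tried.clear()
                        current = apply_missing(current, list(pair))
                        added_this_pass += 2
                        steps.append(
                            {
                                "segment": (target.start, target.end),
                                "best_lag": target.best_lag,
                                "inserted_pair": pair,
                                "local_r_before": base_r,
                                "local_r_after": pair_r,
                            }
                        )
                        continue
                # a flag the trial cannot substantiate is noise: blacklist
                # the window and look at the next one, don't give up outright
                tried.add((target.start, target.end))
                continue
            tried.clear()  # coordinates shift after an insertion
            positions = [q + 1 if q >= best_p else q for q in positions]
            positions.append(best_p)
            positions.sort()
            current = apply_missing(current, [best_p])
            added_this_pass += 1
            steps.append(
                {
                    "segment": (target.start, target.end),
                    "best_lag": target.best_lag,
                    "inserted_at": best_p,
                    "local_r_before": base_r,
                    "local_r_after": best_r,
                }
            )

        # end sweep: a missing ring in the outermost/innermost years
        # misaligns too few rings to flag a window; a trial insertion there
        # is judged on the whole-series t with a strict gate (many end
        # trials, so a lenient gate would capitalize on noise)
        while len(positions) < max_missing:
            cur_t = _whole_series_t(current, ref, cfg)
            n_cur = len(current)
            cand = list(range(0, min(sweep, n_cur))) + list(
                range(max(0, n_cur - sweep), n_cur + 1)
            )
            best_t, best_p = cur_t, None
            for p in cand:
                t = _whole_series_t(apply_missing(current, [p]), ref, cfg)
                if t > best_t:
                    best_t, best_p = t, p
            if best_p is None or best_t - cur_t < cfg.end_epsilon_t:
                break
            positions = [q + 1 if q >= best_p else q for q in positions]
            positions.append(best_p)
            positions.sort()
            current = apply_missing(current, [best_p])
            added_this_pass += 1
            steps.append({"end_sweep": best_p, "t_before": cur_t, "t_after": best_t})

        if added_this_pass == 0:
            break

    # joint refinement: clustered missing rings interact, so each accepted
    # position is re-optimized holding the others fixed (coordinate descent
    # on the whole-series t, bounded to one segment length around it)
    if positions:
        base = series.dated_at(current.first_year)
        for _ in range(2):
            moved = False
            for i in range(len(positions)):
                others = positions[:i] + positions[i + 1 :]
                cur_t = _whole_series_t(apply_missing(base, positions), ref, cfg)
                lo = max(0, positions[i] - cfg.segment_len)
                hi = min(len(base) + len(positions), positions[i] + cfg.segment_len)
                best_t, best_p = cur_t, positions[i]
                for p in range(lo, hi):
                    if p in others:
                        continue
                    t = _whole_series_t(apply_missing(base, others + [p]), ref, cfg)
                    if t > best_t + 1e-9:
                        best_t, best_p = t, p
                if best_p != positions[i]:
                    positions[i] = best_p
                    positions.sort()
                    moved = True
            if not moved:
                break
        # two interacting insertions can sit in a jointly wrong local
        # optimum that one-at-a-time moves cannot leave: re-optimize the
        # pair jointly over a bounded window (affordable up to moderate n)
        if len(positions) == 2 and len(base) <= 400:
            lo = max(0, positions[0] - cfg.segment_len)
            hi = min(len(base) + 2, positions[1] + cfg.segment_len)
            best_t = _whole_series_t(apply_missing(base, positions), ref, cfg)
            best_pair = tuple(positions)
            for p1 in range(lo, hi):
                for p2 in range(p1 + 1, hi):
                    t = _whole_series_t(apply_missing(base, [p1, p2]), ref, cfg)
                    if t > best_t + 1e-9:
                        best_t, best_pair = t, (p1, p2)
            positions = list(best_pair)

        # backward elimination: every insertion must pay its way on the
        # whole-series t — local-gain gates can admit a spurious extra ring
        # that a parsimony check on the full series exposes
        pruned = True
        while pruned and positions:
            pruned = False
            cur_t = _whole_series_t(apply_missing(base, positions), ref, cfg)
            for i, p in enumerate(positions):
                rest = [q - 1 if q > p else q for q in positions[:i] + positions[i + 1 :]]
                if _whole_series_t(apply_missing(base, rest), ref, cfg) >= (
                    cur_t - cfg.insertion_penalty
                ):
                    positions = rest
                    steps.append({"pruned": p})
                    pruned = True
                    break
        current = apply_missing(base, positions)

    score_after = _whole_series_t(current, ref, cfg)
    shift = current.first_year - series.first_year
    if (positions or shift) and score_after < score_before:
        return MissingRingHypothesis(
            positions=[],
            score_before=score_before,
            score_after=score_before,
            segments=first_segments if first_segments is not None else [],
            steps=steps + [{"rejected": "whole-series t deteriorated"}],
        )
    return MissingRingHypothesis(
        positions=positions,
        score_before=score_before,
        score_after=score_after,
        segments=first_segments if first_segments is not None else [],
        steps=steps,
        anchor_shift=shift,
    )


def exhaustive_missing_search(
    series: RingSeries,
    reference: Union[IndexedSeries, Chronology],
    max_k: int = 2,
    cfg: MissingRingConfig = MissingRingConfig(),
) -> tuple[list[int], float]:
    """Brute-force search over all <= ``max_k`` simultaneous insertions.

    Slow verification mode: enumerates every position set of size 0..max_k
    (result-series coordinates) and returns the set maximizing the
    whole-series t-value, ties toward fewer and earlier insertions.  Usable
    only on short series; serves as the oracle for the greedy search.
    """
    ref = _as_reference(reference)
    best_pos: list[int] = []
    best_t = _whole_series_t(series, ref, cfg)
    n = len(series)
    for k in range(1, max_k + 1):
        for combo in itertools.combinations(range(n + k), k):
            t = _whole_series_t(apply_missing(series, combo), ref, cfg)
            if t > best_t + 1e-12:
                best_t, best_pos = t, list(combo)
    return best_pos, best_t
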