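"""End-to-end hierarchical dating workflow.

Cross-dating proceeds hierarchically: radii are reconciled within a disk,
disks are dated against the site chronology, missing rings are proposed and
inserted, and each sample receives an age report.  The reported age is the
cross-dated ring count at the sampling point — pith offset and any
unmeasured inner wood are never added, so every report carries the fixed
caveat that the individual's true age exceeds the reported age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .chronology import build_chronology
from .core import (
    AGE_CAVEAT,
    AgeReport,
    Chronology,
    DatingError,
    IndexedSeries,
    RingFlag,
    RingSeries,
    Status,
    ValidationError,
)
from .crossdate import SlideConfig, bp_tvalue, glk, overlap_corr, slide_date
from .missing import MissingRingConfig, apply_missing, propose_missing
from .standardize import index_series

__all__ = ["PipelineConfig", "merge_radii", "date_and_report", "site_summary"]

#: Informational pith-offset range carried on reports (never added to ages).
PITH_OFFSET_INFO = "unmeasured inner portion estimated at 10-200 years (informational only)"


@dataclass(frozen=True)
class PipelineConfig:
    slide: SlideConfig = field(default_factory=SlideConfig)
    missing: MissingRingConfig = field(default_factory=MissingRingConfig)
    max_missing: int = 10
    provisional_t: float = 2.0  # floor for candidates worth correcting
    max_candidates: int = 25  # distinct provisional placements to correct
    decisive_t: float = 8.0  # corrected t that settles the placement outright
    insertion_penalty: float = 1.0  # t handicap per insertion when selecting
    # and gating placements: searching ~25 basins with free insertions
    # inflates the null well beyond a single slide, and a spurious insertion
    # on noise buys up to ~1.3 in t
    min_separation: float = 1.0  # winner must beat the runner-up by this
    radius_min_overlap: int = 50  # for radius-vs-radius reconciliation


def _radius_slide_cfg(cfg: PipelineConfig, shorter: int) -> SlideConfig:
    mo = max(10, min(cfg.radius_min_overlap, shorter - 10))
    return replace(cfg.slide, min_overlap=mo, offset_range=None)


def merge_radii(
    radii: Sequence[RingSeries],
    cfg: PipelineConfig = PipelineConfig(),
) -> RingSeries:
    """Reconcile 1-4 radii from one disk into a single sample series.

    The longest radius anchors a provisional calendar; every other radius is
    slid against it and must place significantly (otherwise a
    :class:`DatingError` lists the best candidates — the operator decides,
    the code never silently guesses).  Missing-ring proposals are allowed
    per radius during reconciliation.  The merged series spans the union of
    the dated radii; each year carries the mean of the measured widths, and
    years measured on no radius become inserted missing rings.  If the
    anchor was undated the result is returned undated (relative calendar).
    """
    radii = list(radii)
    if not 1 <= len(radii) <= 4:
        raise ValidationError("a disk has one to four radii")
    sample_ids = {r.sample_id for r in radii}
    if len(sample_ids) != 1:
        raise ValidationError(f"radii from different samples: {sorted(sample_ids)}")
    if len(radii) == 1:
        return radii[0]

    anchor = max(radii, key=len)
    was_dated = anchor.first_year is not None
    anchor = anchor if was_dated else anchor.dated_at(0)
    anchor_idx = index_series(anchor, cfg.missing.indexing)

    dated: list[RingSeries] = [anchor]
    others = [r for r in radii if r.series_id != anchor.series_id]
    for r in others:
        scfg = _radius_slide_cfg(cfg, min(len(r), len(anchor)))
        cands = slide_date(r, anchor_idx, scfg)
        if not cands or not cands[0].significant:
            top = [
                (c.candidate_first_year, round(c.tvalue, 2), c.glk) for c in cands[:5]
            ]
            raise DatingError(
                f"radius {r.series_id!r} cannot be reconciled with anchor "
                f"{anchor.series_id!r} above significance thresholds; best "
                f"candidates (first_year, t, glk): {top}"
            )
        dated.append(r.dated_at(cands[0].candidate_first_year))

    # symmetric reconciliation: each radius (the anchor included — its own
    # wedged sectors show up against the others) is checked for missing
    # rings against the mean of the remaining radii, repeated until stable
    for _ in range(2):
        changed = False
        for i, s in enumerate(dated):
            others = dated[:i] + dated[i + 1 :]
            if len(others) == 1:
                ref_i = index_series(others[0], cfg.missing.indexing)
            else:
                ref_i = build_chronology(
                    [index_series(o, cfg.missing.indexing) for o in others]
                ).to_indexed()
            hyp = propose_missing(s, ref_i, max_missing=3, cfg=cfg.missing)
            if hyp.anchor_shift:
                s = s.dated_at(s.first_year + hyp.anchor_shift)
            if hyp.positions:
                s = apply_missing(s, hyp.positions)
            if hyp.anchor_shift or hyp.positions:
                dated[i] = s
                changed = True
        if not changed:
            break

    first = min(s.first_year for s in dated)
    last = max(s.first_year + len(s) - 1 for s in dated)
    n = last - first + 1
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for s in dated:
        off = s.first_year - first
        meas = s.measured_mask
        idx = np.flatnonzero(meas) + off
        sums[idx] += s.widths[meas]
        counts[idx] += 1
    widths = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    flags = np.where(counts > 0, RingFlag.MEASURED, RingFlag.MISSING_INSERTED).astype(np.int8)

    proto = radii[0]
    return RingSeries(
        series_id=f"{proto.sample_id}M",
        widths=widths,
        ring_flags=flags,
        first_year=first if was_dated else None,
        sample_id=proto.sample_id,
        site_id=proto.site_id,
        radius_no=1,
        status=proto.status,
    )


def date_and_report(
    sample: RingSeries,
    reference: Union[Chronology, IndexedSeries],
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[RingSeries, AgeReport]:
    """Date one sample against the reference and produce its age report.

    Workflow: slide to the best significant placement, propose and insert
    missing rings, re-slide the corrected series, report.  With no
    significant placement the report is marked undated and no age is
    claimed — undatable samples are first-class outcomes.
    """
    ref = reference.to_indexed() if isinstance(reference, Chronology) else reference
    undated_sample = sample.dated_at(None)

    def _undated_report() -> tuple[RingSeries, AgeReport]:
        rep = AgeReport(
            sample_id=sample.sample_id,
            n_measured=sample.n_measured,
            n_missing=sample.n_missing,
            age_years=None,
            first_year=None,
            last_year=None,
            dated=False,
            status=sample.status,
            site_id=sample.site_id,
            pith_offset_info=PITH_OFFSET_INFO,
        )
        return undated_sample, rep

    def _stats(s: RingSeries) -> tuple[float, Optional[float], int]:
        idx = index_series(s, cfg.missing.indexing)
        off = s.first_year - ref.first_year
        r, n = overlap_corr(idx, ref, off, cfg.slide.min_overlap)
        if r is None or n <= 2:
            return -np.inf, None, n
        return bp_tvalue(r, n), glk(idx, ref, off), n

    # An uncorrected sample can fail the significance gates purely because of
    # its own missing rings (every ring after an absent year is misaligned),
    # so a generous pool of provisional candidates is corrected first and
    # only the corrected series is judged against both gates.
    # missing-ring correction converges from placements a few years off, so
    # candidates within +-3 years of an already-selected one add nothing
    cands = slide_date(undated_sample, ref, cfg.slide)
    provisional: list = []
    for c in cands:
        if c.tvalue < cfg.provisional_t or len(provisional) >= cfg.max_candidates:
            break
        if all(abs(c.candidate_first_year - p.candidate_first_year) > 3 for p in provisional):
            provisional.append(c)
    if not provisional:
        return _undated_report()

    # candidates are compared on a parsimony-penalized score: a wrong
    # placement can buy t with many spurious insertions, a right one needs
    # few — the penalty makes the difference decisive
    best: Optional[RingSeries] = None
    scores: list[float] = []
    penalty = cfg.insertion_penalty
    for c in provisional:
        placed = sample.dated_at(c.candidate_first_year)
        hyp = propose_missing(placed, ref, max_missing=cfg.max_missing, cfg=cfg.missing)
        if hyp.anchor_shift:
            placed = placed.dated_at(placed.first_year + hyp.anchor_shift)
        if hyp.positions:
            placed = apply_missing(placed, hyp.positions)
        t, _, _ = _stats(placed)
        score = t - penalty * (len(hyp.positions) + abs(hyp.anchor_shift))
        scores.append(score)
        if score > max(scores[:-1], default=-np.inf):
            best = placed
        if score >= cfg.decisive_t:
            # a corrected placement this strong (even after paying for its
            # insertions) is never beaten by a pumped wrong placement
            break

    # final significance: the t-value must clear the acceptance threshold
    # net of the insertion penalty (agreement bought with inserted rings
    # cannot date an undatable sample), the GLK gate must pass, and the
    # winner must clearly beat the runner-up — an ambiguous date is no date
    ordered = sorted(scores, reverse=True)
    best_score = ordered[0]
    second = ordered[1] if len(ordered) > 1 else -np.inf
    separated = best_score >= cfg.decisive_t or best_score - second >= cfg.min_separation
    _, g, _ = _stats(best)
    if not (
        best_score >= cfg.slide.accept_t
        and g is not None
        and g >= cfg.slide.accept_glk
        and separated
    ):
        return _undated_report()
    placed = best

    report = AgeReport(
        sample_id=placed.sample_id,
        n_measured=placed.n_measured,
        n_missing=placed.n_missing,
        age_years=len(placed),
        first_year=placed.first_year,
        last_year=placed.last_year,
        dated=True,
        status=placed.status,
        site_id=placed.site_id,
        pith_offset_info=PITH_OFFSET_INFO,
    )
    return placed, report


def site_summary(reports: Sequence[AgeReport]) -> pd.DataFrame:
    """Per-site summary: maximum age, individuals sampled, living/dead split.

    Maxima only — with an oldest-looking-individual sampling strategy the
    population age structure cannot be inferred, so nothing beyond the
    maximum is claimed.  Undatable samples stay in the counts with no age.
    """
    if not reports:
        raise ValidationError("need at least one report")
    rows = []
    for site, grp in _groupby_site(reports).items():
        ages = [r.age_years for r in grp if r.dated]
        n = len(grp)
        living = sum(1 for r in grp if r.status == Status.LIVING)
        dead = sum(1 for r in grp if r.status == Status.DEAD)
        rows.append(
            {
                "site_id": site,
                "n_sampled": n,
                "max_age_years": max(ages) if ages else None,
                "n_dated": len(ages),
                "n_undated": n - len(ages),
                "pct_living": 100.0 * living / n,
                "pct_dead": 100.0 * dead / n,
            }
        )
    return pd.DataFrame(sorted(rows, key=lambda r: r["site_id"])).reset_index(drop=True)


def _groupby_site(reports: Sequence[AgeReport]) -> dict[str, list[AgeReport]]:
    out: dict[str, list[AgeReport]] = {}
    for r in reports:
        out.setdefault(r.site_id or "", []).append(r)
    return out
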