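"""Synthetic juniper-like ring-width populations with known ground truth.

The generator emulates the statistical structure the dating pipeline
assumes about slow-growing tundra junipers:

* a shared site-level climate signal C_t ~ AR(1)(phi_c), and per-individual
  noise e_it ~ AR(1)(phi_i), both standardized; the composite signal is
  z = sqrt(a)*C + sqrt(1-a)*e so that ``a`` (the signal share) is the
  expected inter-series correlation;
* multiplicative lognormal variability around a declining age trend,
  width(t) = (A*exp(-t/tau) + B) * exp(sigma * z_t), giving strictly
  positive, realistically skewed widths with a measurement floor;
* missing rings: a ring is absent when its width falls below the
  measurement floor, topped up by independent random deletions so the
  realized missing rate matches the configured target; missing rings are
  *deleted* from the emitted series (the detector faces the real problem)
  and only the truth table records where they were;
* one to four radii per disk sharing the disk's widths plus small
  independent noise, with radius-specific wedging sectors (short runs of
  locally absent rings).

Everything is reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import IndexedSeries, RingSeries, Status, ValidationError, make_series
from .tucson import HUNDREDTHS, write_tucson

__all__ = [
    "GeneratorConfig",
    "SeriesTruth",
    "SyntheticTruth",
    "generate_site",
    "export_fixture",
    "load_truth_table",
    "restore_series",
]


@dataclass(frozen=True)
class GeneratorConfig:
    n_samples: int = 20
    radii_per_sample: tuple[int, int] = (1, 4)
    length_range: tuple[int, int] = (150, 1700)
    signal_share: float = 0.5  # a: share of variance from the site signal
    climate_ar1: float = 0.5  # phi_c
    noise_ar1: float = 0.3  # phi_i
    sigma: float = 0.3  # lognormal sigma of the width process
    trend_a: float = 0.8  # mm, initial level of the age trend
    trend_tau: float = 100.0  # yr, e-folding time of the age trend
    trend_b: float = 0.05  # mm, asymptotic width
    missing_rate: float = 0.03  # target fraction of absent rings per disk
    missing_run_length: int = 1  # clustering hook: run length of deletions
    measurement_floor: float = 0.01  # mm
    radius_noise_sigma: float = 0.1
    wedging_prob: float = 0.3  # per-radius chance of one wedging sector
    wedging_max_len: int = 3
    living_fraction: float = 0.7
    dead_end_gap: tuple[int, int] = (10, 300)  # years before present a dead stem died
    present_year: int = 2020
    site_id: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal_share <= 1.0):
            raise ValidationError("signal_share must be in [0, 1]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValidationError("missing_rate must be in [0, 1]")
        if not (-1 < self.climate_ar1 < 1 and -1 < self.noise_ar1 < 1):
            raise ValidationError("AR(1) coefficients must lie in (-1, 1)")
        if min(self.trend_a, self.trend_b, self.trend_tau) <= 0:
            raise ValidationError("age-trend parameters must be positive")
        if not (1 <= self.radii_per_sample[0] <= self.radii_per_sample[1] <= 4):
            raise ValidationError("radii_per_sample must be within 1-4")


@dataclass
class SeriesTruth:
    """Ground truth for one emitted radius series."""

    series_id: str
    sample_id: str
    radius_no: int
    status: Status
    disk_first_year: int  # year of the disk's innermost (pre-deletion) ring
    disk_length: int  # full ring count before any deletion
    deleted: tuple[int, ...]  # deleted positions as indices into the full disk
    first_year: int  # true year of the emitted series' first ring
    expected_insertions: tuple[int, ...]  # interior deletions, restored coords


@dataclass
class SyntheticTruth:
    """Everything needed to score a recovery experiment without re-running
    the generator: per-series truth plus the latent site signal."""

    site_id: str
    climate: np.ndarray
    climate_first_year: int
    records: dict[str, SeriesTruth] = field(default_factory=dict)

    def climate_series(self) -> IndexedSeries:
        """The latent site signal as a dated indexed series (the true master)."""
        return IndexedSeries(
            source_id=f"{self.site_id}_climate",
            index=self.climate.copy(),
            valid=np.ones(self.climate.size, dtype=bool),
            first_year=self.climate_first_year,
        )

    def date(self, series: RingSeries) -> RingSeries:
        """Copy of an emitted series anchored at its true first year.

        Interior deletions are *not* restored, so rings after a deleted year
        remain one year off — use :meth:`restore` for a fully aligned copy.
        """
        return series.dated_at(self.records[series.series_id].first_year)

    def restore(self, series: RingSeries) -> RingSeries:
        """Truth-dated copy with missing rings re-inserted at their true
        interior positions — every ring aligned to its calendar year."""
        from .missing import apply_missing  # local import avoids a cycle

        rec = self.records[series.series_id]
        dated = series.dated_at(rec.first_year)
        if not rec.expected_insertions:
            return dated
        return apply_missing(dated, list(rec.expected_insertions))


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized AR(1): marginal variance 1."""
    x = np.empty(n)
    x[0] = rng.normal()
    innov_sd = np.sqrt(1.0 - phi * phi)
    eps = rng.normal(scale=innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def _choose_missing(
    widths: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator
) -> set[int]:
    """Floor-forced deletions plus a random top-up to the target rate."""
    n = widths.size
    floor_miss = set(np.flatnonzero(widths < cfg.measurement_floor).tolist())
    target = int(round(cfg.missing_rate * n))
    if cfg.missing_rate == 0.0 and floor_miss:
        raise ValidationError(
            "missing_rate 0 is impossible: the measurement floor already forces "
            f"{len(floor_miss)} missing rings — raise the rate or the trend floor"
        )
    missing = set(floor_miss)
    candidates = [i for i in range(n) if i not in missing]
    rng.shuffle(candidates)
    ci = 0
    while len(missing) < target and ci < len(candidates):
        start = candidates[ci]
        ci += 1
        if start in missing:
            continue
        run = range(start, min(start + cfg.missing_run_length, n))
        for p in run:
            if len(missing) < target:
                missing.add(p)
    return missing


def _emit(
    widths: np.ndarray, missing: set[int], floor: float
) -> tuple[np.ndarray, list[int]]:
    keep = [i for i in range(widths.size) if i not in missing]
    w = np.maximum(widths[keep], floor)  # survivors never dip below the floor
    return w, keep


def generate_site(cfg: GeneratorConfig) -> tuple[list[RingSeries], SyntheticTruth]:
    """Generate one site: ``n_samples`` disks, 1-4 radii each, plus truth.

    Emitted series are undated (``first_year is None``) — recovering the
    calendar placement is the pipeline's job; :class:`SyntheticTruth` holds
    the answers.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    span = cfg.length_range[1] + cfg.dead_end_gap[1] + 50
    climate_first = cfg.present_year - span + 1
    climate = _ar1(span, cfg.climate_ar1, rng)
    truth = SyntheticTruth(cfg.site_id, climate, climate_first)
    a = cfg.signal_share

    series_out: list[RingSeries] = []
    for si in range(cfg.n_samples):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        living = rng.random() < cfg.living_fraction
        status = Status.LIVING if living else Status.DEAD
        last = cfg.present_year if living else cfg.present_year - int(
            rng.integers(cfg.dead_end_gap[0], cfg.dead_end_gap[1] + 1)
        )
        first = last - L + 1
        c_win = climate[first - climate_first : last - climate_first + 1]
        e = _ar1(L, cfg.noise_ar1, rng)
        z = np.sqrt(a) * c_win + np.sqrt(1.0 - a) * e
        t = np.arange(L)
        trend = cfg.trend_a * np.exp(-t / cfg.trend_tau) + cfg.trend_b
        disk_widths = trend * np.exp(cfg.sigma * z)
        disk_missing = _choose_missing(disk_widths, cfg, rng)

        sample_id = f"{cfg.site_id[:1]}{si:03d}"
        n_radii = int(rng.integers(cfg.radii_per_sample[0], cfg.radii_per_sample[1] + 1))
        for r in range(1, n_radii + 1):
            rw = disk_widths * np.exp(cfg.radius_noise_sigma * rng.normal(size=L))
            missing = set(disk_missing)
            if rng.random() < cfg.wedging_prob:
                w_len = int(rng.integers(1, cfg.wedging_max_len + 1))
                w_start = int(rng.integers(0, max(1, L - w_len)))
                missing.update(range(w_start, w_start + w_len))
            if len(missing) >= L:
                missing = set(sorted(missing)[: L - 1])
            w, keep = _emit(rw, missing, cfg.measurement_floor)
            sid = f"{sample_id}R{r}"
            deleted = tuple(sorted(missing))
            first_kept, last_kept = keep[0], keep[-1]
            expected = tuple(
                d - first_kept for d in deleted if first_kept < d < last_kept
            )
            s = make_series(
                sid,
                w,
                first_year=None,
                sample_id=sample_id,
                site_id=cfg.site_id,
                radius_no=r,
                status=status,
            )
            series_out.append(s)
            truth.records[sid] = SeriesTruth(
                series_id=sid,
                sample_id=sample_id,
                radius_no=r,
                status=status,
                disk_first_year=first,
                disk_length=L,
                deleted=deleted,
                first_year=first + first_kept,
                expected_insertions=expected,
            )
    return series_out, truth


def export_fixture(
    series: list[RingSeries], truth: SyntheticTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write the site as ``site.rwl`` (truth-dated) plus ``truth.csv``.

    Output is byte-identical for identical inputs (integer ring counts in
    the .rwl, fixed-format truth rows), so fixtures regenerate exactly from
    the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dated = [truth.date(s) for s in series]
    rwl_path = out / "site.rwl"
    rwl_path.write_text(write_tucson(dated, HUNDREDTHS))

    rows = ["series_id,sample_id,radius_no,status,first_year,disk_first_year,disk_length,deleted"]
    for s in series:
        rec = truth.records[s.series_id]
        rows.append(
            f"{rec.series_id},{rec.sample_id},{rec.radius_no},{rec.status.value},"
            f"{rec.first_year},{rec.disk_first_year},{rec.disk_length},"
            f"{';'.join(map(str, rec.deleted))}"
        )
    truth_path = out / "truth.csv"
    truth_path.write_text("\n".join(rows) + "\n")
    return {"rwl": rwl_path, "truth": truth_path}


def load_truth_table(path: str | Path) -> dict[str, SeriesTruth]:
    """Read an exported truth.csv back into per-series truth records."""
    records: dict[str, SeriesTruth] = {}
    lines = Path(path).read_text().strip().splitlines()
    for line in lines[1:]:
        sid, sample_id, radius_no, status, first, disk_first, disk_len, deleted = (
            line.split(",")
        )
        dels = tuple(int(x) for x in deleted.split(";")) if deleted else ()
        first, disk_first, disk_len = int(first), int(disk_first), int(disk_len)
        first_kept = first - disk_first
        kept_last = max(i for i in range(disk_len) if i not in set(dels))
        records[sid] = SeriesTruth(
            series_id=sid,
            sample_id=sample_id,
            radius_no=int(radius_no),
            status=Status(status),
            disk_first_year=disk_first,
            disk_length=disk_len,
            deleted=dels,
            first_year=first,
            expected_insertions=tuple(
                d - first_kept for d in dels if first_kept < d < kept_last
            ),
        )
    return records


def restore_series(series: RingSeries, rec: SeriesTruth) -> RingSeries:
    """Truth-dated copy with missing rings re-inserted at their recorded
    interior positions (see :meth:`SyntheticTruth.restore`)."""
    from .missing import apply_missing

    dated = series.dated_at(rec.first_year)
    if not rec.expected_insertions:
        return dated
    return apply_missing(dated, list(rec.expected_insertions))
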