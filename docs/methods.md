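# Methods

`dendrodate` implements the analysis chain by which very slow-growing woody
plants — prostrate tundra junipers being the motivating case — are assigned
calendar ages from ring-width measurements: high-pass indexing,
cross-dating statistics, sliding calendar placement, missing-ring
detection, robust mean chronologies, and per-sample age reports, plus a
synthetic generator with ground truth so every stage can be validated
without field data.

## Data model and calendar conventions

A `RingSeries` stores one measured radius (or a merged sample series) as
widths in millimetres, innermost ring first; ring `i` of a dated series
formed in year `first_year + i`. A missing ring — a year with no detectable
ring on the measured radius — is represented in-band as width 0.0 plus a
`MISSING_INSERTED` flag, never as a gap, which keeps year arithmetic
positional and matches the Tucson format's zero convention. Width 0 is
*reserved* for that meaning: measurement input with a literal zero is
rejected rather than silently reinterpreted.

Ages are reported as `n_measured + n_missing`, the cross-dated ring count
at the sampling point. No allowance is ever added for pith offset or an
unmeasured inner portion; every report carries a fixed caveat that the true
age of the plant exceeds the reported age, and an optional informational
field can carry an offset range without touching the age.

## High-pass indexing

Cross-dating must compare year-to-year variation, not age trend or
individual vigor, so widths are converted to a dimensionless index first.

* `moving_ratio` (default, window 5): `index[t] = width[t] /` centred
  moving average. The `(window−1)/2` edge positions are invalid. The moving
  average is taken over *measured* rings only, so an inserted zero cannot
  distort its neighbours' index values — this also makes the index exactly
  scale-invariant.
* `log_diff`: first difference of log widths, clamped below by
  `zero_replacement` (default 0.005 mm, half the smallest positive width of
  the hundredths-mm dialect). Position 0, missing positions, and positions
  whose predecessor is missing are invalid.

Invalid positions are excluded from every downstream statistic, never
imputed: fabricating agreement at series ends — exactly where dating is
weakest — is worse than losing a few years of overlap.

## Cross-dating statistics

Over the jointly valid overlap of two indexed series:

* **GLK** (Gleichläufigkeit): mean sign agreement of first differences,
  ties (either difference exactly 0) scoring ½. Symmetric in its arguments,
  bounded in [0, 1], undefined rather than numeric when fewer than two
  difference pairs are valid.
* **Pearson r** with the overlap length `n`; undefined below a configurable
  minimum overlap (default 50 years) or when either window has zero
  variance.
* **t-value**: `t = r·√(n−2)/√(1−r²)`, the correlation as a t statistic on
  `n−2` degrees of freedom. Signed: inverted matches rank last and are
  never flagged significant. `|r| ≥ 1` returns a large sentinel
  (10⁶, signed) with a warning instead of overflowing.

`slide_date` evaluates every candidate first year with sufficient overlap
and ranks by t (ties: larger GLK, larger overlap, smaller |first year|).
The ranking key is t because it integrates overlap length; GLK acts as a
confirmatory gate. A placement is *significant* when `t ≥ accept_t`
(default 3.5) and `GLK ≥ accept_glk` (default 0.60) — conventional
screening values, configurable and echoed in output.

## Missing-ring detection

A locally absent ring shifts every later ring one year early, so the
series' lag profile against a reference is a non-decreasing step function:
0 before the first absent year, +1 after it, and so on. The detector
(`propose_missing`) repairs this profile left to right:

1. **Flagging.** Segments (length 50, scanned densely at step 5, plus
   half-length windows that resolve transitions near the ends and tight
   clusters) are correlated with the reference at lags −3…+3; a segment is
   flagged when its best lag is nonzero and beats lag 0 by ≥ 0.10 in r.
2. **Local trial.** For the earliest positively-lagged flag, an insertion
   is trialled at every position between the last well-dated segment and
   the flag's end, scored by the *local window's* lag-0 correlation. The
   whole-series t is deliberately not the step objective: it is nearly flat
   in the insertion position, and with clustered missing rings a single
   correct insertion can lower it transiently (a misaligned block moving
   from lag 3 to lag 2 correlates more negatively under the index's
   oscillating autocorrelation). A step is kept when it gains ≥ 0.05 in
   local r; a flag whose trial fails is blacklisted, not fatal.
   Flags with lag ≥ 2 whose single-insertion trial fails get one joint
   pair trial (two deletions can sit so close that one insertion barely
   moves the local fit); pair trials are rationed and require a strong
   best-lag correlation (≥ 0.45) plus double the local gain.
3. **Re-anchoring.** A negative lag at the very start means the slide
   overshot (a deletion can never produce a negative lag), so the
   provisional first year is shifted rather than the series edited; the
   shift must improve the flagged window itself, otherwise re-anchoring is
   disabled for the run. Mid-series negative flags are noise and ignored.
4. **End sweep.** A missing ring within ~20 rings of either end misaligns
   too few rings to flag a window; trial insertions there are accepted on
   the whole-series t with a strict gate (0.6) because many end trials
   would otherwise capitalize on noise.
5. **Refinement.** Accepted positions are re-optimized by bounded
   coordinate descent on the whole-series t, plus a joint 2-opt when
   exactly two insertions were made (interacting pairs have jointly wrong
   local optima); finally each insertion must pay ≥ 0.5 in whole-series t
   or it is pruned (backward elimination).

The accepted hypothesis must not have decreased the whole-series t-value;
its audit trail records every flag, trial, re-anchor, and pruning.
`exhaustive_missing_search` enumerates all ≤ 2 simultaneous insertions and
serves as the test oracle for the greedy search on short series.
Insertion positions index the *result* series — the slots that end up
flagged missing — so adjacent missing rings are expressible while duplicate
positions remain an error.

The detector is purely statistical and makes no climatic assumption, since
locally absent rings in junipers are not confined to extreme years.

## Chronology building

Chronologies are built on indexed series, never raw widths (age-trend and
vigor differences would dominate otherwise). Per year the value is the
Tukey biweight robust mean (tuning constant 9, one-pass, median/MAD
centred) of the contributing valid indices when sample depth ≥ 4, and the
arithmetic mean at lower depth where the biweight is unstable; both the
value and the per-year depth are recorded. Quality diagnostics follow
standard practice: rbar (mean pairwise Pearson r over a window, pairs with
< 30 jointly valid years skipped) and EPS = n·rbar/(n·rbar + (1 − rbar))
with n the mean depth.

## Hierarchical dating pipeline

`merge_radii` reconciles the one-to-four radii of a disk: the longest
radius anchors a provisional calendar, the others must place significantly
against it (an irreconcilable radius raises an error listing the best
candidates — the operator decides, never the code), and each radius —
anchor included — is checked for missing rings against the mean of the
others until stable. The merged sample series spans the union of the dated
radii, carries the mean of the measured widths per year, and marks years
measured on no radius as inserted missing rings.

`date_and_report` dates a sample against the chronology. Because a
sample's own missing rings depress its raw statistics below the
significance gates, up to 25 provisionally accepted placements (raw
t ≥ 2.0, de-duplicated to distinct ±3-year basins) are corrected first and
only the corrected series is judged. Candidates are compared on a
parsimony-penalized score, t − 1.0 per insertion or anchor shift: a wrong
placement can buy t with many spurious insertions (up to ~1.3 each on
noise) while a right one needs few, and with ~25 basins searched the
unpenalized null is far above a single slide's. The final significance
gate applies the same penalized t against `accept_t` together with the GLK
gate, so agreement bought with inserted rings cannot date an undatable
sample; a sample with no significant corrected placement is reported
undated — a first-class outcome, never dropped. Dead (relic) samples are
dated identically to living ones; their candidate range simply extends
earlier than the living span.

`site_summary` reports, per site: maximum age, individuals sampled, and
the living/dead percentage split. Maxima only — an oldest-looking-
individual sampling strategy supports no inference about population age
structure.

## Synthetic generator

`generate_site` emulates the statistical structure the pipeline assumes:

| parameter | default | meaning |
| --- | --- | --- |
| `n_samples` | 20 | disks per site |
| `radii_per_sample` | 1–4 | radii measured per disk |
| `length_range` | 150–1700 yr | disk ring counts |
| `signal_share` (a) | 0.5 | variance share of the site signal |
| `climate_ar1` / `noise_ar1` | 0.5 / 0.3 | AR(1) coefficients of signal / individual noise |
| `sigma` | 0.3 | lognormal width sigma |
| `trend_a`, `trend_tau`, `trend_b` | 0.8 mm, 100 yr, 0.05 mm | age trend A·e^(−t/τ)+B |
| `missing_rate` | 0.03 | target absent-ring fraction (order of 35/1176) |
| `measurement_floor` | 0.01 mm | widths below it are absent |
| `radius_noise_sigma` | 0.1 | per-radius lognormal noise |
| `wedging_prob`, `wedging_max_len` | 0.3, 3 | per-radius wedging sector |
| `living_fraction` | 0.7 | dead stems end 10–300 yr before present |

Widths are `trend(t)·exp(sigma·z)` with `z = √a·C + √(1−a)·e`, both
AR(1) and standardized, so `a` is the expected inter-series correlation at
the z level. Rings are absent when the width falls below the floor,
topped up by independent random deletions to the target rate; absent rings
are *deleted* from the emitted series (the detector faces the real
problem) and only the truth table records them. Radii share the disk's
widths plus small independent noise and radius-specific wedging deletions.
Everything is reproducible from one seed via deterministic substreams, and
`export_fixture` writes byte-identical files for identical inputs.

What the generator does **not** emulate: real covariance between ring
narrowness and ring absence beyond the measurement floor (top-up deletions
are independent of width, whereas real missing rings cluster in narrow
years), runs of consecutive missing years (the clustering hook defaults to
run length 1), disturbance histories, and any climate realism beyond AR(1)
persistence. Passing tests therefore demonstrate the statistical machinery
under a known model, not performance on any particular field data set.

A subtlety the tests respect: rbar between *indexed* series equals `a`
exactly only when signal and noise share a spectrum (equal AR
coefficients); with the defaults (0.5 vs 0.3) the high-pass reweights the
split and indexed rbar sits near 0.40 at a = 0.5. The recovery test
therefore uses matched spectra; the defaults are kept for realism.

## Numerical choices and degenerate inputs

Ties in `slide_date` break by GLK, then overlap, then smaller |first
year|; ties in insertion trials break toward the earlier position — all
deterministic. Undefined statistics (short overlap, zero variance) return
`None` rather than NaN so callers must handle them explicitly. Tucson
output quantizes any positive width smaller than one resolution quantum to
one count, never 0 (0 would fabricate a missing ring); series ids longer
than 8 characters truncate deterministically and a collision is an error.
Series shorter than one scan segment are scanned whole with a warning.

## Known limitations

* **End-zone missing rings are near-invisible.** A missing ring within
  ~10 rings of either end of a series misaligns too few rings to detect
  against a reference of typical quality (inter-series r ≈ 0.6), and a
  deletion at ring 1 is formally indistinguishable from a one-year anchor
  shift. With uniformly placed deletions this caps exact whole-population
  first-year-and-age recovery near 55–75% even though interior deletions
  localize to ±1 ring in ≈ 98–100% of cases. Real studies mitigate this
  with anatomical inspection near the pith and bark, which no statistical
  detector replaces.
* Localization against *noisy* references is intrinsically coarser: even
  the exact maximum-likelihood argmax achieves only ~47% within ±1 against
  a reference carrying half the series' variance.
* The greedy detector can in principle miss configurations the exhaustive
  oracle finds for > 2 simultaneous insertions in one 50-ring window.
* The pipeline's thresholds (accept_t 3.5, accept_glk 0.60, penalties 0.5
  and 1.0) are screening conventions, not calibrated error rates; the
  false-positive experiments in the test suite measure their joint
  behaviour under the generator model only.
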