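# dendrodate

Cross-dating and age determination for slow-grown ring-width series —
built for the hardest material dendrochronology handles, such as prostrate
tundra junipers (*Juniperus communis*) whose stems grow a few hundredths of
a millimetre per year, wedge out around the circumference, and skip rings
entirely in bad years. Assigning such a stem a calendar age means matching
its year-to-year width pattern against an independently dated reference,
finding the years in which it produced no measurable ring, and counting
what remains. This package implements that entire chain as a library with
a thin CLI, plus a synthetic ring-width generator with known ground truth
so every stage can be validated at desk scale.

## The statistics at the core

Raw widths are first converted to a dimensionless high-pass index
(default: width over its centred 5-year moving average) so that dating
compares year-to-year variation rather than age trend or vigor. Over the
n-year overlap of two indexed series the package computes the three
classical dating statistics:

* **GLK** (Gleichläufigkeit) — the fraction of years in which the two
  series' first differences share the same sign (ties count ½);
* **r** — the Pearson correlation over the jointly valid overlap;
* **t** = r·√(n−2)/√(1−r²) — the correlation as a t statistic on n−2
  degrees of freedom, the classical dating score because it integrates
  overlap length.

`slide_date` ranks every admissible calendar placement by t; a placement
is significant when t ≥ 3.5 and GLK ≥ 0.60 (configurable, always echoed in
output). A missing ring reveals itself as a step in the lag profile —
every later ring matches the reference one year late — and
`propose_missing` repairs the profile left to right, with an audit trail,
an exhaustive small-case oracle, and a parsimony rule that makes every
inserted ring pay for itself. Chronologies are Tukey-biweight robust means
with per-year sample depth and rbar/EPS diagnostics. Ages are reported as
measured + inserted missing rings at the sampling point; pith offset is
never added, and every report says so.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data. `python analysis/01_simulate_site.py --seed 1` generates a
20-disk site (ring counts 260–1,696, realized missing-ring rate 0.030);
`02` re-inserts the recorded missing rings and builds the chronology;
`03` cross-dates two samples against it:

```
chronology spans 315-2018 (1704 years)
raw series (missing rings absent): rbar 0.027, EPS 0.470
after re-inserting missing rings:  rbar 0.383, EPS 0.952

[heavy] S018R2: 1645 measured rings, 51 interior missing rings, true first year 313
[heavy] best raw placement 349 (GLK = 0.52; Corr. = 0.10; t-value = 3.9)
[heavy] pipeline verdict: undated (this density of absent years defeats
        rigid alignment; refusing is the correct outcome)
[target] S011R1: 315 measured rings, 3 interior missing rings, true first year 1703
[target] rank-1 placement 1857 (GLK = 0.55; Corr. = 0.30; t-value = 4.0; n = 160)
[target] corrected: 315 measured + 3 missing rings -> age 318 years (1703-2020);
         truth span starts 1703
```

Three things to read off this output. Re-inserting missing rings lifts the
mean inter-series correlation from 0.03 to 0.38 — an uncorrected absent
year decorrelates everything after it, which is why missing-ring work is
the heart of juniper dating. A series with ~50 absent years defeats any
rigid alignment, so the pipeline refuses to date it rather than guess (an
undated report is a first-class outcome). And for the 315-ring sample the
*raw* best placement is wrong (1857), yet correcting the top candidate
placements before judging them recovers the exact true first year, the
three absent years, and therefore the exact age: 315 + 3 = 318 years,
spanning 1703–2020.

`04` audits missing-ring localization (93% of planted deletions recovered
within ±1 ring at seed 1), and `05` runs the full hierarchical pipeline —
radius merging, dating, correction, site summary — on a desk-scale
population, printing a per-site table of maximum age, sample count, and
living/dead split. `06` re-analyses the study's deposited measurement
series if a copy is placed under `data/archive/` (it downloads nothing).

The same operations are available from the shell:
`dendrodate simulate|convert|index|crossdate|missing|chronology|pipeline`.

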