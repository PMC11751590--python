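"""Worked cross-dating example: date samples against the site chronology.

Two cases from the simulated site, each slid (undated, missing rings still
absent as measured) along a chronology built from the *other* samples'
corrected series:

1. the longest radius — at the site's 3% missing-ring rate a
   millennium-scale series carries ~50 absent years, which decorrelates
   every rigid alignment; the pipeline must refuse to date it rather than
   guess (heavy material is dated incrementally with anatomical work, not
   in one statistical shot);
2. a sample from a companion site simulated at desk-scale missing density
   (~1%, two to three absent years per disk) — the regime the statistical
   detector is designed for — slid, corrected, and checked against truth.

At the study's full 3% rate a long series carries dozens of absent years
and *no* rigid alignment survives; such material is dated incrementally
with anatomical work, which is why case 1 must end in a refusal while
case 2 ends in an exact date. Writes the ranked candidate table of case 2
to results/crossdate_candidates.csv.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

import dendrodate as dd
from dendrodate.synthetic import load_truth_table, restore_series

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--rwl", default=ROOT / "results" / "site" / "site.rwl")
    ap.add_argument("--truth", default=ROOT / "results" / "site" / "truth.csv")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default=ROOT / "results" / "crossdate_candidates.csv")
    args = ap.parse_args()

    series = dd.read_tucson(Path(args.rwl).read_text())
    truth = load_truth_table(args.truth)

    def chron_excluding(sample_id):
        pool = [
            restore_series(s, truth[s.series_id])
            for s in series
            if s.sample_id != sample_id
        ]
        return dd.build_chronology([dd.index_series(s) for s in pool])

    # case 1: the longest series, missing rings and all
    heavy = max(series, key=len)
    chron = chron_excluding(heavy.sample_id)
    best = dd.slide_date(heavy.dated_at(None), chron)[0]
    n_miss = len(truth[heavy.series_id].expected_insertions)
    print(f"[heavy] {heavy.series_id}: {len(heavy)} measured rings, "
          f"{n_miss} interior missing rings, true first year "
          f"{truth[heavy.series_id].first_year}")
    print(f"[heavy] best raw placement {best.candidate_first_year} "
          f"(GLK = {best.glk:.2f}; Corr. = {best.corr:.2f}; "
          f"t-value = {best.tvalue:.1f}) — ")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, rep = dd.date_and_report(heavy.dated_at(None), chron)
    print(f"[heavy] pipeline verdict: {'dated' if rep.dated else 'undated'} "
          "(this density of absent years defeats rigid alignment; "
          "refusing is the correct outcome)")

    # case 2: companion site at desk-scale missing density
    cfg2 = dd.GeneratorConfig(
        n_samples=12, radii_per_sample=(1, 1), length_range=(200, 320),
        missing_rate=0.01, wedging_prob=0.0, seed=args.seed + 1,
    )
    series2, truth2 = dd.generate_site(cfg2)
    target = max(series2, key=len)
    rec = truth2.records[target.series_id]
    chron = dd.build_chronology(
        [
            dd.index_series(truth2.restore(s))
            for s in series2
            if s.sample_id != target.sample_id
        ]
    )
    results = dd.slide_date(target.dated_at(None), chron)
    pd.DataFrame(
        [
            {
                "rank": c.rank,
                "first_year": c.candidate_first_year,
                "overlap_n": c.overlap_n,
                "glk": c.glk,
                "corr": c.corr,
                "tvalue": c.tvalue,
                "significant": c.significant,
            }
            for c in results
        ]
    ).to_csv(args.out, index=False)
    best = results[0]
    print(f"[target] {target.series_id}: {len(target)} measured rings, "
          f"{len(rec.expected_insertions)} interior missing rings, "
          f"true first year {rec.first_year}")
    print(f"[target] rank-1 placement {best.candidate_first_year} "
          f"(GLK = {best.glk:.2f}; Corr. = {best.corr:.2f}; "
          f"t-value = {best.tvalue:.1f}; n = {best.overlap_n})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, rep = dd.date_and_report(target.dated_at(None), chron)
    if rep.dated:
        print(f"[target] corrected: {rep.n_measured} measured + {rep.n_missing} "
              f"missing rings -> age {rep.age_years} years "
              f"({rep.first_year}-{rep.last_year}); "
              f"truth span starts {rec.first_year}")
    else:
        print("[target] pipeline verdict: undated")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
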