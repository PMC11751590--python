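import warnings

import numpy as np
import pytest

import dendrodate as dd


@pytest.fixture(autouse=True)
def _quiet_runtime_warnings():
    """The dating heuristics emit advisory RuntimeWarnings (sentinel t,
    short-segment scans); tests assert on results, not warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def small_site():
    """Three clean single-radius series sharing one site signal."""
    cfg = dd.GeneratorConfig(
        n_samples=3,
        radii_per_sample=(1, 1),
        length_range=(300, 300),
        missing_rate=0.0,
        wedging_prob=0.0,
        seed=11,
    )
    series, truth = dd.generate_site(cfg)
    return series, truth


def delete_rings(series: dd.RingSeries, positions) -> dd.RingSeries:
    """Plant-and-recover helper: remove rings at the given indices."""
    w = np.delete(series.widths, sorted(positions))
    return dd.make_series(
        series.series_id + "_del", w, first_year=series.first_year
    )


def insertable_positions(base_len: int, candidates) -> list[int]:
    """Largest subset of candidate insertion slots valid for a series of
    ``base_len`` rings (slots index the result series, which grows as
    positions are kept)."""
    kept: list[int] = []
    for p in sorted(set(int(c) for c in candidates)):
        if 0 <= p < base_len + len(kept) + 1:
            kept.append(p)
    return kept
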