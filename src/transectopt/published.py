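"""Published scenario screening flags for the NWERN monitoring network.

The plot-scale sampling-error screening published for the 13-plot NWERN
network reports, for every subsampling scenario (number of transects x
transect length x LPI interval), whether the reduced design met both
acceptable-difference criteria (unbiased, and agreement bounds within
the family threshold) against the full three-100-m-transect design.
Those printed pass flags are transcribed here as input data for the
design selector, so the headline minimum-design recommendations can be
reproduced without the field data.

Only the line-point-intercept indicator grids (total foliar cover and
species count) are encoded; they are the ones the headline
recommendations quote.
"""

from __future__ import annotations

import pandas as pd

from .indicators import COVER, SPECIES

# (n_transects, length_m, lpi_interval_m) designs meeting BOTH criteria
# at the 95% level in the published screening.
_COVER_PASS_95 = [(2, 100, 0.25), (2, 100, 0.5), (3, 100, 0.5), (3, 100, 1.0)]
_SPECIES_PASS_95 = [(2, 100, 0.25), (2, 100, 0.5), (3, 100, 0.5)]
# At the 80% level the screening additionally admits one 100-m transect
# at 0.25-m spacing and three 50-m transects at 0.5-m spacing for cover.
_COVER_PASS_80 = _COVER_PASS_95 + [(1, 100, 0.25), (3, 50, 0.5)]

_TRANSECT_GRID = [(n, ln) for n in (1, 2, 3) for ln in (25, 50, 100)]
_LPI_INTERVALS_M = [0.25, 0.5, 1.0, 2.0]


def _grid(passing: list[tuple], indicator: str, level: float) -> pd.DataFrame:
    passing = set(passing)
    rows = []
    for n, length_m in _TRANSECT_GRID:
        for interval_m in _LPI_INTERVALS_M:
            # the full design is the reference, not a candidate
            if (n, length_m, interval_m) == (3, 100, 0.25):
                continue
            rows.append(
                {
                    "indicator": indicator,
                    "level": level,
                    "n_transects": n,
                    "length_m": length_m,
                    "interval_m": interval_m,
                    "total_length_cm": n * length_m * 100,
                    "n_measurements": int(n * length_m / interval_m),
                    "passed": (n, length_m, interval_m) in passing,
                }
            )
    return pd.DataFrame(rows)


def published_scenario_flags(indicator: str = COVER, level: float = 0.95) -> pd.DataFrame:
    """Scenario grid with published pass flags for an LPI indicator."""
    table = {
        (COVER, 0.95): _COVER_PASS_95,
        (COVER, 0.80): _COVER_PASS_80,
        (SPECIES, 0.95): _SPECIES_PASS_95,
    }
    try:
        passing = table[(indicator, level)]
    except KeyError:
        raise KeyError(
            f"no published flags encoded for {indicator!r} at level {level}"
        ) from None
    return _grid(passing, indicator, level)
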