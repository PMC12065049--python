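"""Minimum-effort design selection from scenario pass flags.

Given pass/fail flags over the scenario grid for one indicator and
confidence level, recommend the lowest-effort passing design. Effort is
ordered lexicographically: total transect length first, then number of
measurements — walking transect is the dominant field cost, and the
measurement count breaks ties within a layout. Because reasonable crews
may weigh the two axes differently, all Pareto-minimal passing designs on
(total length, measurement count) are reported as alternates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

EFFORT_COLS = ["total_length_cm", "n_measurements"]


@dataclass
class DesignRecommendation:
    """Ranked passing designs for one indicator at one level.

    ``primary`` is the lexicographic minimum on (total_length_cm,
    n_measurements); ``alternates`` are all Pareto-minimal passing
    designs (the primary is always among them). Empty when nothing
    passes.
    """

    indicator: str
    level: float
    primary: dict | None = None
    alternates: list[dict] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.primary is None


def _dominates(a: dict, b: dict) -> bool:
    """Weak Pareto domination: a is <= b on both axes, < on at least one."""
    le = all(a[c] <= b[c] for c in EFFORT_COLS)
    lt = any(a[c] < b[c] for c in EFFORT_COLS)
    return le and lt


def select_minimum_design(
    flags: pd.DataFrame, indicator: str = "", level: float = 0.95
) -> DesignRecommendation:
    """Lowest-effort passing design and its Pareto-minimal alternates.

    ``flags`` has one row per scenario with a boolean ``passed`` column
    and the effort columns ``total_length_cm`` and ``n_measurements``;
    any other columns (n_transects, length_cm, interval ...) ride along
    into the recommendation rows.
    """
    passing = flags[flags["passed"].astype(bool)]
    rec = DesignRecommendation(indicator=indicator, level=level)
    if passing.empty:
        return rec
    rows = passing.to_dict("records")
    rows.sort(key=lambda r: tuple(r[c] for c in EFFORT_COLS))
    rec.primary = rows[0]
    rec.alternates = [
        r for r in rows if not any(_dominates(o, r) for o in rows if o is not r)
    ]
    return rec


def recommendations_table(recs: list[DesignRecommendation]) -> pd.DataFrame:
    """Flatten recommendations into a ranked long table."""
    rows = []
    for rec in recs:
        for rank, r in enumerate(rec.alternates, start=1):
            rows.append(
                {"indicator": rec.indicator, "level": rec.level, "rank": rank, **r}
            )
    return pd.DataFrame(rows)
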