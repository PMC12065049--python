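"""Core transect-method indicators.

Four indicator families are computed from a plot-event dataset:

* **Total foliar cover** (percent): share of LPI pins intercepting at
  least one plant layer, live or dead.
* **Species count**: number of distinct plant species codes detected
  across all LPI layers.
* **Canopy gap class cover** (percent per class): share of the sampled
  transect length falling in gaps of 5-24, 25-50, 51-100, 101-200 and
  >200 cm.
* **Mean vegetation height** (cm): arithmetic mean over height points
  with a rooted plant; plantless points are excluded, not zeroed.

All computations are exact integer-centimeter arithmetic except the final
percentages and the height mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .records import NonPlantCodeSet

#: Canonical indicator names used in all output tables.
COVER = "AH_TotalFoliarCover"
SPECIES = "NumSpecies"
HEIGHT = "Hgt_Mean_cm"
GAP_NAMES = ["GapPct_5_24", "GapPct_25_50", "GapPct_51_100", "GapPct_101_200", "GapPct_200_plus"]
ALL_INDICATORS = [COVER, SPECIES, *GAP_NAMES, HEIGHT]


class UndefinedIndicatorError(ValueError):
    """The indicator has no value because its input is empty."""


@dataclass(frozen=True)
class GapClassScheme:
    """Ordered integer-cm gap size classes.

    Membership is by integer gap length: a 24-cm gap falls in the first
    class, a 25-cm gap in the second. The last class is open-ended. The
    classes are disjoint and cover every length >= 5 cm.
    """

    bounds: tuple[tuple[int, float], ...] = (
        (5, 24),
        (25, 50),
        (51, 100),
        (101, 200),
        (201, math.inf),
    )
    names: tuple[str, ...] = tuple(GAP_NAMES)

    def classify(self, length_cm: int) -> int:
        """Index of the class containing ``length_cm``; -1 if below minimum."""
        for i, (lo, hi) in enumerate(self.bounds):
            if lo <= length_cm <= hi:
                return i
        return -1


DEFAULT_GAP_SCHEME = GapClassScheme()


@dataclass
class IndicatorSet:
    """The four indicator families for one plot-event under one design.

    A value of ``None`` marks an indicator undefined for this dataset
    (e.g. mean height when no height point intercepted a plant); it
    propagates as a missing cell, never as zero.
    """

    total_foliar_pct: float | None
    species_count: int | None
    gap_pct: dict[str, float] | None
    mean_height_cm: float | None

    def as_dict(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {
            COVER: self.total_foliar_pct,
            SPECIES: self.species_count,
        }
        for name in GAP_NAMES:
            out[name] = None if self.gap_pct is None else self.gap_pct[name]
        out[HEIGHT] = self.mean_height_cm
        return out


def total_foliar_cover(pins: pd.DataFrame, nonplant: NonPlantCodeSet) -> float:
    """Percent of pins with at least one plant interception in any layer.

    A pin intercepting only non-plant codes counts toward the denominator
    but not the numerator.
    """
    if pins.empty:
        raise UndefinedIndicatorError("no pins: total foliar cover undefined")
    is_plant = ~pins["code"].isin(nonplant.codes)
    hits = pins.loc[is_plant, ["transect_id", "position_cm"]].drop_duplicates()
    n_pins = len(pins[["transect_id", "position_cm"]].drop_duplicates())
    return 100.0 * len(hits) / n_pins


def species_count(pins: pd.DataFrame, nonplant: NonPlantCodeSet) -> int:
    """Number of distinct plant codes over all layers of all pins."""
    if pins.empty:
        raise UndefinedIndicatorError("no pins: species count undefined")
    return len(set(pins["code"]) - set(nonplant.codes))


def gap_class_cover(
    gaps: pd.DataFrame,
    sampled_length_cm: dict[str, int],
    scheme: GapClassScheme = DEFAULT_GAP_SCHEME,
) -> dict[str, float]:
    """Percent of total sampled transect length in each gap size class.

    ``sampled_length_cm`` maps each sampled transect to its (possibly
    truncated) length; the denominator is the sum over sampled transects,
    so it reflects the design actually walked, not the full layout.
    """
    total = sum(sampled_length_cm.values())
    if total <= 0:
        raise UndefinedIndicatorError("zero sampled length: gap cover undefined")
    sums = dict.fromkeys(scheme.names, 0)
    if not gaps.empty:
        lengths = (gaps["end_cm"] - gaps["start_cm"]).to_numpy()
        for length in lengths:
            idx = scheme.classify(int(length))
            if idx >= 0:
                sums[scheme.names[idx]] += int(length)
    return {name: 100.0 * sums[name] / total for name in scheme.names}


def mean_height(heights: pd.DataFrame) -> float:
    """Mean of present height values; plantless points are excluded."""
    present = heights["height_cm"].dropna()
    if present.empty:
        raise UndefinedIndicatorError("no rooted plants at height points")
    return float(present.mean())


def compute_indicator_set(
    ds,
    scheme: GapClassScheme = DEFAULT_GAP_SCHEME,
    nonplant: NonPlantCodeSet | None = None,
) -> IndicatorSet:
    """All four indicator families for one plot-event dataset.

    Each indicator is flagged undefined (``None``) when its input is
    empty rather than raising, so a sparse plot yields a partial row
    instead of aborting the scenario grid.
    """
    nonplant = nonplant or NonPlantCodeSet()
    try:
        cover = total_foliar_cover(ds.pins, nonplant)
        nspec = species_count(ds.pins, nonplant)
    except UndefinedIndicatorError:
        cover, nspec = None, None
    lengths = dict(zip(ds.layout["transect_id"], ds.layout["length_cm"]))
    try:
        gaps = gap_class_cover(ds.gaps, lengths, scheme)
    except UndefinedIndicatorError:
        gaps = None
    try:
        hgt = mean_height(ds.heights)
    except UndefinedIndicatorError:
        hgt = None
    return IndicatorSet(cover, nspec, gaps, hgt)


def indicator_family(name: str) -> str:
    """Map an indicator name to its acceptance-criteria family."""
    if name == COVER:
        return "cover"
    if name == SPECIES:
        return "species"
    if name == HEIGHT:
        return "height"
    if name in GAP_NAMES:
        return "gap"
    raise KeyError(f"unknown indicator {name!r}")
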