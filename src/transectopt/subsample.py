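"""Reduced sampling designs: fewer, shorter, sparser transects.

A :class:`Scenario` describes one subsampling design. Applying it to a
full dataset composes three reductions:

1. randomly omit transects (one seeded draw shared by all three methods,
   mimicking a crew laying out fewer physical transects);
2. truncate transects, run from the plot center toward the edge; gaps are
   clipped at the boundary and re-checked against the 5-cm minimum;
3. thin LPI pins and height points to sparser intervals (gap intercept is
   continuous and is never thinned).

Truncation and thinning are deterministic and commute; only the transect
draw is random. The full design (3 transects, 100 m, base intervals)
reproduces the full-data indicators exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .indicators import DEFAULT_GAP_SCHEME, IndicatorSet, compute_indicator_set
from .records import (
    BASE_HEIGHT_INTERVAL_CM,
    BASE_LPI_INTERVAL_CM,
    DEFAULT_LENGTH_CM,
    MIN_GAP_CM,
    NonPlantCodeSet,
    PlotEventDataset,
)


@dataclass(frozen=True)
class Scenario:
    """One subsampling design.

    Positive difference sign convention downstream: d = full - subsample,
    so positive bias means the design underestimates the indicator.
    """

    n_transects: int = 3
    length_cm: int = DEFAULT_LENGTH_CM
    lpi_interval_cm: int = BASE_LPI_INTERVAL_CM
    height_interval_cm: int = BASE_HEIGHT_INTERVAL_CM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transects < 1:
            raise ValueError("n_transects must be >= 1")
        if self.length_cm <= 0:
            raise ValueError("length_cm must be > 0")
        if self.lpi_interval_cm % BASE_LPI_INTERVAL_CM != 0:
            raise ValueError(
                f"lpi_interval_cm must be a multiple of {BASE_LPI_INTERVAL_CM}"
            )
        if self.height_interval_cm % BASE_HEIGHT_INTERVAL_CM != 0:
            raise ValueError(
                f"height_interval_cm must be a multiple of {BASE_HEIGHT_INTERVAL_CM}"
            )

    @property
    def total_length_cm(self) -> int:
        return self.n_transects * self.length_cm

    @property
    def n_lpi_points(self) -> int:
        return self.n_transects * (self.length_cm // self.lpi_interval_cm)

    @property
    def n_height_points(self) -> int:
        return self.n_transects * (self.length_cm // self.height_interval_cm)

    @property
    def is_full_design(self) -> bool:
        return (
            self.n_transects == 3
            and self.length_cm == DEFAULT_LENGTH_CM
            and self.lpi_interval_cm == BASE_LPI_INTERVAL_CM
            and self.height_interval_cm == BASE_HEIGHT_INTERVAL_CM
        )


def select_transects(
    ds: PlotEventDataset, n: int, rng: np.random.Generator
) -> PlotEventDataset:
    """Restrict the dataset to a uniformly random size-``n`` transect subset.

    The draw is deterministic given the generator state and is shared by
    all three methods (the caller applies it once per scenario draw).
    """
    transects = sorted(ds.layout["transect_id"])
    if n > len(transects):
        raise ValueError(f"cannot select {n} of {len(transects)} transects")
    keep = set(rng.choice(transects, size=n, replace=False))
    out = ds.copy()
    out.layout = out.layout[out.layout["transect_id"].isin(keep)].reset_index(drop=True)
    out.pins = out.pins[out.pins["transect_id"].isin(keep)].reset_index(drop=True)
    out.gaps = out.gaps[out.gaps["transect_id"].isin(keep)].reset_index(drop=True)
    out.heights = out.heights[out.heights["transect_id"].isin(keep)].reset_index(
        drop=True
    )
    return out


def truncate_transects(ds: PlotEventDataset, length_cm: int) -> PlotEventDataset:
    """Shorten every transect to ``length_cm``, measured from the plot center.

    Pins and height points beyond the cut are dropped; gaps are clipped at
    the boundary (the field protocol terminates a gap at the transect
    end), then fragments shorter than the 5-cm minimum are discarded.
    Layout lengths are updated so gap denominators use the walked length.
    """
    if length_cm <= 0 or (length_cm > ds.layout["length_cm"]).any():
        raise ValueError("truncation length must lie in (0, layout length]")
    out = ds.copy()
    out.layout["length_cm"] = np.minimum(out.layout["length_cm"], length_cm)
    out.pins = out.pins[out.pins["position_cm"] <= length_cm].reset_index(drop=True)
    out.heights = out.heights[out.heights["position_cm"] <= length_cm].reset_index(
        drop=True
    )
    g = out.gaps[out.gaps["start_cm"] < length_cm].copy()
    g["end_cm"] = g["end_cm"].clip(upper=length_cm)
    g = g[(g["end_cm"] - g["start_cm"]) >= MIN_GAP_CM]
    out.gaps = g.reset_index(drop=True)
    return out


def thin_points(
    ds: PlotEventDataset, lpi_interval_cm: int, height_interval_cm: int
) -> PlotEventDataset:
    """Keep pins/heights whose position is a multiple of the new interval."""
    if lpi_interval_cm % BASE_LPI_INTERVAL_CM != 0:
        raise ValueError(f"LPI interval must be a multiple of {BASE_LPI_INTERVAL_CM} cm")
    if height_interval_cm % BASE_HEIGHT_INTERVAL_CM != 0:
        raise ValueError(
            f"height interval must be a multiple of {BASE_HEIGHT_INTERVAL_CM} cm"
        )
    out = ds.copy()
    out.pins = out.pins[out.pins["position_cm"] % lpi_interval_cm == 0].reset_index(
        drop=True
    )
    out.heights = out.heights[
        out.heights["position_cm"] % height_interval_cm == 0
    ].reset_index(drop=True)
    return out


def subsample_dataset(
    ds: PlotEventDataset, scenario: Scenario, rng: np.random.Generator | None = None
) -> PlotEventDataset:
    """select -> truncate -> thin, returning the reduced dataset."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    out = select_transects(ds, scenario.n_transects, rng)
    out = truncate_transects(out, scenario.length_cm)
    return thin_points(out, scenario.lpi_interval_cm, scenario.height_interval_cm)


def apply_scenario(
    ds: PlotEventDataset,
    scenario: Scenario,
    scheme=DEFAULT_GAP_SCHEME,
    nonplant: NonPlantCodeSet | None = None,
    rng: np.random.Generator | None = None,
) -> IndicatorSet:
    """Indicators of the dataset reduced to the given design."""
    return compute_indicator_set(
        subsample_dataset(ds, scenario, rng), scheme=scheme, nonplant=nonplant
    )
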