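"""Field-method record tables, plot geometry, validation and CSV I/O.

All along-transect positions are stored as integer centimeters. The three
transect methods (line-point intercept, canopy gap intercept, vegetation
height) share a plot layout of radial transects running from the plot
center (position 0) outward. The standard full design is three 100-m
transects at 60-degree intervals on a 1-ha plot: 400 LPI pins per transect
(every 25 cm), height points every 2 m, and continuous gap records with a
5-cm minimum gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Base LPI pin spacing (cm): a pin every 0.25 m.
BASE_LPI_INTERVAL_CM = 25
#: Base height-point spacing (cm): a measurement every 2 m.
BASE_HEIGHT_INTERVAL_CM = 200
#: Minimum recordable canopy gap (cm).
MIN_GAP_CM = 5
#: Standard transect length (cm): 100 m.
DEFAULT_LENGTH_CM = 10_000

#: Code recorded for a pin that intercepts nothing.
NO_HIT_CODE = "NONE"

#: Default layer codes that do not count as plant species: no-hit marker,
#: herbaceous/woody litter, soil, rock, bedrock, duff, moss, lichen, water.
DEFAULT_NONPLANT_CODES = frozenset(
    {NO_HIT_CODE, "L", "HL", "WL", "S", "R", "BR", "D", "M", "LC", "W"}
)

PIN_COLUMNS = ["plot_id", "event_id", "transect_id", "position_cm", "layer", "code"]
GAP_COLUMNS = ["plot_id", "event_id", "transect_id", "start_cm", "end_cm"]
HEIGHT_COLUMNS = ["plot_id", "event_id", "transect_id", "position_cm", "height_cm"]
LAYOUT_COLUMNS = ["plot_id", "transect_id", "azimuth_deg", "length_cm"]


class FormatError(ValueError):
    """A table is missing required columns or cannot be parsed."""


class ValidationError(ValueError):
    """A record violates a structural invariant of its method."""


@dataclass(frozen=True)
class NonPlantCodeSet:
    """Layer codes that do not count as plant species.

    Code dialects vary across monitoring programs, so the set is
    configuration rather than hard-coded; the default covers the common
    surface and litter codes plus the no-hit marker.
    """

    codes: frozenset[str] = DEFAULT_NONPLANT_CODES

    def __contains__(self, code: str) -> bool:
        return code in self.codes


@dataclass
class PlotEventDataset:
    """All records for one plot at one sampling event.

    Attributes
    ----------
    layout : DataFrame
        One row per transect: transect_id, azimuth_deg, length_cm.
    pins : DataFrame
        Tall LPI table, one row per intercepted layer:
        transect_id, position_cm, layer, code. A pin with no interception
        appears as a single row with code ``NONE``.
    gaps : DataFrame
        transect_id, start_cm, end_cm.
    heights : DataFrame
        transect_id, position_cm, height_cm (NaN = no rooted plant).
    """

    plot_id: str
    event_id: str
    layout: pd.DataFrame
    pins: pd.DataFrame
    gaps: pd.DataFrame
    heights: pd.DataFrame

    def copy(self) -> "PlotEventDataset":
        return PlotEventDataset(
            self.plot_id,
            self.event_id,
            self.layout.copy(),
            self.pins.copy(),
            self.gaps.copy(),
            self.heights.copy(),
        )

    @property
    def n_pins(self) -> int:
        """Number of distinct pin drops (not layer rows)."""
        if self.pins.empty:
            return 0
        return len(self.pins[["transect_id", "position_cm"]].drop_duplicates())

    @property
    def n_height_points(self) -> int:
        return len(self.heights)


def default_layout(plot_id: str, length_cm: int = DEFAULT_LENGTH_CM) -> pd.DataFrame:
    """Three radial transects at 60-degree intervals from the plot center."""
    return pd.DataFrame(
        {
            "plot_id": plot_id,
            "transect_id": ["T1", "T2", "T3"],
            "azimuth_deg": [0.0, 60.0, 120.0],
            "length_cm": length_cm,
        }
    )


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{name}: missing required column(s) {missing}")


def validate_dataset(ds: PlotEventDataset) -> None:
    """Check all structural invariants; raise ValidationError on the first hit.

    Checks performed:

    * every record's transect_id exists in the layout
    * pin positions are positive multiples of 25 cm
    * height positions are positive multiples of 200 cm
    * gaps have end > start, length >= 5 cm, lie within the transect,
      and do not overlap on one transect
    """
    known = set(ds.layout["transect_id"])
    lengths = dict(zip(ds.layout["transect_id"], ds.layout["length_cm"]))
    if (ds.layout["length_cm"] <= 0).any():
        raise ValidationError(f"{ds.plot_id}/{ds.event_id}: non-positive transect length")

    for name, df in (("pins", ds.pins), ("gaps", ds.gaps), ("heights", ds.heights)):
        bad = set(df["transect_id"]) - known
        if bad:
            raise ValidationError(
                f"{ds.plot_id}/{ds.event_id}: {name} reference unknown transect(s) {sorted(bad)}"
            )

    for name, df, base in (
        ("pins", ds.pins, BASE_LPI_INTERVAL_CM),
        ("heights", ds.heights, BASE_HEIGHT_INTERVAL_CM),
    ):
        pos = df["position_cm"].to_numpy()
        off = np.flatnonzero((pos <= 0) | (pos % base != 0))
        if off.size:
            i = int(off[0])
            raise ValidationError(
                f"{ds.plot_id}/{ds.event_id}: {name} row {i}: position_cm "
                f"{pos[i]} is not a positive multiple of {base}"
            )

    g = ds.gaps
    bad = g["end_cm"] <= g["start_cm"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{ds.plot_id}/{ds.event_id}: gap row {i}: end before start "
            f"({g['end_cm'].iloc[i]} <= {g['start_cm'].iloc[i]})"
        )
    short = (g["end_cm"] - g["start_cm"]) < MIN_GAP_CM
    if short.any():
        i = int(np.flatnonzero(short.to_numpy())[0])
        raise ValidationError(
            f"{ds.plot_id}/{ds.event_id}: gap row {i}: shorter than {MIN_GAP_CM} cm"
        )
    for tid, sub in g.groupby("transect_id", sort=False):
        if (sub["start_cm"] < 0).any() or (sub["end_cm"] > lengths[tid]).any():
            raise ValidationError(
                f"{ds.plot_id}/{ds.event_id}: gap outside [0, length] on transect {tid}"
            )
        s = sub.sort_values("start_cm")
        if (s["start_cm"].to_numpy()[1:] < s["end_cm"].to_numpy()[:-1]).any():
            raise ValidationError(
                f"{ds.plot_id}/{ds.event_id}: overlapping gaps on transect {tid}"
            )


def read_method_tables(
    lpi_path,
    gap_path,
    height_path,
    layout_path,
    validate: bool = True,
) -> dict[tuple[str, str], PlotEventDataset]:
    """Read the four method CSVs and group them by (plot_id, event_id).

    Expected headers (tall tables as distributed by monitoring data commons):

    * ``lpi.csv``: plot_id,event_id,transect_id,position_cm,layer,code
    * ``gap.csv``: plot_id,event_id,transect_id,start_cm,end_cm
    * ``height.csv``: plot_id,event_id,transect_id,position_cm,height_cm
    * ``layout.csv``: plot_id,transect_id,azimuth_deg,length_cm
    """
    str_cols = {"plot_id": str, "event_id": str, "transect_id": str}
    pins = pd.read_csv(lpi_path, dtype={**str_cols, "code": str})
    gaps = pd.read_csv(gap_path, dtype=str_cols)
    heights = pd.read_csv(height_path, dtype=str_cols)
    layout = pd.read_csv(layout_path, dtype={"plot_id": str, "transect_id": str})

    _require_columns(pins, PIN_COLUMNS, "lpi.csv")
    _require_columns(gaps, GAP_COLUMNS, "gap.csv")
    _require_columns(heights, HEIGHT_COLUMNS, "height.csv")
    _require_columns(layout, LAYOUT_COLUMNS, "layout.csv")

    for df, cols in ((pins, ["position_cm"]), (gaps, ["start_cm", "end_cm"]),
                     (heights, ["position_cm"])):
        for c in cols:
            df[c] = df[c].astype(np.int64)
    heights["height_cm"] = heights["height_cm"].astype(float)

    keys = sorted(
        set(map(tuple, pins[["plot_id", "event_id"]].drop_duplicates().to_numpy()))
        | set(map(tuple, gaps[["plot_id", "event_id"]].drop_duplicates().to_numpy()))
        | set(map(tuple, heights[["plot_id", "event_id"]].drop_duplicates().to_numpy()))
    )
    out: dict[tuple[str, str], PlotEventDataset] = {}
    for plot_id, event_id in keys:
        ds = PlotEventDataset(
            plot_id=plot_id,
            event_id=event_id,
            layout=layout[layout["plot_id"] == plot_id]
            .drop(columns="plot_id")
            .reset_index(drop=True),
            pins=_slice(pins, plot_id, event_id, PIN_COLUMNS),
            gaps=_slice(gaps, plot_id, event_id, GAP_COLUMNS),
            heights=_slice(heights, plot_id, event_id, HEIGHT_COLUMNS),
        )
        if validate:
            validate_dataset(ds)
        out[(plot_id, event_id)] = ds
    return out


def _slice(df: pd.DataFrame, plot_id: str, event_id: str, cols: list[str]) -> pd.DataFrame:
    m = (df["plot_id"] == plot_id) & (df["event_id"] == event_id)
    return df.loc[m, [c for c in cols if c not in ("plot_id", "event_id")]].reset_index(
        drop=True
    )


def write_dataset_csvs(datasets: dict[tuple[str, str], PlotEventDataset], outdir) -> None:
    """Write a dataset collection back to the four-CSV suite."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pins, gaps, heights, layouts = [], [], [], {}
    for (plot_id, event_id), ds in sorted(datasets.items()):
        for frames, df in ((pins, ds.pins), (gaps, ds.gaps), (heights, ds.heights)):
            d = df.copy()
            d.insert(0, "event_id", event_id)
            d.insert(0, "plot_id", plot_id)
            frames.append(d)
        lay = ds.layout.copy()
        lay.insert(0, "plot_id", plot_id)
        layouts[plot_id] = lay
    pd.concat(pins, ignore_index=True)[PIN_COLUMNS].to_csv(outdir / "lpi.csv", index=False)
    pd.concat(gaps, ignore_index=True)[GAP_COLUMNS].to_csv(outdir / "gap.csv", index=False)
    pd.concat(heights, ignore_index=True)[HEIGHT_COLUMNS].to_csv(
        outdir / "height.csv", index=False
    )
    pd.concat(layouts.values(), ignore_index=True)[LAYOUT_COLUMNS].to_csv(
        outdir / "layout.csv", index=False
    )


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write the agreement results table (one row per indicator x scenario x level).

    Values round-trip losslessly to six decimals through
    :func:`read_results_table`.
    """
    if results is None or len(results) == 0:
        raise ValueError("results collection is empty; nothing to write")
    results.to_csv(path, index=False, float_format="%.6f")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
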