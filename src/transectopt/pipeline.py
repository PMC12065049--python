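"""Scenario-grid orchestration: differences, agreement fits, recommendations.

The grid crosses transect designs (number x length) with measurement
intervals per point-based method, evaluates each reduced design against
the full design with the nested limits-of-agreement model at each
confidence level, and feeds the pass flags to the design selector. A
master seed deterministically spawns one random stream per (plot, event,
transect design), so the same transects are omitted for all methods and
intervals within a design draw, and adding scenarios does not perturb
existing ones.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import (
    AcceptanceCriteria,
    NestedLoA,
    check_difference_normality,
    evaluate_criteria,
)
from .design import DesignRecommendation, recommendations_table, select_minimum_design
from .indicators import (
    COVER,
    GAP_NAMES,
    HEIGHT,
    SPECIES,
    DEFAULT_GAP_SCHEME,
    compute_indicator_set,
    gap_class_cover,
    indicator_family,
    species_count,
    total_foliar_cover,
)
from .records import (
    NonPlantCodeSet,
    PlotEventDataset,
    read_method_tables,
    write_results_table,
)
from .simulate import SyntheticConfig, generate_study
from .subsample import select_transects, truncate_transects

#: The nine transect designs: one to three transects of 25, 50, 100 m.
DEFAULT_TRANSECT_GRID = tuple(
    (n, length) for n in (1, 2, 3) for length in (2_500, 5_000, 10_000)
)
DEFAULT_LPI_INTERVALS = (25, 50, 100, 200)
DEFAULT_HEIGHT_INTERVALS = (200, 400, 800, 1_600, 2_000)


@dataclass
class RunConfig:
    """Settings for one full scenario-grid analysis."""

    synthetic: SyntheticConfig | None = None
    data_dir: str | None = None
    transect_grid: tuple = DEFAULT_TRANSECT_GRID
    lpi_intervals_cm: tuple = DEFAULT_LPI_INTERVALS
    height_intervals_cm: tuple = DEFAULT_HEIGHT_INTERVALS
    levels: tuple = (0.80, 0.95)
    criteria: AcceptanceCriteria = field(default_factory=AcceptanceCriteria)
    seed: int = 0
    per_plot: bool = False
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "criteria"},
            default=lambda o: o.__dict__,
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_study(config: RunConfig) -> dict[tuple[str, str], PlotEventDataset]:
    if config.data_dir is not None:
        d = Path(config.data_dir)
        return read_method_tables(
            d / "lpi.csv", d / "gap.csv", d / "height.csv", d / "layout.csv"
        )
    if config.synthetic is not None:
        return generate_study(config.synthetic)
    raise ValueError("RunConfig needs either data_dir or a synthetic config")


def _stream(seed: int, plot_id: str, event_id: str, n: int, length_cm: int):
    """Deterministic per-(plot, event, transect design) random stream."""
    key = (zlib.crc32(plot_id.encode()), zlib.crc32(event_id.encode()), n, length_cm)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def compute_scenario_differences(
    study: dict[tuple[str, str], PlotEventDataset],
    config: RunConfig,
    nonplant: NonPlantCodeSet | None = None,
) -> pd.DataFrame:
    """Long table of full-minus-subsample differences over the whole grid.

    Columns: plot_id, event_id, indicator, n_transects, length_cm,
    interval_cm (NaN for the continuous gap method), d. Undefined
    indicator cells are dropped pairwise.
    """
    nonplant = nonplant or NonPlantCodeSet()
    rows = []
    for (plot_id, event_id), ds in sorted(study.items()):
        full = compute_indicator_set(ds, nonplant=nonplant).as_dict()
        for n, length_cm in config.transect_grid:
            rng = _stream(config.seed, plot_id, event_id, n, length_cm)
            sub = truncate_transects(select_transects(ds, n, rng), length_cm)
            lengths = dict(zip(sub.layout["transect_id"], sub.layout["length_cm"]))

            gap_sub = gap_class_cover(sub.gaps, lengths, DEFAULT_GAP_SCHEME)
            for name in GAP_NAMES:
                if full[name] is None:
                    continue
                rows.append(
                    (plot_id, event_id, name, n, length_cm, np.nan,
                     full[name] - gap_sub[name])
                )

            for lpi_cm in config.lpi_intervals_cm:
                pins = sub.pins[sub.pins["position_cm"] % lpi_cm == 0]
                if pins.empty:
                    continue
                if full[COVER] is not None:
                    rows.append(
                        (plot_id, event_id, COVER, n, length_cm, lpi_cm,
                         full[COVER] - total_foliar_cover(pins, nonplant))
                    )
                if full[SPECIES] is not None:
                    rows.append(
                        (plot_id, event_id, SPECIES, n, length_cm, lpi_cm,
                         full[SPECIES] - species_count(pins, nonplant))
                    )

            for h_cm in config.height_intervals_cm:
                hts = sub.heights[sub.heights["position_cm"] % h_cm == 0]
                if full[HEIGHT] is None or hts["height_cm"].dropna().empty:
                    continue
                rows.append(
                    (plot_id, event_id, HEIGHT, n, length_cm, h_cm,
                     full[HEIGHT] - float(hts["height_cm"].dropna().mean()))
                )
    return pd.DataFrame(
        rows,
        columns=["plot_id", "event_id", "indicator", "n_transects", "length_cm",
                 "interval_cm", "d"],
    )


def fit_agreement_grid(
    differences: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Nested LoA per (indicator, interval, transect design, level).

    The full design appears with bias 0 and half-width 0 by construction
    and is emitted as a self-check (``full_design`` column); it is not a
    candidate for recommendation.
    """
    results = []
    group_cols = ["indicator", "n_transects", "length_cm", "interval_cm"]
    for key, sub in differences.groupby(group_cols, dropna=False, sort=True):
        indicator, n, length_cm, interval_cm = key
        family = indicator_family(indicator)
        if sub["plot_id"].nunique() < 2:
            continue
        model = NestedLoA.from_dataframe(sub)
        base_interval = 25 if family in ("cover", "species") else 200
        full_design = (
            n == 3 and length_cm == 10_000
            and (np.isnan(interval_cm) or interval_cm == base_interval)
        )
        if family == "gap":
            n_measurements = 0
        else:
            n_measurements = int(n * length_cm // int(interval_cm))
        for level in config.levels:
            res = model.fit(level=level)
            flags = evaluate_criteria(res, indicator, config.criteria)
            results.append(
                {
                    "method": {"cover": "LPI", "species": "LPI",
                               "gap": "Gap intercept", "height": "Height"}[family],
                    "indicator": indicator,
                    "n_transects": int(n),
                    "length_cm": int(length_cm),
                    "interval_cm": interval_cm,
                    "total_length_cm": int(n * length_cm),
                    "n_measurements": n_measurements,
                    "full_design": bool(full_design),
                    **res.as_row(),
                    **flags,
                }
            )
    return pd.DataFrame(results)


def recommend_designs(results: pd.DataFrame) -> list[DesignRecommendation]:
    """Minimum-effort recommendation per indicator and level."""
    recs = []
    candidates = results[~results["full_design"]]
    for (indicator, level), sub in candidates.groupby(["indicator", "level"]):
        recs.append(
            select_minimum_design(
                sub[["n_transects", "length_cm", "interval_cm",
                     "total_length_cm", "n_measurements", "passed"]],
                indicator=indicator,
                level=level,
            )
        )
    return recs


def run_scenario_grid(config: RunConfig) -> dict:
    """End-to-end analysis; optionally writes the CSV/JSON output suite.

    Returns a dict with ``differences``, ``results``, ``recommendations``
    and ``normality`` DataFrames.
    """
    study = load_study(config)
    differences = compute_scenario_differences(study, config)
    if differences.empty:
        raise ValueError("scenario grid produced no differences (empty study?)")
    results = fit_agreement_grid(differences, config)
    recs = recommend_designs(results)
    rec_table = recommendations_table(recs)
    normality = check_difference_normality(
        differences, group_cols=("indicator", "n_transects", "length_cm")
    )

    out = {
        "differences": differences,
        "results": results,
        "recommendations": rec_table,
        "normality": normality,
    }

    if config.per_plot:
        per_plot = []
        for plot_id, sub in differences.groupby("plot_id"):
            # within one plot the events are the subjects: classical LoA
            for key, g in sub.groupby(
                ["indicator", "n_transects", "length_cm", "interval_cm"], dropna=False
            ):
                if g["event_id"].nunique() < 2:
                    continue
                model = NestedLoA(g["d"].to_numpy(), g["event_id"].to_numpy())
                for level in config.levels:
                    res = model.fit(level=level)
                    per_plot.append(
                        {"plot_id": plot_id, "indicator": key[0],
                         "n_transects": key[1], "length_cm": key[2],
                         "interval_cm": key[3], **res.as_row()}
                    )
        out["per_plot_results"] = pd.DataFrame(per_plot)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        differences.to_csv(outdir / "differences.csv", index=False)
        write_results_table(results, outdir / "results.csv")
        rec_table.to_csv(outdir / "recommendations.csv", index=False)
        normality.to_csv(outdir / "normality.csv", index=False)
        if "per_plot_results" in out:
            out["per_plot_results"].to_csv(outdir / "per_plot_results.csv", index=False)
        log = {"config_hash": config.config_hash(), "seed": config.seed,
               "n_differences": int(len(differences)), "n_results": int(len(results))}
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return out
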