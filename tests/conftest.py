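import numpy as np
import pandas as pd
import pytest

from transectopt.records import (
    BASE_HEIGHT_INTERVAL_CM,
    BASE_LPI_INTERVAL_CM,
    MIN_GAP_CM,
    NO_HIT_CODE,
    NonPlantCodeSet,
    PlotEventDataset,
    default_layout,
)
from transectopt.simulate import SyntheticConfig, generate_study

PLANT_CODES = ["ARTR2", "BOER4", "PLJA", "SPAI", "GUSA2", "ATCA2", "PASM"]
NONPLANT_CODES = [NO_HIT_CODE, "L", "S", "R"]


def random_dataset(
    rng: np.random.Generator,
    plot_id: str = "P01",
    event_id: str = "E01",
    length_cm: int = 10_000,
    pin_fraction: float = 1.0,
) -> PlotEventDataset:
    """Randomized but structurally valid plot-event dataset."""
    layout = default_layout(plot_id, length_cm).drop(columns="plot_id")
    pin_rows, gap_rows, height_rows = [], [], []
    for tid in layout["transect_id"]:
        positions = np.arange(BASE_LPI_INTERVAL_CM, length_cm + 1, BASE_LPI_INTERVAL_CM)
        if pin_fraction < 1.0:
            n_keep = max(1, int(pin_fraction * len(positions)))
            positions = np.sort(rng.choice(positions, n_keep, replace=False))
        for pos in positions:
            n_layers = rng.integers(0, 4)
            if n_layers == 0:
                pin_rows.append((tid, int(pos), 1, NO_HIT_CODE))
            else:
                codes = rng.choice(PLANT_CODES + NONPLANT_CODES[1:], n_layers, replace=False)
                for layer, code in enumerate(codes, start=1):
                    pin_rows.append((tid, int(pos), layer, code))
        cursor = int(rng.integers(0, 200))
        while cursor < length_cm - MIN_GAP_CM:
            glen = int(rng.integers(MIN_GAP_CM, 600))
            end = min(cursor + glen, length_cm)
            if end - cursor >= MIN_GAP_CM and rng.random() < 0.7:
                gap_rows.append((tid, cursor, end))
            cursor = end + int(rng.integers(1, 400))
        for pos in range(BASE_HEIGHT_INTERVAL_CM, length_cm + 1, BASE_HEIGHT_INTERVAL_CM):
            h = float(rng.lognormal(3.0, 0.5)) if rng.random() < 0.6 else np.nan
            height_rows.append((tid, pos, h))
    return PlotEventDataset(
        plot_id,
        event_id,
        layout,
        pd.DataFrame(pin_rows, columns=["transect_id", "position_cm", "layer", "code"]),
        pd.DataFrame(gap_rows, columns=["transect_id", "start_cm", "end_cm"]),
        pd.DataFrame(height_rows, columns=["transect_id", "position_cm", "height_cm"]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def nonplant():
    return NonPlantCodeSet(frozenset(NONPLANT_CODES))


@pytest.fixture(scope="session")
def small_study():
    """Compact synthetic study reused across tests (deterministic)."""
    cfg = SyntheticConfig(
        n_plots=6, events_min=3, events_max=4, cover_min=0.05, cover_max=0.7, seed=11
    )
    return generate_study(cfg)
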