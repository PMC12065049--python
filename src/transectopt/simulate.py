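"""Synthetic vegetation-plot studies for pipeline validation.

Generates multi-plot, multi-event datasets with the geometry and variance
structure the agreement analysis assumes, so every stage is testable
without field data:

* plant canopies are disks placed by a Thomas cluster process (Poisson
  parents, Poisson offspring displaced by an isotropic Gaussian), which
  produces the patchy canopies typical of rangeland vegetation; a plain
  Poisson field is the special case offspring_mean = 1, cluster_sd = 0;
* a gradient of per-plot canopy density spans near-bare (playa-like)
  through near-closed canopy, plus a lognormal plot random effect, giving
  between-plot variance;
* each sampling event perturbs the plot's base map (a configurable
  fraction of plants is moved and re-sized), inducing the within-plot
  event-to-event correlation the nested model partitions;
* the three field methods are read off the map exactly: a pin intercepts
  every disk covering its coordinates, gaps are the maximal uncovered
  intervals along each transect (>= 5 cm, integer cm), and the height at
  a point is the tallest intercepting canopy.

Under a stationary Poisson field of equal disks the pin-level cover has
the closed Boolean-model form 1 - exp(-lambda * pi * r^2), which serves
as an independent oracle for the whole sampling chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    BASE_HEIGHT_INTERVAL_CM,
    BASE_LPI_INTERVAL_CM,
    MIN_GAP_CM,
    NO_HIT_CODE,
    PlotEventDataset,
    default_layout,
)

#: 1-ha plot half-width (cm); the plot is the square [-5000, 5000]^2.
PLOT_HALF_CM = 5_000.0
#: The vegetation field must cover the full reach of the 100-m radial
#: transects (10000 cm from the center), not just the nominal 1-ha square.
FIELD_HALF_CM = 10_000.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level generator settings.

    The defaults emulate the structure of the 13-plot monitoring network
    the analysis is designed for: 13 one-hectare plots, five to twelve
    sampling events each, with per-plot foliar cover spanning roughly 2%
    (sparse playa) to 98% (closed canopy).
    """

    n_plots: int = 13
    events_min: int = 5
    events_max: int = 12
    #: per-plot target cover fractions are log-spaced in canopy density
    #: between these two ends of the gradient
    cover_min: float = 0.02
    cover_max: float = 0.98
    #: Thomas process: mean offspring per parent and cluster spread (cm).
    offspring_mean: float = 8.0
    cluster_sd_cm: float = 300.0
    #: optional explicit parent intensity (parents per hectare); when set
    #: it overrides the cover-target gradient (used for oracle checks)
    parent_intensity_per_ha: float | None = None
    #: lognormal canopy radius: median (cm) and log-scale sigma
    radius_median_cm: float = 30.0
    radius_sigma: float = 0.4
    n_species: int = 12
    #: relative abundance of species i is proportional to decay**i
    abundance_decay: float = 0.65
    #: per-species lognormal height medians are log-spaced over this range
    height_median_min_cm: float = 8.0
    height_median_max_cm: float = 120.0
    height_sigma: float = 0.35
    #: sd of the lognormal plot random effect on canopy density
    sigma_plot: float = 0.2
    #: fraction of plants moved/re-sized between sampling events
    sigma_event: float = 0.15
    #: edge buffer (cm) so canopies rooted outside the plot still overlap it
    buffer_cm: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.events_min < 1 or self.events_max < self.events_min:
            raise ValueError("invalid plot/event counts")
        if not (0 <= self.cover_min <= self.cover_max < 1):
            raise ValueError("cover targets must satisfy 0 <= min <= max < 1")
        if self.offspring_mean <= 0 or self.radius_median_cm <= 0:
            raise ValueError("rates and scales must be positive")
        if not 0 <= self.sigma_event <= 1:
            raise ValueError("sigma_event is a fraction in [0, 1]")

    @property
    def species_codes(self) -> list[str]:
        return [f"SP{i + 1:02d}" for i in range(self.n_species)]

    @property
    def abundances(self) -> np.ndarray:
        w = self.abundance_decay ** np.arange(self.n_species)
        return w / w.sum()

    @property
    def height_medians_cm(self) -> np.ndarray:
        return np.geomspace(
            self.height_median_min_cm, self.height_median_max_cm, self.n_species
        )

    @property
    def mean_sq_radius_cm2(self) -> float:
        """E[r^2] of the lognormal radius distribution."""
        return self.radius_median_cm**2 * math.exp(2 * self.radius_sigma**2)

    def _radius_quadrature(self, n: int = 24):
        """Gauss-Hermite nodes/weights for the lognormal radius."""
        if self.radius_sigma == 0:
            return np.array([self.radius_median_cm]), np.array([1.0])
        x, w = np.polynomial.hermite.hermgauss(n)
        r = self.radius_median_cm * np.exp(self.radius_sigma * math.sqrt(2.0) * x)
        return r, w / math.sqrt(math.pi)

    def cluster_coverage_integral_cm2(self) -> float:
        """The per-parent coverage integral I of the Thomas disk model.

        A point is left uncovered with probability exp(-lambda_p * I),
        where I = int_0^inf (1 - exp(-mu_c * q(s))) * 2*pi*s ds and q(s)
        is the probability that one offspring disk of a parent at
        distance s covers the point (a noncentral-chi-square tail,
        averaged over the radius distribution). Under weak clustering
        (mu_c * q small) I reduces to the Boolean-model value
        mu_c * pi * E[r^2]; within-cluster canopy overlap makes I
        smaller, i.e. clustered plants cover less area per plant.
        """
        from scipy import stats as _st

        r, w = self._radius_quadrature()
        sc = self.cluster_sd_cm
        s = np.linspace(0.0, 6.0 * sc + float(r.max()), 800)
        if sc > 0:
            q = (
                w[None, :]
                * _st.ncx2.cdf((r[None, :] / sc) ** 2, 2, (s[:, None] / sc) ** 2)
            ).sum(axis=1)
        else:
            q = (w[None, :] * (s[:, None] <= r[None, :])).sum(axis=1)
        integrand = (1.0 - np.exp(-self.offspring_mean * q)) * 2.0 * math.pi * s
        return float(np.trapezoid(integrand, s))

    def density_for_cover(self, cover: float) -> float:
        """Canopy density (disks per cm^2) whose Thomas-model point
        coverage equals ``cover``, accounting for within-cluster overlap."""
        lam_parent = -math.log(1.0 - cover) / self.cluster_coverage_integral_cm2()
        return lam_parent * self.offspring_mean


@dataclass
class PlantMap:
    """Simulated plant canopies on one plot (disk model).

    Coordinates are centimeters with the plot center at the origin;
    plants may be rooted in the edge buffer outside the 1-ha square.
    """

    x_cm: np.ndarray
    y_cm: np.ndarray
    radius_cm: np.ndarray
    species: np.ndarray  # integer index into the config species pool
    height_cm: np.ndarray

    @property
    def n_plants(self) -> int:
        return len(self.x_cm)


def _draw_attributes(config: SyntheticConfig, n: int, rng: np.random.Generator):
    radius = config.radius_median_cm * np.exp(
        rng.normal(0.0, config.radius_sigma, n)
    )
    species = rng.choice(config.n_species, size=n, p=config.abundances)
    height = config.height_medians_cm[species] * np.exp(
        rng.normal(0.0, config.height_sigma, n)
    )
    return radius, species, height


def generate_plant_map(
    config: SyntheticConfig,
    rng: np.random.Generator,
    parent_intensity_per_ha: float | None = None,
) -> PlantMap:
    """Draw one Thomas-cluster plant map over the buffered plot.

    Parent intensity comes from the argument, else the config field;
    one of the two must be set.
    """
    lam = parent_intensity_per_ha
    if lam is None:
        lam = config.parent_intensity_per_ha
    if lam is None:
        raise ValueError("parent intensity not specified (argument or config)")
    if lam < 0:
        raise ValueError("parent intensity must be >= 0")
    half = FIELD_HALF_CM + config.buffer_cm
    area_ha = (2 * half) ** 2 / 1e8
    n_parents = rng.poisson(lam * area_ha)
    px = rng.uniform(-half, half, n_parents)
    py = rng.uniform(-half, half, n_parents)
    counts = rng.poisson(config.offspring_mean, n_parents)
    x = np.repeat(px, counts)
    y = np.repeat(py, counts)
    n = len(x)
    if config.cluster_sd_cm > 0:
        x = x + rng.normal(0.0, config.cluster_sd_cm, n)
        y = y + rng.normal(0.0, config.cluster_sd_cm, n)
    radius, species, height = _draw_attributes(config, n, rng)
    return PlantMap(x, y, radius, species, height)


def generate_poisson_map(
    config: SyntheticConfig, rng: np.random.Generator, intensity_per_ha: float
) -> PlantMap:
    """Stationary Poisson disk field (no clustering).

    The limiting un-clustered case, used for Boolean-model oracle checks:
    point coverage is exactly 1 - exp(-lambda * pi * E[r^2]).
    """
    if intensity_per_ha < 0:
        raise ValueError("intensity must be >= 0")
    half = FIELD_HALF_CM + config.buffer_cm
    area_ha = (2 * half) ** 2 / 1e8
    n = rng.poisson(intensity_per_ha * area_ha)
    x = rng.uniform(-half, half, n)
    y = rng.uniform(-half, half, n)
    radius, species, height = _draw_attributes(config, n, rng)
    return PlantMap(x, y, radius, species, height)


def perturb_map(
    pmap: PlantMap, config: SyntheticConfig, rng: np.random.Generator
) -> PlantMap:
    """Event-to-event perturbation: move and re-size a fraction of plants.

    Selected plants are displaced by the cluster-scale Gaussian and get
    fresh radii/heights from their species distributions; the rest of the
    map is shared across events, which creates the within-plot
    repeat-measures correlation the nested analysis assumes.
    """
    n = pmap.n_plants
    n_move = int(round(config.sigma_event * n))
    if n_move == 0:
        return pmap
    idx = rng.choice(n, size=n_move, replace=False)
    x = pmap.x_cm.copy()
    y = pmap.y_cm.copy()
    radius = pmap.radius_cm.copy()
    height = pmap.height_cm.copy()
    sd = config.cluster_sd_cm if config.cluster_sd_cm > 0 else config.radius_median_cm
    x[idx] = x[idx] + rng.normal(0.0, sd, n_move)
    y[idx] = y[idx] + rng.normal(0.0, sd, n_move)
    radius[idx] = config.radius_median_cm * np.exp(
        rng.normal(0.0, config.radius_sigma, n_move)
    )
    height[idx] = config.height_medians_cm[pmap.species[idx]] * np.exp(
        rng.normal(0.0, config.height_sigma, n_move)
    )
    return PlantMap(x, y, radius, pmap.species, height)


def _transect_intervals(pmap: PlantMap, azimuth_deg: float, length_cm: float):
    """Canopy chords along one radial transect.

    Returns (a, b, plant_idx): for each disk crossing the transect line
    within [0, length], the chord interval [a, b] in along-transect cm
    and the index of the plant.
    """
    az = math.radians(azimuth_deg)
    ux, uy = math.sin(az), math.cos(az)
    t0 = pmap.x_cm * ux + pmap.y_cm * uy
    dperp = np.abs(pmap.x_cm * uy - pmap.y_cm * ux)
    near = dperp < pmap.radius_cm
    if not near.any():
        z = np.empty(0)
        return z, z, np.empty(0, dtype=int)
    idx = np.flatnonzero(near)
    h = np.sqrt(pmap.radius_cm[idx] ** 2 - dperp[idx] ** 2)
    a = t0[idx] - h
    b = t0[idx] + h
    keep = (b > 0) & (a < length_cm)
    idx, a, b = idx[keep], a[keep], b[keep]
    return np.clip(a, 0, length_cm), np.clip(b, 0, length_cm), idx


def _uncovered_gaps(a: np.ndarray, b: np.ndarray, length_cm: int):
    """Integer-cm maximal uncovered intervals of [0, length]."""
    gaps = []
    if len(a) == 0:
        return [(0, length_cm)] if length_cm >= MIN_GAP_CM else []
    order = np.argsort(a)
    a, b = a[order], b[order]
    cursor = 0.0
    for ai, bi in zip(a, b):
        if ai > cursor:
            gaps.append((cursor, ai))
        cursor = max(cursor, bi)
    if cursor < length_cm:
        gaps.append((cursor, float(length_cm)))
    out = []
    for lo, hi in gaps:
        start = int(math.ceil(round(lo, 6)))
        end = int(math.floor(round(hi, 6)))
        if end - start >= MIN_GAP_CM:
            out.append((start, end))
    return out


def sample_transects(
    pmap: PlantMap,
    layout: pd.DataFrame,
    config: SyntheticConfig,
    plot_id: str,
    event_id: str,
) -> PlotEventDataset:
    """Run the three field methods over a plant map.

    LPI pins every 25 cm record the species of every intercepting canopy,
    tallest first, or the no-hit marker; canopy gaps are the uncovered
    intervals >= 5 cm; height points every 2 m record the maximum canopy
    height among intercepting plants, absent when uncovered.
    """
    codes = np.array(config.species_codes)
    pin_rows, gap_rows, height_rows = [], [], []
    for row in layout.itertuples(index=False):
        tid, az, length = row.transect_id, row.azimuth_deg, int(row.length_cm)
        a, b, idx = _transect_intervals(pmap, az, length)

        pins = np.arange(BASE_LPI_INTERVAL_CM, length + 1, BASE_LPI_INTERVAL_CM)
        if len(idx):
            cover = (a[None, :] <= pins[:, None]) & (pins[:, None] <= b[None, :])
        else:
            cover = np.zeros((len(pins), 0), dtype=bool)
        for pi, pos in enumerate(pins):
            hit = idx[cover[pi]]
            if len(hit) == 0:
                pin_rows.append((tid, int(pos), 1, NO_HIT_CODE))
                continue
            order = np.argsort(-pmap.height_cm[hit], kind="stable")
            seen = set()
            layer = 0
            for plant in hit[order]:
                code = codes[pmap.species[plant]]
                if code in seen:  # one layer entry per species per pin
                    continue
                seen.add(code)
                layer += 1
                pin_rows.append((tid, int(pos), layer, code))

        for start, end in _uncovered_gaps(a, b, length):
            gap_rows.append((tid, start, end))

        hpos = np.arange(BASE_HEIGHT_INTERVAL_CM, length + 1, BASE_HEIGHT_INTERVAL_CM)
        if len(idx):
            hcover = (a[None, :] <= hpos[:, None]) & (hpos[:, None] <= b[None, :])
        else:
            hcover = np.zeros((len(hpos), 0), dtype=bool)
        for pi, pos in enumerate(hpos):
            hit = idx[hcover[pi]]
            h = float(pmap.height_cm[hit].max()) if len(hit) else np.nan
            height_rows.append((tid, int(pos), h))

    pins_df = pd.DataFrame(
        pin_rows, columns=["transect_id", "position_cm", "layer", "code"]
    )
    gaps_df = pd.DataFrame(gap_rows, columns=["transect_id", "start_cm", "end_cm"])
    heights_df = pd.DataFrame(
        height_rows, columns=["transect_id", "position_cm", "height_cm"]
    )
    return PlotEventDataset(plot_id, event_id, layout.drop(columns=["plot_id"], errors="ignore").copy(), pins_df, gaps_df, heights_df)


def generate_study(config: SyntheticConfig) -> dict[tuple[str, str], PlotEventDataset]:
    """Full multi-plot, multi-event synthetic study, deterministic per seed.

    Per plot: a canopy-density target from the sparse-to-dense gradient,
    scaled by a lognormal plot effect, yields a base map; each event is
    an independent perturbation of that base map.
    """
    root = np.random.SeedSequence(config.seed)
    plot_seeds = root.spawn(config.n_plots)
    if config.parent_intensity_per_ha is not None:
        densities = np.full(
            config.n_plots,
            config.parent_intensity_per_ha * config.offspring_mean / 1e8,
        )
    else:
        lo = config.density_for_cover(config.cover_min)
        hi = config.density_for_cover(max(config.cover_max, config.cover_min + 1e-9))
        densities = np.geomspace(lo, hi, config.n_plots)
    study: dict[tuple[str, str], PlotEventDataset] = {}
    for i in range(config.n_plots):
        rng = np.random.default_rng(plot_seeds[i])
        plot_id = f"P{i + 1:02d}"
        density = densities[i] * math.exp(rng.normal(0.0, config.sigma_plot))
        parent_per_ha = density * 1e8 / config.offspring_mean
        base = generate_plant_map(config, rng, parent_intensity_per_ha=parent_per_ha)
        layout = default_layout(plot_id)
        n_events = int(rng.integers(config.events_min, config.events_max + 1))
        for j in range(n_events):
            event_id = f"E{j + 1:02d}"
            pmap = perturb_map(base, config, rng)
            study[(plot_id, event_id)] = sample_transects(
                pmap, layout, config, plot_id, event_id
            )
    return study


def simulate_differences(
    mu: float,
    sigma_b: float,
    sigma_e: float,
    k: int,
    n_i,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Direct draws from the nested difference model d_ij = mu + b_i + e_ij."""
    if sigma_b < 0 or sigma_e < 0:
        raise ValueError("standard deviations must be >= 0")
    if k < 2:
        raise ValueError("k must be >= 2")
    n_i = np.broadcast_to(np.asarray(n_i, dtype=int), (k,))
    b = rng.normal(0.0, sigma_b, k)
    rows = []
    for i in range(k):
        e = rng.normal(0.0, sigma_e, n_i[i])
        for j in range(n_i[i]):
            rows.append(
                {"plot_id": f"P{i + 1:02d}", "event_id": f"E{j + 1:02d}",
                 "d": mu + b[i] + e[j]}
            )
    return pd.DataFrame(rows)
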