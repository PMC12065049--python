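import numpy as np
import pandas as pd
import pytest

from transectopt.indicators import compute_indicator_set
from transectopt.records import default_layout, validate_dataset
from transectopt.simulate import (
    PlantMap,
    SyntheticConfig,
    generate_plant_map,
    generate_study,
    perturb_map,
    sample_transects,
    simulate_differences,
)


def _cfg(**kw):
    return SyntheticConfig(**kw)


class TestGeneratePlantMap:
    def test_zero_intensity_gives_empty_map(self):
        pmap = generate_plant_map(_cfg(), np.random.default_rng(0),
                                  parent_intensity_per_ha=0.0)
        assert pmap.n_plants == 0

    def test_deterministic_given_seed(self):
        a = generate_plant_map(_cfg(), np.random.default_rng(7),
                               parent_intensity_per_ha=40.0)
        b = generate_plant_map(_cfg(), np.random.default_rng(7),
                               parent_intensity_per_ha=40.0)
        assert np.array_equal(a.x_cm, b.x_cm)
        assert np.array_equal(a.radius_cm, b.radius_cm)

    def test_missing_intensity_rejected(self):
        with pytest.raises(ValueError, match="intensity"):
            generate_plant_map(_cfg(), np.random.default_rng(0))

    def test_mean_count_matches_cluster_process_moments(self):
        """Mean plant count over 200 seeds within 4 SE of lambda_p*mu_c*area.

        The per-map count of a Poisson cluster process has variance
        lambda_p*A*mu_c*(1+mu_c), which sets the Monte-Carlo SE.
        """
        from transectopt.simulate import FIELD_HALF_CM

        cfg = _cfg(offspring_mean=6.0, buffer_cm=500.0)
        lam, mu = 30.0, cfg.offspring_mean
        area_ha = (2 * (FIELD_HALF_CM + cfg.buffer_cm)) ** 2 / 1e8
        expect = lam * area_ha * mu
        counts = [
            generate_plant_map(cfg, np.random.default_rng(1000 + s),
                               parent_intensity_per_ha=lam).n_plants
            for s in range(200)
        ]
        se = np.sqrt(lam * area_ha * mu * (1 + mu) / 200)
        assert abs(np.mean(counts) - expect) <= 4 * se


class TestSampleTransects:
    def _single_disk_map(self):
        return PlantMap(
            x_cm=np.array([0.0]), y_cm=np.array([1000.0]),
            radius_cm=np.array([50.0]), species=np.array([0]),
            height_cm=np.array([40.0]),
        )

    def test_empty_map_gives_bare_plot(self):
        cfg = _cfg()
        pmap = PlantMap(*[np.empty(0)] * 2, np.empty(0), np.empty(0, dtype=int), np.empty(0))
        ds = sample_transects(pmap, default_layout("P01"), cfg, "P01", "E01")
        validate_dataset(ds)
        iset = compute_indicator_set(ds)
        assert iset.total_foliar_pct == 0.0
        assert iset.gap_pct["GapPct_200_plus"] == pytest.approx(100.0)
        assert iset.mean_height_cm is None

    def test_single_disk_chord_geometry(self):
        """Disk r=50 centred on the transect at 1000 cm: pins in [950, 1050]
        hit; gaps are [0, 950] and [1050, 10000]."""
        cfg = _cfg()
        layout = default_layout("P01").iloc[:1]  # azimuth 0: transect along +y
        ds = sample_transects(self._single_disk_map(), layout, cfg, "P01", "E01")
        hit = ds.pins[ds.pins["code"] != "NONE"]["position_cm"].tolist()
        assert hit == [950, 975, 1000, 1025, 1050]
        assert ds.gaps[["start_cm", "end_cm"]].to_numpy().tolist() == [
            [0, 950], [1050, 10_000]
        ]
        present = ds.heights.dropna(subset=["height_cm"])
        assert present["position_cm"].tolist() == [1000]
        assert present["height_cm"].iloc[0] == pytest.approx(40.0)

    def test_tallest_layer_recorded_first(self):
        cfg = _cfg()
        pmap = PlantMap(
            x_cm=np.array([0.0, 0.0]), y_cm=np.array([1000.0, 1000.0]),
            radius_cm=np.array([60.0, 60.0]), species=np.array([0, 1]),
            height_cm=np.array([10.0, 90.0]),
        )
        layout = default_layout("P01").iloc[:1]
        ds = sample_transects(pmap, layout, cfg, "P01", "E01")
        pin = ds.pins[ds.pins["position_cm"] == 1000].sort_values("layer")
        assert pin["code"].tolist() == ["SP02", "SP01"]  # taller species on top


class TestGenerateStudy:
    def test_no_event_perturbation_gives_identical_indicators(self):
        cfg = _cfg(n_plots=2, events_min=3, events_max=3, sigma_event=0.0,
                   cover_min=0.1, cover_max=0.3, seed=4)
        study = generate_study(cfg)
        for plot in {k[0] for k in study}:
            sets = [compute_indicator_set(ds).as_dict()
                    for key, ds in sorted(study.items()) if key[0] == plot]
            assert all(s == sets[0] for s in sets)

    def test_between_plot_variance_exceeds_within(self):
        """The density gradient plus plot effect should dominate the
        event-to-event perturbation in full-design cover."""
        cfg = _cfg(n_plots=8, events_min=3, events_max=3, cover_min=0.05,
                   cover_max=0.7, seed=21)
        study = generate_study(cfg)
        rows = [(k[0], compute_indicator_set(ds).total_foliar_pct)
                for k, ds in study.items()]
        df = pd.DataFrame(rows, columns=["plot", "cover"])
        between = df.groupby("plot")["cover"].mean().var(ddof=1)
        within = df.groupby("plot")["cover"].var(ddof=1).mean()
        assert between > within

    def test_cover_gradient_spans_configured_range(self):
        cfg = _cfg(n_plots=6, events_min=2, events_max=2, cover_min=0.05,
                   cover_max=0.8, seed=13)
        study = generate_study(cfg)
        covers = [compute_indicator_set(ds).total_foliar_pct for ds in study.values()]
        assert min(covers) < 20.0
        assert max(covers) > 55.0

    def test_all_records_validate(self, small_study):
        for ds in small_study.values():
            validate_dataset(ds)

    def test_byte_identical_given_seed(self):
        cfg = _cfg(n_plots=2, events_min=2, events_max=2, cover_min=0.1,
                   cover_max=0.3, seed=99)
        a, b = generate_study(cfg), generate_study(cfg)
        assert set(a) == set(b)
        for key in a:
            for attr in ("pins", "gaps", "heights"):
                pd.testing.assert_frame_equal(getattr(a[key], attr),
                                              getattr(b[key], attr))


class TestSimulateDifferences:
    def test_no_variance_gives_constant(self):
        diffs = simulate_differences(2.5, 0.0, 0.0, 3, [2, 2, 2],
                                     np.random.default_rng(0))
        assert (diffs["d"] == 2.5).all()

    def test_moment_recovery(self):
        """Method-of-moments estimates recover (mu, sigma_b2, sigma_e2)
        at k=200, n_i=50; tolerances follow the estimator SEs."""
        mu, sb, se_, k, n = 10.0, 2.0, 3.0, 200, 50
        diffs = simulate_differences(mu, sb, se_, k, n, np.random.default_rng(42))
        g = diffs.groupby("plot_id")["d"]
        means = g.mean()
        assert means.mean() == pytest.approx(mu, rel=0.05)
        sigma_e2 = g.apply(lambda x: x.var(ddof=1)).mean()
        assert sigma_e2 == pytest.approx(se_**2, rel=0.05)
        sigma_b2 = means.var(ddof=1) - sigma_e2 / n
        # SE(sigma_b2) ~ sqrt(2/(k-1))*(sb^2+se^2/n): ~10% here, allow 3 SE
        assert sigma_b2 == pytest.approx(sb**2, rel=0.32)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_differences(0, -1.0, 1.0, 3, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_differences(0, 1.0, 1.0, 1, 2, np.random.default_rng(0))


def test_perturbation_moves_expected_fraction():
    cfg = _cfg(sigma_event=0.2)
    rng = np.random.default_rng(17)
    pmap = generate_plant_map(cfg, rng, parent_intensity_per_ha=200.0)
    moved = perturb_map(pmap, cfg, rng)
    changed = np.mean(pmap.x_cm != moved.x_cm)
    assert changed == pytest.approx(0.2, abs=0.01)
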