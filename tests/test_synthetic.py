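"""Synthetic-data generator: grid, panel moments, spectra and whey forward model."""

import numpy as np
import pandas as pd
import pytest

from milkspec.fractionation import diffusible_from_dilution
from milkspec.synthetic import (
    ELEMENTS,
    GeneratorConfig,
    draw_mineral_panel,
    generate_dataset,
    make_wavenumber_grid,
    render_spectra,
    simulate_whey_measurements,
)


class TestWavenumberGrid:
    @pytest.mark.parametrize(
        "lo, hi, n, spacing",
        [
            (686.0, 5012.0, 1060, (5012 - 686) / 1059),
            (0.0, 1.0, 2, 1.0),
            (964.5, 1562.5, 11, 59.8),
        ],
    )
    def test_uniform_inclusive_grid(self, lo, hi, n, spacing):
        g = make_wavenumber_grid(lo, hi, n)
        assert g.size == n
        assert g[0] == lo and g[-1] == hi
        assert np.allclose(np.diff(g), spacing)
        assert np.all(np.diff(g) > 0)

    @pytest.mark.parametrize("lo, hi, n", [(0, 1, 1), (0, 1, 0), (5, 5, 10), (6, 5, 10)])
    def test_invalid_config(self, lo, hi, n):
        with pytest.raises(ValueError):
            make_wavenumber_grid(lo, hi, n)


class TestMineralPanel:
    def test_partition_identity_exact(self, rng):
        panel = draw_mineral_panel(GeneratorConfig(n_samples=200, seed=3), rng)
        d = panel.data
        assert np.all(d["total"] - d["diffusible"] - d["micellar"] == 0.0)
        assert np.all(d["total"] > 0)

    def test_micellar_na_identically_zero(self, rng):
        panel = draw_mineral_panel(GeneratorConfig(n_samples=50, seed=4), rng)
        na = panel.data[panel.data["element"] == "Na"]
        assert np.all(na["micellar"].to_numpy() == 0.0)

    def test_moments_match_configuration(self):
        cfg = GeneratorConfig(n_samples=10_000, seed=5)
        panel = draw_mineral_panel(cfg, np.random.default_rng(cfg.seed))
        for el in ELEMENTS:
            p = cfg.element_params[el]
            total = panel.trait(f"{el}_total")
            se_mean = p.total_sd / np.sqrt(total.size)
            assert abs(total.mean() - p.total_mean) < 3 * se_mean
            se_sd = p.total_sd / np.sqrt(2 * total.size)
            assert abs(np.std(total, ddof=1) - p.total_sd) < 3 * se_sd

    def test_ratio_consistent(self, rng):
        panel = draw_mineral_panel(GeneratorConfig(n_samples=30, seed=6), rng)
        ca = panel.data[panel.data["element"] == "Ca"]
        np.testing.assert_allclose(
            ca["ratio_micellar_diffusible"], ca["micellar"] / ca["diffusible"]
        )

    def test_optional_total_correlation(self):
        corr = np.eye(5)
        corr[0, 1] = corr[1, 0] = 0.8  # Ca-P
        cfg = GeneratorConfig(n_samples=5000, seed=7, total_correlation=corr)
        panel = draw_mineral_panel(cfg, np.random.default_rng(cfg.seed))
        r = np.corrcoef(panel.trait("Ca_total"), panel.trait("P_total"))[0, 1]
        assert 0.7 < r < 0.9


class TestRenderSpectra:
    def test_no_noise_no_signal_identical_rows(self, rng):
        cfg = GeneratorConfig(n_samples=8, seed=0, noise_sd=0.0, signal_strength=0.0)
        panel = draw_mineral_panel(cfg, rng)
        spectra, _ = render_spectra(panel, cfg, rng)
        assert np.all(spectra.values == spectra.values[0])

    def test_transmittance_absorbance_roundtrip(self, default_dataset):
        a = default_dataset.absorbance.values
        t = default_dataset.transmittance.values
        np.testing.assert_allclose(np.log10(1.0 / t), a, atol=1e-12)
        assert np.all((t > 0) & (t <= 1))

    def test_ols_at_exclusive_planted_variable_recovers_signal(self, rng):
        cfg = GeneratorConfig(n_samples=60, seed=1, noise_sd=0.0)
        panel = draw_mineral_panel(cfg, rng)
        spectra, truth = render_spectra(panel, cfg, rng)
        others = np.concatenate(
            [cols for t, cols in truth.items() if t != "Ca_total"]
        )
        exclusive = np.setdiff1d(truth["Ca_total"], others)
        assert exclusive.size > 0
        y = panel.trait("Ca_total")
        a = spectra.values[:, exclusive[0]]
        slope = np.polyfit(y, a, 1)[0]
        assert abs(slope - cfg.signal_strength) <= 1e-8

    def test_truth_mask_within_selected_regions(self, default_dataset):
        cfg = default_dataset.config
        mask = cfg.regions.contains(cfg.wavenumbers)
        selected = set(np.flatnonzero(mask))
        for cols in default_dataset.truth_mask.values():
            assert set(cols) <= selected

    def test_planted_interval_out_of_range_rejected(self, rng):
        cfg = GeneratorConfig(
            n_samples=5, seed=0, planted_intervals={"Ca_total": [999]}
        )
        panel = draw_mineral_panel(cfg, rng)
        with pytest.raises(ValueError, match="outside partition range"):
            render_spectra(panel, cfg, rng)


class TestWheyForwardModel:
    @pytest.fixture
    def panel_d27(self):
        """Single-sample panel whose diffusible concentrations are all 27."""
        rows = [
            {"sample_id": "S0", "element": el, "total": 54.0, "diffusible": 27.0,
             "micellar": 27.0, "ratio_micellar_diffusible": 1.0}
            for el in ELEMENTS
        ]
        from milkspec.synthetic import MineralPanel

        return MineralPanel(pd.DataFrame(rows))

    def test_one_ml_excluded_volume(self, panel_d27):
        whey = simulate_whey_measurements(panel_d27, excluded_volume=1.0)
        np.testing.assert_allclose(whey["c_whey"], 30.0)
        np.testing.assert_allclose(whey["c_diluted_whey"], 40.0 / 3.0)

    def test_zero_excluded_volume(self, panel_d27):
        whey = simulate_whey_measurements(panel_d27, excluded_volume=0.0)
        np.testing.assert_allclose(whey["c_whey"], 27.0)
        np.testing.assert_allclose(whey["c_diluted_whey"], 13.5)

    @pytest.mark.parametrize("v_ex", [0.0, 0.7, 1.0, 2.5, 4.9])
    def test_roundtrip_through_mass_balance(self, panel_d27, v_ex):
        whey = simulate_whey_measurements(panel_d27, excluded_volume=v_ex)
        for rec in whey.itertuples():
            res = diffusible_from_dilution(rec.c_whey, rec.c_diluted_whey)
            assert abs(res.diffusible - 27.0) <= 1e-9

    def test_excluded_volume_bounds(self, panel_d27):
        with pytest.raises(ValueError):
            simulate_whey_measurements(panel_d27, excluded_volume=5.0)
        with pytest.raises(ValueError):
            simulate_whey_measurements(panel_d27, excluded_volume=-0.1)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = dict(n_samples=25, seed=99, n_points=300)
        a = generate_dataset(GeneratorConfig(**cfg))
        b = generate_dataset(GeneratorConfig(**cfg))
        assert np.array_equal(a.absorbance.values, b.absorbance.values)
        assert a.panel.data.equals(b.panel.data)
        assert a.whey.equals(b.whey)
        assert all(
            np.array_equal(a.truth_mask[t], b.truth_mask[t]) for t in a.truth_mask
        )
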