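"""Generators: spectra library, camera forward model, cohorts, chromatograms."""

import numpy as np
import pandas as pd
import pytest

from wingsignal.lcms import COMPOUNDS
from wingsignal.spectra import GRID, Spectrum
from wingsignal.synthetic import (
    FAMILIES,
    RESPONSE_FACTORS,
    RawPatch,
    ScenarioConfig,
    make_chromatogram,
    make_cohort,
    make_reflectance_library,
    render_patch,
)


class TestReflectanceLibrary:
    def test_black_template_bounded_below_ten_percent(self):
        (fam, spec), = make_reflectance_library(1, {"black_scale"}, seed=1)
        assert fam == "black_scale"
        assert spec.value.min() >= 0.0 and spec.value.max() <= 0.1

    def test_deterministic_under_seed(self):
        a = make_reflectance_library(5, {"red_marking"}, seed=7)
        b = make_reflectance_library(5, {"red_marking"}, seed=7)
        assert all(x[1] == y[1] for x, y in zip(a, b))

    def test_red_family_reflects_long_wavelengths(self):
        lib = make_reflectance_library(3, seed=2)
        assert len(lib) == 15
        for fam, spec in lib:
            if fam != "red_marking":
                continue
            above = spec.value[spec.wavelength_nm > 600].mean()
            below = spec.value[spec.wavelength_nm < 500].mean()
            assert above > below

    def test_unknown_family_rejected_with_valid_names(self):
        with pytest.raises(ValueError, match="red_marking"):
            make_reflectance_library(1, {"chartreuse"}, seed=0)


class TestRenderPatch:
    def test_flat_seven_percent_equals_standard(self, camera, illum):
        grey = Spectrum(GRID, np.full_like(GRID, 0.07))
        patch = render_patch(grey, camera, illum, noise_sd=0.0)
        np.testing.assert_allclose(patch.channel_values, patch.std7_values, rtol=1e-12)

    def test_linear_camera_matches_quadrature(self, illum):
        from wingsignal.spectra import make_camera

        cam1 = make_camera(response_exponent=1.0)
        red = make_reflectance_library(1, {"red_marking"}, seed=3)[0][1]
        patch = render_patch(red, cam1, illum, gain_jitter=1.0, noise_sd=0.0)
        expected = [
            np.trapezoid(red.value * illum.value * ch.value, GRID)
            for ch in cam1.channel_sensitivities
        ]
        np.testing.assert_allclose(patch.channel_values, expected, rtol=1e-12)

    def test_gain_doubles_linearly_at_exponent_one(self, illum):
        from wingsignal.spectra import make_camera

        cam1 = make_camera(response_exponent=1.0)
        red = make_reflectance_library(1, {"red_marking"}, seed=3)[0][1]
        p1 = render_patch(red, cam1, illum, gain_jitter=1.0, noise_sd=0.0)
        p2 = render_patch(red, cam1, illum, gain_jitter=2.0, noise_sd=0.0)
        np.testing.assert_allclose(p2.channel_values, 2 * p1.channel_values, rtol=1e-12)
        np.testing.assert_allclose(p2.std93_values, 2 * p1.std93_values, rtol=1e-12)

    def test_grid_mismatch_rejected(self, camera, illum):
        short = Spectrum(GRID[:200], np.full(200, 0.5))
        with pytest.raises(ValueError, match="grid"):
            render_patch(short, camera, illum)

    def test_inverted_standards_rejected(self):
        with pytest.raises(ValueError, match="standard"):
            RawPatch(np.ones(4), np.full(4, 2.0), np.full(4, 1.0))


class TestCohort:
    def test_deterministic(self):
        cfg = ScenarioConfig(n_populations=2, n_per_pop_per_sex=3, seed=11)
        a, b = make_cohort(cfg), make_cohort(cfg)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.patches, b.patches)

    def test_females_heavier_than_males(self):
        cfg = ScenarioConfig(n_populations=2, n_per_pop_per_sex=40, seed=1)
        t = make_cohort(cfg, render_patches=False).truth
        means = t.groupby("sex")["mass_mg"].mean()
        assert means["F"] > means["M"]

    def test_null_scenario_decorrelates_concentration_and_colour(self):
        """With honesty_slope = 0 the ground-truth colour latents and the
        quadrature metrics are independent of toxin concentration."""
        cfg = ScenarioConfig(
            n_populations=1, n_per_pop_per_sex=1000, honesty_slope=0.0, seed=21
        )
        t = make_cohort(cfg, render_patches=False).truth
        conc = np.log(t["concentration_nmol_per_mg"])
        for col in (
            "fw_latent_luminance", "fw_latent_redness", "fw_luminance",
            "fw_saturation", "fw_hue", "hw_luminance",
        ):
            r = np.corrcoef(conc, t[col])[0, 1]
            assert abs(r) < 0.05, f"{col}: |r|={abs(r):.3f}"

    def test_honest_scenario_couples_target_latent(self):
        cfg = ScenarioConfig(
            n_populations=1, n_per_pop_per_sex=1000, honesty_slope=0.6, seed=22
        )
        t = make_cohort(cfg, render_patches=False).truth
        conc = np.log(t["concentration_nmol_per_mg"])
        r = np.corrcoef(conc, t["fw_latent_luminance"])[0, 1]
        assert r == pytest.approx(0.6, abs=0.06)

    def test_total_amount_is_concentration_times_mass(self):
        cfg = ScenarioConfig(n_populations=1, n_per_pop_per_sex=10, seed=2)
        t = make_cohort(cfg, render_patches=False).truth
        np.testing.assert_allclose(
            t["total_nmol"], t["concentration_nmol_per_mg"] * t["mass_mg"]
        )

    def test_nonfinite_slope_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(honesty_slope=float("nan"))


class TestChromatogram:
    def test_zero_amounts_flat_baseline(self):
        c = make_chromatogram({"linamarin": 0.0, "lotaustralin": 0.0},
                              is_amount_nmol=0.0, noise_sd=0.0)
        for mz, trace in c.traces.items():
            assert np.ptp(trace) == pytest.approx(0.0)

    def test_peak_area_matches_closed_form(self):
        """Noise-free integrated area equals amount x response factor: the
        Gaussian profile integrates analytically to its prefactor."""
        from wingsignal.lcms import extract_eic, integrate_peak

        c = make_chromatogram({"linamarin": 10.0, "lotaustralin": 4.0}, noise_sd=0.0)
        for compound, amount in (("linamarin", 10.0), ("lotaustralin", 4.0),
                                 ("amygdalin", 44.0)):
            mz, rt = COMPOUNDS[compound]
            area = integrate_peak(*extract_eic(c, mz, rt, 0.6))
            assert area == pytest.approx(amount * RESPONSE_FACTORS[compound], rel=1e-3)

    def test_drift_cancels_in_area_ratio(self):
        from wingsignal.lcms import peak_area

        amounts = {"linamarin": 8.0, "lotaustralin": 3.0}
        c1 = make_chromatogram(amounts, drift=1.0, noise_sd=0.0)
        c2 = make_chromatogram(amounts, drift=0.37, noise_sd=0.0)
        r1 = peak_area(c1, "linamarin") / peak_area(c1, "amygdalin")
        r2 = peak_area(c2, "linamarin") / peak_area(c2, "amygdalin")
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_negative_amounts_rejected(self):
        with pytest.raises(ValueError):
            make_chromatogram({"linamarin": -1.0})

    def test_apex_at_catalogued_retention_time(self):
        c = make_chromatogram({"linamarin": 5.0, "lotaustralin": 5.0}, noise_sd=0.0)
        for compound, (mz, rt) in COMPOUNDS.items():
            apex = c.time_min[np.argmax(c.traces[mz])]
            assert apex == pytest.approx(rt, abs=0.05)
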