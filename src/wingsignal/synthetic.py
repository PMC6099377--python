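"""Synthetic-data generators: spectra, camera patches, cohorts, chromatograms.

Every input the analysis pipeline consumes can be simulated here with known
ground truth, so calibration, visual modelling, quantification and the
statistical tests can all be checked for recovery. Cohorts are generated
under explicit signal-honesty scenarios: the slope linking toxin
concentration to a designated colour latent is a config knob (positive =
honest, zero = null, negative = dishonest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discrimination import chromatic_jnd, luminance_jnd
from .lcms import COMPOUNDS, IS_AMOUNT_NMOL, Chromatogram
from .metrics import hue_channel, standardize_catches, tetra_saturation
from .spectra import (
    GRID,
    CameraSystem,
    Spectrum,
    VisualSystem,
    illuminant_d65like,
    make_camera,
    make_visual_system,
    same_grid,
)
from .visual import cone_catch_from_spectrum

FAMILIES = ("red_marking", "black_scale", "green_leaf", "yellow_petal", "purple_petal")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# reflectance templates
# ---------------------------------------------------------------------------

def red_marking_spectrum(
    amplitude: float = 0.50,
    edge_nm: float = 583.0,
    steepness_nm: float = 18.0,
    pedestal: float = 0.05,
    uv_sheen: float = 0.0,
    wavelength_nm: np.ndarray = GRID,
) -> Spectrum:
    """Red wing marking: a logistic reflectance step rising past ``edge_nm``.

    ``amplitude`` sets long-wavelength reflectance (lightness), ``pedestal``
    the short-wavelength floor (lower pedestal = purer, more saturated red)
    and ``uv_sheen`` a weak independent UV reflection from the scale
    surface, giving the chroma a second dimension as in real pigmentary
    colours.
    """
    wl = np.asarray(wavelength_nm, float)
    r = (
        pedestal
        + amplitude * _logistic((wl - edge_nm) / steepness_nm)
        + uv_sheen * np.exp(-0.5 * ((wl - 350.0) / 32.0) ** 2)
    )
    return Spectrum(wl, np.clip(r, 0.0, 1.5))


def black_scale_spectrum(
    level: float = 0.035,
    tilt: float = 0.01,
    uv_sheen: float = 0.0,
    wavelength_nm: np.ndarray = GRID,
) -> Spectrum:
    """Dark melanised scales: low and nearly flat, with two chromatic nuisances.

    ``tilt`` is a gentle long-wavelength rise (melanin absorbs more at short
    wavelengths); ``uv_sheen`` a weak UV reflection from the scale surface.
    Both are small in absolute terms but matter relative to the low level.
    """
    wl = np.asarray(wavelength_nm, float)
    r = (
        level
        + tilt * (wl - 300.0) / 400.0
        + uv_sheen * np.exp(-0.5 * ((wl - 345.0) / 35.0) ** 2)
    )
    return Spectrum(wl, np.clip(r, 0.0, 0.099))


def green_leaf_spectrum(
    peak_height: float = 0.13, wavelength_nm: np.ndarray = GRID
) -> Spectrum:
    """Chlorophyll-like leaf: green bump at 550 nm between blue/red troughs."""
    wl = np.asarray(wavelength_nm, float)
    r = 0.04 + peak_height * np.exp(-0.5 * ((wl - 552.0) / 38.0) ** 2)
    r = r + 0.35 * _logistic((wl - 706.0) / 8.0)  # red-edge shoulder, mostly >700
    return Spectrum(wl, np.clip(r, 0.0, 1.5))


def yellow_petal_spectrum(
    plateau: float = 0.55, cuton_nm: float = 515.0, wavelength_nm: np.ndarray = GRID
) -> Spectrum:
    """Yellow flower (bird's-foot trefoil): reflectance plateau above ~515 nm."""
    wl = np.asarray(wavelength_nm, float)
    r = 0.06 + plateau * _logistic((wl - cuton_nm) / 22.0)
    return Spectrum(wl, np.clip(r, 0.0, 1.5))


def purple_petal_spectrum(
    blue_height: float = 0.30, red_plateau: float = 0.30, wavelength_nm: np.ndarray = GRID
) -> Spectrum:
    """Lilac/purple flower (field scabious): blue-UV hump plus red shoulder."""
    wl = np.asarray(wavelength_nm, float)
    r = (
        0.08
        + blue_height * np.exp(-0.5 * ((wl - 425.0) / 55.0) ** 2)
        + red_plateau * _logistic((wl - 635.0) / 28.0)
    )
    return Spectrum(wl, np.clip(r, 0.0, 1.5))


def make_reflectance_library(
    n_per_family: int,
    families=FAMILIES,
    seed: int | np.random.Generator = 0,
    wavelength_nm: np.ndarray = GRID,
) -> list[tuple[str, Spectrum]]:
    """Jittered parametric spectra, ``n_per_family`` per requested family.

    Deterministic under seed; returns (family, Spectrum) pairs in a fixed
    family order.
    """
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    bad = set(families) - set(FAMILIES)
    if bad:
        raise ValueError(f"unknown families {sorted(bad)}; valid: {list(FAMILIES)}")
    rng = _rng(seed)
    out: list[tuple[str, Spectrum]] = []
    for fam in FAMILIES:  # fixed order for determinism
        if fam not in families:
            continue
        for _ in range(n_per_family):
            if fam == "red_marking":
                s = red_marking_spectrum(
                    amplitude=rng.uniform(0.35, 0.65),
                    edge_nm=rng.uniform(570.0, 598.0),
                    steepness_nm=rng.uniform(14.0, 24.0),
                    pedestal=rng.uniform(0.02, 0.08),
                    wavelength_nm=wavelength_nm,
                )
            elif fam == "black_scale":
                s = black_scale_spectrum(
                    level=rng.uniform(0.02, 0.06),
                    tilt=rng.uniform(0.0, 0.02),
                    wavelength_nm=wavelength_nm,
                )
            elif fam == "green_leaf":
                s = green_leaf_spectrum(
                    peak_height=rng.uniform(0.09, 0.18), wavelength_nm=wavelength_nm
                )
            elif fam == "yellow_petal":
                s = yellow_petal_spectrum(
                    plateau=rng.uniform(0.4, 0.7),
                    cuton_nm=rng.uniform(505.0, 525.0),
                    wavelength_nm=wavelength_nm,
                )
            else:
                s = purple_petal_spectrum(
                    blue_height=rng.uniform(0.2, 0.4),
                    red_plateau=rng.uniform(0.2, 0.4),
                    wavelength_nm=wavelength_nm,
                )
            out.append((fam, s))
    return out


# ---------------------------------------------------------------------------
# camera forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawPatch:
    """Raw 4-channel camera responses for one patch plus in-frame standards."""

    channel_values: np.ndarray
    std7_values: np.ndarray
    std93_values: np.ndarray
    area_mm2: float = 1.0
    scale_px_per_mm: float = 100.0

    def __post_init__(self) -> None:
        for name in ("channel_values", "std7_values", "std93_values"):
            v = np.asarray(getattr(self, name), float)
            if v.shape != (4,) or np.any(v < 0):
                raise ValueError(f"{name} must be 4 non-negative values")
            object.__setattr__(self, name, v)
        if not np.all(self.std93_values > self.std7_values):
            raise ValueError("93% standard must exceed 7% standard in every channel")
        if self.area_mm2 <= 0:
            raise ValueError("patch area must be positive")


def _linear_channel_response(
    refl: Spectrum, camera: CameraSystem, illum: Spectrum
) -> np.ndarray:
    wl = same_grid(refl, illum, *camera.channel_sensitivities)
    return np.array(
        [np.trapezoid(refl.value * illum.value * ch.value, wl)
         for ch in camera.channel_sensitivities]
    )


def render_patch(
    refl: Spectrum,
    camera: CameraSystem,
    illum: Spectrum,
    gain_jitter: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    area_mm2: float = 1.0,
) -> RawPatch:
    """Forward-model one photographed patch with its grey standards.

    Linear response per channel is the reflectance x illuminant x sensitivity
    integral, scaled by a frame-level gain, with multiplicative Gaussian
    sensor noise of relative sd ``noise_sd`` (photon/read noise acts on the
    linear signal), then passed through the camera's power-law response.
    The 7%/93% standards go through the identical path within the same frame.
    """
    rng = _rng(seed)
    g = camera.response_exponent
    lin = gain_jitter * _linear_channel_response(refl, camera, illum)
    wl = refl.wavelength_nm
    r7, r93 = camera.standard_reflectances
    lin7 = gain_jitter * _linear_channel_response(
        Spectrum(wl, np.full_like(wl, r7)), camera, illum
    )
    lin93 = gain_jitter * _linear_channel_response(
        Spectrum(wl, np.full_like(wl, r93)), camera, illum
    )

    def shoot(linear: np.ndarray) -> np.ndarray:
        v = linear
        if noise_sd > 0:
            v = v * (1.0 + rng.normal(0.0, noise_sd, size=4))
        return np.clip(v, 0.0, None) ** g

    return RawPatch(shoot(lin), shoot(lin7), shoot(lin93), area_mm2=area_mm2)


def true_channel_reflectance(
    refl: Spectrum, camera: CameraSystem, illum: Spectrum
) -> np.ndarray:
    """Ground-truth calibrated value: illuminant-weighted mean reflectance per channel."""
    wl = same_grid(refl, illum, *camera.channel_sensitivities)
    out = []
    for ch in camera.channel_sensitivities:
        w = illum.value * ch.value
        out.append(np.trapezoid(refl.value * w, wl) / np.trapezoid(w, wl))
    return np.array(out)


# ---------------------------------------------------------------------------
# specimen cohorts
# ---------------------------------------------------------------------------

#: colour latents; honesty_slope acts on the one named in ScenarioConfig
LATENTS = ("luminance", "redness", "darkness", "spot_area")


@dataclass
class ScenarioConfig:
    """Knobs of a simulated field study.

    ``honesty_slope`` is the standardized effect of toxin concentration on
    the designated colour latent (``target_latent``): the honest scenario
    uses a positive slope, the null scenario zero, the dishonest scenario a
    negative slope. ``sex_effects`` are male-minus-female offsets in latent
    SD units; defaults encode redder/more saturated males and relatively
    larger female spots. Masses are in mg fresh weight; concentration is
    lognormal in nmol per mg.
    """

    n_populations: int = 3
    n_per_pop_per_sex: int = 12
    honesty_slope: float = 0.0
    target_latent: str = "luminance"
    sex_effects: dict[str, float] = field(
        default_factory=lambda: {
            "luminance": 0.0, "redness": 0.8, "darkness": 0.0, "spot_area": -0.8,
        }
    )
    toxin_lognormal_params: tuple[float, float] = (-0.5, 0.4)
    mass_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"F": (65.0, 8.0), "M": (48.0, 6.0)}
    )
    noise_sd: float | dict[str, float] = field(
        default_factory=lambda: {
            "luminance": 0.8, "redness": 0.5, "darkness": 0.8, "spot_area": 0.8,
        }
    )
    population_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.n_per_pop_per_sex < 1:
            raise ValueError("counts must be >= 1")
        if not np.isfinite(self.honesty_slope):
            raise ValueError("honesty_slope must be finite")
        if self.target_latent not in LATENTS:
            raise ValueError(f"target_latent must be one of {LATENTS}")
        if isinstance(self.noise_sd, (int, float)):
            self.noise_sd = {lat: float(self.noise_sd) for lat in LATENTS}
        if min(self.noise_sd.values()) < 0 or self.population_sd < 0:
            raise ValueError("noise/population sd must be >= 0")
        if self.toxin_lognormal_params[1] < 0:
            raise ValueError("toxin sigma must be >= 0")


@dataclass
class Cohort:
    """Simulated specimens: ground truth, raw patches, true spectra."""

    truth: pd.DataFrame
    patches: pd.DataFrame
    spectra: dict[tuple[str, str], Spectrum]
    config: ScenarioConfig


#: wing regions rendered per specimen
REGIONS = ("fw_red", "fw_black", "hw_red", "hw_black")


def _region_spectrum(region: str, latents: dict[str, float]) -> Spectrum:
    if region.endswith("_red"):
        # lightness from the luminance latent, colour purity from redness:
        # a lower short-wavelength pedestal gives a purer (more saturated,
        # redder by the LW-ratio measure) marking; edge position and
        # steepness vary independently, as in real pigmentary spectra
        amp = float(np.clip(0.50 + 0.12 * latents["luminance"], 0.10, 0.90))
        ped = 0.050 * float(np.exp(-0.35 * latents["redness"]))
        return red_marking_spectrum(
            amplitude=amp,
            edge_nm=latents["edge_nm"],
            steepness_nm=latents["steepness_nm"],
            pedestal=min(ped, 0.20),
            uv_sheen=latents["red_uv_sheen"],
        )
    level = min(0.030 * float(np.exp(0.50 * latents["darkness"])), 0.065)
    # melanin absorbs more strongly at short wavelengths, so the spectral
    # slope scales with the pigment level itself (a relative, chromatic
    # tilt); the cap keeps the background below 10% reflectance everywhere
    slope = min(latents["black_slope"], 0.090 / level - 1.0)
    return black_scale_spectrum(
        level=level,
        tilt=level * slope,
        uv_sheen=latents["black_uv_sheen"],
    )


def make_cohort(
    config: ScenarioConfig,
    camera: CameraSystem | None = None,
    illum: Spectrum | None = None,
    system: VisualSystem | None = None,
    render_noise_sd: float = 0.002,
    render_patches: bool = True,
) -> Cohort:
    """Simulate a specimen cohort under the configured honesty scenario.

    Per specimen: sex, population, mass (females larger), lognormal toxin
    concentration, total amount = concentration x mass; per wing a set of
    colour latents = sex effect + population effect + honesty_slope x
    standardized concentration + noise; wing spectra parameterised by the
    latents and photographed through the camera forward model. The ground
    truth table carries the latents, toxin values, and quadrature colour
    metrics for the requested visual system.
    """
    camera = camera or make_camera()
    illum = illum or illuminant_d65like()
    system = system or make_visual_system("UVS")
    rng = np.random.default_rng(config.seed)
    mu, sigma = config.toxin_lognormal_params

    pop_names = [f"pop{i+1:02d}" for i in range(config.n_populations)]
    pop_fx = {
        p: {lat: rng.normal(0.0, config.population_sd) for lat in LATENTS}
        for p in pop_names
    }

    rows = []
    patch_rows = []
    spectra: dict[tuple[str, str], Spectrum] = {}
    idx = 0
    for pop in pop_names:
        for sex in ("F", "M"):
            m_mean, m_sd = config.mass_params[sex]
            for _ in range(config.n_per_pop_per_sex):
                idx += 1
                sid = f"Z{idx:04d}"
                mass = max(rng.normal(m_mean, m_sd), 5.0)
                conc = float(np.exp(rng.normal(mu, sigma)))
                # standardized concentration (analytic lognormal moments), so
                # honesty_slope is the effect per SD of concentration itself
                if sigma > 0:
                    c_mean = np.exp(mu + sigma**2 / 2.0)
                    c_sd = c_mean * np.sqrt(np.expm1(sigma**2))
                    z_conc = (conc - c_mean) / c_sd
                else:
                    z_conc = 0.0
                row = {
                    "specimen_id": sid, "population": pop, "sex": sex,
                    "mass_mg": mass, "concentration_nmol_per_mg": conc,
                    "total_nmol": conc * mass,
                    "linamarin_nmol": 0.65 * conc * mass,
                    "lotaustralin_nmol": 0.35 * conc * mass,
                }
                for wing in ("fw", "hw"):
                    latents = {}
                    for lat in LATENTS:
                        val = (
                            pop_fx[pop][lat]
                            + (config.sex_effects.get(lat, 0.0) if sex == "M" else 0.0)
                            + rng.normal(0.0, config.noise_sd[lat])
                        )
                        if lat == config.target_latent:
                            val += config.honesty_slope * z_conc
                        latents[lat] = val
                        row[f"{wing}_latent_{lat}"] = val
                    # independent template nuisance variation (not latent-linked)
                    latents["edge_nm"] = rng.normal(583.0, 4.0)
                    latents["steepness_nm"] = float(np.clip(rng.normal(18.0, 2.5), 10.0, 28.0))
                    latents["red_uv_sheen"] = rng.uniform(0.0, 0.02)
                    latents["black_slope"] = rng.uniform(0.1, 3.0)
                    latents["black_uv_sheen"] = rng.uniform(0.0, 0.08)
                    wing_area = max(rng.normal(55.0 + 0.55 * mass, 4.0), 10.0)
                    spot_frac = float(np.clip(0.22 + 0.035 * latents["spot_area"], 0.03, 0.6))
                    row[f"{wing}_wing_area_mm2"] = wing_area
                    row[f"{wing}_spot_area_mm2"] = spot_frac * wing_area
                    row[f"{wing}_rel_spot_area"] = spot_frac

                    red = _region_spectrum(f"{wing}_red", latents)
                    black = _region_spectrum(f"{wing}_black", latents)
                    spectra[(sid, f"{wing}_red")] = red
                    spectra[(sid, f"{wing}_black")] = black

                    # quadrature ground-truth colour metrics for this wing
                    qr = cone_catch_from_spectrum(red, illum, system)
                    qb = cone_catch_from_spectrum(black, illum, system)
                    rel = standardize_catches(qr.q)
                    row[f"{wing}_luminance"] = qr.double
                    row[f"{wing}_saturation"] = tetra_saturation(rel)
                    row[f"{wing}_hue"] = hue_channel(rel)
                    row[f"{wing}_chromatic_jnd"] = chromatic_jnd(qr.q, qb.q, system)
                    row[f"{wing}_luminance_jnd"] = luminance_jnd(
                        qr.double, qb.double, system.weber_omega
                    )

                    if not render_patches:
                        continue
                    gain = rng.uniform(0.85, 1.15)  # one frame per wing
                    for region, spec_ in ((f"{wing}_red", red), (f"{wing}_black", black)):
                        area = spot_frac * wing_area if region.endswith("red") else wing_area
                        patch = render_patch(
                            spec_, camera, illum, gain_jitter=gain,
                            noise_sd=render_noise_sd, seed=rng, area_mm2=area,
                        )
                        prow = {"specimen_id": sid, "region": region, "area_mm2": area}
                        for j, ch in enumerate(camera.channel_names):
                            prow[ch] = patch.channel_values[j]
                            prow[f"std7_{ch}"] = patch.std7_values[j]
                            prow[f"std93_{ch}"] = patch.std93_values[j]
                        patch_rows.append(prow)
                rows.append(row)
    return Cohort(pd.DataFrame(rows), pd.DataFrame(patch_rows), spectra, config)


# ---------------------------------------------------------------------------
# chromatograms
# ---------------------------------------------------------------------------

#: EIC area units per nmol injected, per compound (instrument response)
RESPONSE_FACTORS = {"linamarin": 8.0e4, "lotaustralin": 1.1e5, "amygdalin": 9.0e4}

#: chromatographic peak sd (min)
PEAK_SIGMA_MIN = 0.045

#: flat background level (counts)
BASELINE_LEVEL = 30.0


def make_chromatogram(
    amounts_nmol: dict[str, float],
    is_amount_nmol: float = IS_AMOUNT_NMOL,
    drift: float = 1.0,
    noise_sd: float = 0.0,
    rel_noise: float = 0.0,
    seed: int | np.random.Generator = 0,
    specimen_id: str = "",
    dt_min: float = 0.005,
) -> Chromatogram:
    """Simulate EIC traces with Gaussian peaks at the catalogued RTs.

    Peak area = amount x response factor x ``drift`` (whole-run sensitivity
    drift, cancelled downstream by the internal standard) x a per-compound
    lognormal factor of relative sd ``rel_noise``. ``noise_sd`` is additive
    baseline noise in counts. The amygdalin internal standard is always
    spiked at ``is_amount_nmol``.
    """
    for c, a in amounts_nmol.items():
        if a < 0:
            raise ValueError(f"negative amount for {c}")
    if drift <= 0:
        raise ValueError("drift must be positive")
    rng = _rng(seed)
    t = np.arange(0.0, 17.0 + dt_min / 2, dt_min)
    all_amounts = dict(amounts_nmol)
    all_amounts["amygdalin"] = is_amount_nmol
    traces = {}
    for compound, (mz, rt) in COMPOUNDS.items():
        amount = all_amounts.get(compound, 0.0)
        area = amount * RESPONSE_FACTORS[compound] * drift
        if rel_noise > 0:
            area *= float(np.exp(rng.normal(0.0, rel_noise)))
        peak = area * np.exp(-0.5 * ((t - rt) / PEAK_SIGMA_MIN) ** 2) / (
            PEAK_SIGMA_MIN * np.sqrt(2.0 * np.pi)
        )
        y = BASELINE_LEVEL + peak
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=t.shape)
        traces[mz] = np.clip(y, 0.0, None)
    return Chromatogram(t, traces, specimen_id, is_amount_nmol)


def make_calibration_standards(
    amounts_nmol: np.ndarray,
    is_amount_nmol: float = IS_AMOUNT_NMOL,
    noise_sd: float = 0.0,
    rel_noise: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[Chromatogram]:
    """Standards series: both analytes spiked at each amount, IS constant."""
    rng = _rng(seed)
    return [
        make_chromatogram(
            {"linamarin": float(a), "lotaustralin": float(a)},
            is_amount_nmol=is_amount_nmol,
            noise_sd=noise_sd,
            rel_noise=rel_noise,
            seed=rng,
            specimen_id=f"std_{i}",
        )
        for i, a in enumerate(np.asarray(amounts_nmol, float))
    ]
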