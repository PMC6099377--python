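"""Spectral primitives: wavelength grids, spectra, illuminants, receptors, cameras.

Everything downstream works on a shared 1-nm grid spanning 300-700 nm, the
range passed by the quartz optics and the UV/IR filter pair used in
UV-sensitive wing photography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WL_MIN = 300.0
WL_MAX = 700.0

#: default 1-nm working grid, 300-700 nm inclusive
GRID = np.arange(WL_MIN, WL_MAX + 1.0, 1.0)


@dataclass(frozen=True)
class Spectrum:
    """A reflectance or relative-irradiance spectrum on an ascending nm grid.

    Reflectance is dimensionless (typically <= 1; values up to 1.5 are
    tolerated to allow specular glint). Irradiance is in relative units.
    """

    wavelength_nm: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        val = np.asarray(self.value, dtype=float)
        if wl.ndim != 1 or wl.shape != val.shape:
            raise ValueError("wavelength and value must be 1-D arrays of equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if np.any(val < 0):
            raise ValueError("spectrum values must be non-negative")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "value", val)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return np.array_equal(self.wavelength_nm, other.wavelength_nm) and np.array_equal(
            self.value, other.value
        )


def same_grid(*spectra: Spectrum) -> np.ndarray:
    """Return the shared grid, raising if any spectrum disagrees."""
    wl = spectra[0].wavelength_nm
    for s in spectra[1:]:
        if s.wavelength_nm.shape != wl.shape or not np.array_equal(s.wavelength_nm, wl):
            raise ValueError("spectra are not defined on the same wavelength grid")
    return wl


def flat(level: float, wavelength_nm: np.ndarray = GRID) -> Spectrum:
    """Spectrally flat reflectance (e.g. the 7% and 93% grey standards)."""
    return Spectrum(wavelength_nm, np.full_like(np.asarray(wavelength_nm, float), level))


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def illuminant_d65like(wavelength_nm: np.ndarray = GRID) -> Spectrum:
    """Smooth analytic daylight-like illuminant on 300-700 nm.

    Rises steeply through the near-UV and is broad and gently curved across
    the visible, approximating the relative shape of D65 daylight. Only the
    relative shape matters: quantum catches are von Kries normalised and the
    camera calibration is anchored to in-frame grey standards.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    rise = 0.25 + 0.75 * _logistic((wl - 345.0) / 22.0)
    hump = 1.0 - 0.18 * ((wl - 490.0) / 210.0) ** 2
    return Spectrum(wl, rise * hump)


def lognormal_sensitivity(
    peak_nm: float, width: float = 0.055, wavelength_nm: np.ndarray = GRID
) -> Spectrum:
    """Log-normal-shaped receptor sensitivity template, peak-normalised to 1.

    Visual-pigment absorbance curves are well approximated by log-normal
    functions of wavelength; ``width`` is the log-domain standard deviation.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    s = np.exp(-0.5 * (np.log(wl / peak_nm) / width) ** 2)
    return Spectrum(wl, s)


@dataclass(frozen=True)
class VisualSystem:
    """An avian tetrachromat: four single cones, a double cone, noise model.

    ``abundances`` are relative cone abundances (UV/V, SW, MW, LW) and
    ``weber_omega`` is the Weber fraction attached to the most abundant cone.
    """

    name: str
    receptor_sensitivities: tuple[Spectrum, Spectrum, Spectrum, Spectrum]
    double_cone: Spectrum
    abundances: np.ndarray
    weber_omega: float = 0.05

    def __post_init__(self) -> None:
        eta = np.asarray(self.abundances, dtype=float)
        if eta.shape != (4,) or np.any(eta <= 0):
            raise ValueError("abundances must be 4 positive values")
        if not 0 < self.weber_omega < 1:
            raise ValueError("weber_omega must lie in (0, 1)")
        object.__setattr__(self, "abundances", eta)

    receptor_names: tuple[str, ...] = field(
        default=("uv", "sw", "mw", "lw"), init=False, repr=False
    )


# Peak wavelengths for the two avian colour-vision classes. The UVS class
# (blue tit-like) has its shortest cone in the ultraviolet; the VS class
# (peafowl-like) in the violet. The double cone is broad, peaking near 560 nm.
_UVS_PEAKS = (371.0, 445.0, 508.0, 565.0)
_VS_PEAKS = (420.0, 455.0, 505.0, 567.0)
_DOUBLE_PEAK = 560.0

# Relative cone abundances for each class (UV/V, SW, MW, LW).
UVS_ABUNDANCES = (1.0, 1.92, 2.68, 2.7)
VS_ABUNDANCES = (1.0, 1.9, 2.2, 2.1)


def make_visual_system(name: str, wavelength_nm: np.ndarray = GRID) -> VisualSystem:
    """Build the UVS or VS tetrachromat on the working grid."""
    key = name.upper()
    if key == "UVS":
        peaks, eta = _UVS_PEAKS, UVS_ABUNDANCES
    elif key == "VS":
        peaks, eta = _VS_PEAKS, VS_ABUNDANCES
    else:
        raise ValueError(f"unknown visual system {name!r}: expected 'UVS' or 'VS'")
    singles = tuple(lognormal_sensitivity(p, wavelength_nm=wavelength_nm) for p in peaks)
    double = lognormal_sensitivity(_DOUBLE_PEAK, width=0.12, wavelength_nm=wavelength_nm)
    return VisualSystem(key, singles, double, np.asarray(eta, float))


@dataclass(frozen=True)
class CameraSystem:
    """A UV-capable four-channel camera with a power-law response.

    Channels are visible LW/MW/SW (behind a UV/IR blocking filter passing
    300-700 nm) plus a UV channel (behind a UV-pass filter, 300-400 nm).
    ``response_exponent`` is the single power-law nonlinearity applied to
    the linear sensor response. The two in-frame grey standards reflect 7%
    and 93% across the whole range.
    """

    channel_sensitivities: tuple[Spectrum, Spectrum, Spectrum, Spectrum]
    response_exponent: float = 0.45
    standard_reflectances: tuple[float, float] = (0.07, 0.93)

    channel_names: tuple[str, ...] = field(
        default=("vis_lw", "vis_mw", "vis_sw", "uv"), init=False, repr=False
    )

    def __post_init__(self) -> None:
        if self.response_exponent <= 0:
            raise ValueError("response_exponent must be positive")
        uv = self.channel_sensitivities[3]
        above = uv.wavelength_nm > 400.0
        if np.any(above) and uv.value[above].max() > 1e-3 * uv.value.max():
            raise ValueError("UV channel must be blocked above 400 nm")


def _gaussian(wl: np.ndarray, peak: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - peak) / sigma) ** 2)


def make_camera(
    response_exponent: float = 0.45, wavelength_nm: np.ndarray = GRID
) -> CameraSystem:
    """Default camera: three visible Gaussian channels plus a UV channel.

    The visible channels are cut off below ~405 nm (UV/IR block filter) and
    the UV channel above ~395 nm (UV-pass filter), mirroring the two-exposure
    protocol that yields four image layers.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    vis_block = _logistic((wl - 405.0) / 4.0)
    uv_pass = _logistic((393.0 - wl) / 3.0) * (wl <= 400.0)
    chans = (
        Spectrum(wl, _gaussian(wl, 600.0, 52.0) * vis_block),
        Spectrum(wl, _gaussian(wl, 540.0, 45.0) * vis_block),
        Spectrum(wl, _gaussian(wl, 468.0, 38.0) * vis_block),
        Spectrum(wl, _gaussian(wl, 352.0, 26.0) * uv_pass),
    )
    return CameraSystem(chans, response_exponent)
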