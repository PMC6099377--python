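"""Quantum catches from spectra and polynomial camera-to-cone-catch mapping.

Receptor quantum catches are illuminant-weighted reflectance integrals with
von Kries normalization to a perfect white. Calibrated camera channel values
are mapped to predicted cone catches by a low-order polynomial regression
trained on a spectral library — the standard route for turning calibrated
multispectral photographs into "predator vision" images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import PolynomialFeatures

from .spectra import CameraSystem, Spectrum, VisualSystem, same_grid

logger = logging.getLogger(__name__)

CATCH_FLOOR = 1e-6


@dataclass(frozen=True)
class ConeCatch:
    """Von Kries-normalised quantum catches: 4 single cones + double cone."""

    q: np.ndarray
    double: float
    normalization: str = "von_kries_white"

    def __post_init__(self) -> None:
        q = np.asarray(self.q, float)
        if q.shape != (4,) or np.any(~np.isfinite(q)) or np.any(q < 0):
            raise ValueError("q must be 4 finite non-negative catches")
        if not np.isfinite(self.double) or self.double < 0:
            raise ValueError("double-cone catch must be finite and non-negative")
        object.__setattr__(self, "q", q)
        if np.any(q == 0):
            logger.warning("zero single-cone catch: log-ratio contrasts will fail")


def cone_catch_from_spectrum(
    refl: Spectrum, illum: Spectrum, system: VisualSystem
) -> ConeCatch:
    """q_i = integral(refl * illum * S_i) / integral(illum * S_i).

    The denominator is the catch of a perfect white, so a flat reflectance r
    gives q_i = r for every receptor and q is invariant to rescaling the
    illuminant.
    """
    wl = same_grid(refl, illum, *system.receptor_sensitivities, system.double_cone)

    def catch(sens: Spectrum) -> float:
        w = illum.value * sens.value
        denom = np.trapezoid(w, wl)
        if denom <= 0:
            raise ValueError("all-zero receptor sensitivity")
        return float(np.trapezoid(refl.value * w, wl) / denom)

    q = np.array([catch(s) for s in system.receptor_sensitivities])
    return ConeCatch(q, catch(system.double_cone))


@dataclass
class CatchMapping:
    """Per-receptor polynomial map from 4 camera channels to cone catches.

    Rows of ``coefficients`` correspond to (uv, sw, mw, lw, double); columns
    to the polynomial terms of the 4 normalized channel values.
    ``r_squared`` holds the held-out goodness of fit per receptor.
    """

    degree: int
    coefficients: np.ndarray
    r_squared: np.ndarray
    receptor_names: tuple[str, ...] = ("uv", "sw", "mw", "lw", "double")
    _poly: PolynomialFeatures = field(repr=False, default=None)

    def design(self, channels: np.ndarray) -> np.ndarray:
        return self._poly.transform(np.atleast_2d(channels))


def fit_catch_mapping(
    training_spectra: list[Spectrum],
    camera: CameraSystem,
    illum: Spectrum,
    system: VisualSystem,
    degree: int = 2,
) -> CatchMapping:
    """Fit the polynomial channel->catch regression on a spectral library.

    Channels are the noise-free calibrated (reflectance-scale) responses;
    targets are quadrature quantum catches. A fixed 80/20 split (every 5th
    spectrum held out) provides per-receptor held-out R². Requires at least
    5x more spectra than polynomial terms.
    """
    from .synthetic import true_channel_reflectance  # avoids a module cycle

    if degree < 1:
        raise ValueError("degree must be >= 1")
    poly = PolynomialFeatures(degree=degree, include_bias=True)
    n = len(training_spectra)
    n_terms = poly.fit(np.zeros((1, 4))).n_output_features_
    if n < 5 * n_terms:
        raise ValueError(
            f"need >= {5 * n_terms} training spectra for {n_terms} polynomial "
            f"terms at degree {degree}; got {n}"
        )
    X = np.vstack([true_channel_reflectance(s, camera, illum) for s in training_spectra])
    Y = np.vstack(
        [
            np.append(c.q, c.double)
            for c in (cone_catch_from_spectrum(s, illum, system) for s in training_spectra)
        ]
    )
    test = np.zeros(n, dtype=bool)
    test[4::5] = True  # fixed 80/20 split
    D = poly.transform(X)
    if np.linalg.matrix_rank(D[~test]) < n_terms:
        raise ValueError(
            f"rank-deficient design: {n_terms} polynomial terms from {n} spectra"
        )
    # weighted least squares with 1/catch weights: catches span two orders of
    # magnitude (near-black UV vs bright LW), so minimising relative rather
    # than absolute residuals keeps dark patches accurate too
    coef = np.empty((n_terms, Y.shape[1]))
    for j in range(Y.shape[1]):
        w = 1.0 / np.maximum(Y[~test][:, j], 1e-4)
        coef[:, j], _, _, _ = np.linalg.lstsq(
            D[~test] * w[:, None], Y[~test][:, j] * w, rcond=None
        )
    pred = D[test] @ coef
    resid = Y[test] - pred
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum((Y[test] - Y[test].mean(axis=0)) ** 2, axis=0)
    r2 = 1.0 - ss_res / ss_tot
    return CatchMapping(degree, coef.T, r2, _poly=poly)


def apply_catch_mapping(mapping: CatchMapping, normalized_channels: np.ndarray) -> ConeCatch:
    """Predict cone catches for one patch's normalized channel values.

    Negative polynomial extrapolations are clipped to a small positive floor
    so that downstream log-ratio contrasts stay defined.
    """
    if mapping._poly is None:
        raise ValueError("mapping has not been fitted")
    ch = np.asarray(normalized_channels, float)
    if not np.all(np.isfinite(ch)):
        raise ValueError("channel values must be finite")
    pred = (mapping.design(ch) @ mapping.coefficients.T)[0]
    if np.any(pred < CATCH_FLOOR):
        logger.warning("clipping %d predicted catch(es) to the %g floor",
                       int(np.sum(pred < CATCH_FLOOR)), CATCH_FLOOR)
        pred = np.clip(pred, CATCH_FLOOR, None)
    return ConeCatch(pred[:4], float(pred[4]))
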