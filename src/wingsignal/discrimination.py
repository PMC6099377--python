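"""Receptor-noise-limited discrimination: chromatic and luminance JNDs.

Chromatic contrast follows the log form of the receptor-noise-limited
colour discrimination model for a tetrachromat: differences of log quantum
catches are combined with per-receptor noise set by relative cone abundance
and the Weber fraction of the most abundant cone. Luminance contrast is the
absolute log ratio of double-cone catches over the same Weber fraction.
Values are in just-noticeable differences (JND); below 1 JND two colours
should be indiscriminable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectra import VisualSystem

CATCH_FLOOR = 1e-6


def receptor_noise(system: VisualSystem) -> np.ndarray:
    """Per-receptor noise e_i = omega * sqrt(eta_max / eta_i).

    The most abundant cone class carries exactly the Weber fraction; rarer
    classes are noisier in inverse square-root proportion to abundance.
    """
    eta = np.asarray(system.abundances, float)
    if np.any(eta <= 0):
        raise ValueError("cone abundances must be positive")
    return system.weber_omega * np.sqrt(eta.max() / eta)


def _log_ratios(catch_a: np.ndarray, catch_b: np.ndarray) -> np.ndarray:
    a = np.asarray(catch_a, float)
    b = np.asarray(catch_b, float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError(
            "zero or negative quantum catch: apply the catch floor "
            f"({CATCH_FLOOR}) before computing log-ratio contrasts"
        )
    return np.log(a / b)


def chromatic_jnd(catch_a: np.ndarray, catch_b: np.ndarray, system: VisualSystem) -> float:
    """Tetrachromatic noise-limited colour distance of two catch vectors.

    With df_i = ln(q_i^A / q_i^B) and noise e_i, the squared distance is the
    ratio of the pairwise sum over receptor pairs (j<k) of
    (prod of the other two e)^2 (df_j - df_k)^2 to the sum over receptor
    triples of their squared noise product. Symmetric in A/B and zero iff
    all df_i are equal (a purely achromatic shift).
    """
    e = receptor_noise(system)
    df = _log_ratios(catch_a, catch_b)
    e1, e2, e3, e4 = e
    f1, f2, f3, f4 = df
    num = (
        (e1 * e2) ** 2 * (f4 - f3) ** 2
        + (e1 * e3) ** 2 * (f4 - f2) ** 2
        + (e1 * e4) ** 2 * (f3 - f2) ** 2
        + (e2 * e3) ** 2 * (f4 - f1) ** 2
        + (e2 * e4) ** 2 * (f3 - f1) ** 2
        + (e3 * e4) ** 2 * (f2 - f1) ** 2
    )
    den = (
        (e1 * e2 * e3) ** 2
        + (e1 * e2 * e4) ** 2
        + (e1 * e3 * e4) ** 2
        + (e2 * e3 * e4) ** 2
    )
    return float(np.sqrt(num / den))


def dichromat_jnd(
    catch_a: np.ndarray, catch_b: np.ndarray, noise: np.ndarray
) -> float:
    """Two-receptor closed form: |df_1 - df_2| / sqrt(e_1^2 + e_2^2).

    Limiting case of the tetrachromat formula when two receptors carry
    negligible noise weight; kept as an independent cross-check.
    """
    df = _log_ratios(catch_a, catch_b)
    e = np.asarray(noise, float)
    if df.shape != (2,) or e.shape != (2,):
        raise ValueError("dichromat form needs 2 catches and 2 noise values")
    return float(abs(df[0] - df[1]) / np.sqrt(e[0] ** 2 + e[1] ** 2))


def luminance_jnd(double_a: float, double_b: float, omega: float) -> float:
    """Achromatic contrast: |ln(double_A / double_B)| / omega."""
    if double_a <= 0 or double_b <= 0:
        raise ValueError("double-cone catches must be positive")
    if omega <= 0:
        raise ValueError("omega must be positive")
    return float(abs(np.log(double_a / double_b)) / omega)


def background_conspicuousness(
    specimen_catches: pd.DataFrame,
    plant_catches: pd.DataFrame,
    system: VisualSystem,
) -> pd.DataFrame:
    """JNDs of each specimen's marking against averaged plant backgrounds.

    ``specimen_catches`` has one row per specimen with columns q_uv, q_sw,
    q_mw, q_lw, q_double (the marking); ``plant_catches`` the same catch
    columns plus ``plant_type``, several samples per type. Plant catches are
    averaged per type first, then chromatic and luminance JNDs are computed
    marking-vs-average; one output row per specimen x plant type.
    """
    qcols = ["q_uv", "q_sw", "q_mw", "q_lw", "q_double"]
    if plant_catches.empty:
        raise ValueError("no plant patches supplied")
    plant_means = plant_catches.groupby("plant_type")[qcols].mean()
    rows = []
    for _, spec in specimen_catches.iterrows():
        qa = spec[qcols[:4]].to_numpy(dtype=float)
        for ptype, mean in plant_means.iterrows():
            qb = mean[qcols[:4]].to_numpy(dtype=float)
            rows.append(
                {
                    "specimen_id": spec["specimen_id"],
                    "plant_type": ptype,
                    "system": system.name,
                    "chromatic_jnd": chromatic_jnd(qa, qb, system),
                    "luminance_jnd": luminance_jnd(
                        float(spec["q_double"]), float(mean["q_double"]), system.weber_omega
                    ),
                }
            )
    return pd.DataFrame(rows)
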