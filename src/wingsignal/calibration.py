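"""Camera calibration: linearization and grey-standard normalization.

Raw camera responses follow a power-law nonlinearity; the two in-frame grey
standards (7% and 93% reflectance) let us both estimate that exponent and
remove frame-to-frame lighting variation, yielding channel values on a
reflectance scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STANDARD_REFLECTANCES = (0.07, 0.93)


def linearize(values: np.ndarray, exponent: float) -> np.ndarray:
    """Invert the camera's power law: value -> value**(1/exponent)."""
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("raw values must be non-negative")
    return v ** (1.0 / exponent)


def estimate_exponent(
    std7: float, std93: float, reference_pair: tuple[float, float] = STANDARD_REFLECTANCES
) -> float:
    """Exponent g solving (std93/std7)**(1/g) = r93/r7.

    With a pure power-law response the two grey standards determine the
    nonlinearity: their raw ratio is the reflectance ratio raised to g.
    """
    if not 0 < std7 < std93:
        raise ValueError("impossible standards: need 0 < std7 < std93")
    r7, r93 = reference_pair
    return float(np.log(std93 / std7) / np.log(r93 / r7))


def normalize(
    linear_patch: np.ndarray, linear_std7: np.ndarray, linear_std93: np.ndarray
) -> np.ndarray:
    """Per-channel affine map sending the standards to (0.07, 0.93).

    Exact on the standards; values outside [0.07, 0.93] are legitimate for
    out-of-range patches, but negatives are clipped to 0 (with a logged
    warning) because downstream log-ratio contrasts need positive catches.
    """
    p = np.asarray(linear_patch, float)
    s7 = np.asarray(linear_std7, float)
    s93 = np.asarray(linear_std93, float)
    if np.any(s93 <= s7):
        raise ValueError("equal or inverted standards in some channel")
    r7, r93 = STANDARD_REFLECTANCES
    out = r7 + (p - s7) * (r93 - r7) / (s93 - s7)
    if np.any(out < 0):
        logger.warning("clipping %d negative normalized channel value(s) to 0",
                       int(np.sum(out < 0)))
        out = np.clip(out, 0.0, None)
    return out


def calibrate_patch_table(
    patches: pd.DataFrame,
    channel_names: tuple[str, ...] = ("vis_lw", "vis_mw", "vis_sw", "uv"),
    exponent: float | str = "auto",
) -> pd.DataFrame:
    """Calibrate a raw patch table to reflectance-scale channel values.

    Expects per-row channel columns plus ``std7_<ch>``/``std93_<ch>`` for the
    in-frame standards. ``exponent='auto'`` estimates the power law per row
    as the mean of the per-channel two-standard estimates; a float applies a
    known exponent. Returns the table with channel columns replaced by
    normalized values (standards columns dropped).
    """
    out_rows = []
    for _, row in patches.iterrows():
        raw = row[list(channel_names)].to_numpy(dtype=float)
        s7 = row[[f"std7_{c}" for c in channel_names]].to_numpy(dtype=float)
        s93 = row[[f"std93_{c}" for c in channel_names]].to_numpy(dtype=float)
        if exponent == "auto":
            g = float(np.mean([estimate_exponent(a, b) for a, b in zip(s7, s93)]))
        else:
            g = float(exponent)
        norm = normalize(linearize(raw, g), linearize(s7, g), linearize(s93, g))
        out = {k: row[k] for k in patches.columns
               if not (k in channel_names or k.startswith("std"))}
        out.update(dict(zip(channel_names, norm)))
        out["exponent_used"] = g
        out_rows.append(out)
    return pd.DataFrame(out_rows)
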