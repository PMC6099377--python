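"""LC-MS quantification of cyanogenic glucosides from extracted ion chromatograms.

Linamarin and lotaustralin are quantified from EIC peak areas, normalised to
an amygdalin internal standard spiked at extraction, and converted to amounts
via linear calibration curves; per-specimen concentration is total amount per
mg fresh mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: sodium-adduct m/z channel and retention time (min) per compound
COMPOUNDS: dict[str, tuple[int, float]] = {
    "linamarin": (270, 2.6),
    "lotaustralin": (284, 5.5),
    "amygdalin": (480, 6.6),
}

#: default EIC integration window (min), peaks at 2.6/5.5/6.6 are well separated
DEFAULT_WINDOW_MIN = 0.6

#: internal-standard amount per extraction: 0.044 mM amygdalin in 1 ml = 44 nmol
IS_AMOUNT_NMOL = 44.0


@dataclass
class Chromatogram:
    """Time x m/z-channel intensity traces on a 0-17 min gradient run."""

    time_min: np.ndarray
    traces: dict[int, np.ndarray]
    specimen_id: str = ""
    is_amount_nmol: float = IS_AMOUNT_NMOL

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly ascending")
        self.time_min = t
        for mz, y in self.traces.items():
            y = np.asarray(y, dtype=float)
            if y.shape != t.shape:
                raise ValueError(f"trace m/z {mz} does not match the time grid")
            if np.any(y < 0):
                raise ValueError(f"trace m/z {mz} has negative intensities")
            self.traces[mz] = y

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (time_min, mz_channel, intensity)."""
        rows = [
            pd.DataFrame(
                {"time_min": self.time_min, "mz_channel": mz, "intensity": y}
            )
            for mz, y in sorted(self.traces.items())
        ]
        return pd.concat(rows, ignore_index=True)


def chromatogram_from_frame(
    df: pd.DataFrame, specimen_id: str = "", is_amount_nmol: float = IS_AMOUNT_NMOL
) -> Chromatogram:
    """Rebuild a :class:`Chromatogram` from its long-form table."""
    traces = {}
    t = None
    for mz, sub in df.groupby("mz_channel"):
        sub = sub.sort_values("time_min")
        if t is None:
            t = sub["time_min"].to_numpy()
        traces[int(mz)] = sub["intensity"].to_numpy()
    return Chromatogram(t, traces, specimen_id, is_amount_nmol)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration: IS-normalised area ratio per nmol of analyte."""

    compound: str
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


@dataclass(frozen=True)
class ToxinResult:
    """Per-specimen cyanogenic glucoside amounts and concentration."""

    specimen_id: str
    linamarin_nmol: float
    lotaustralin_nmol: float
    mass_mg: float
    total_nmol: float = field(init=False)
    concentration_nmol_per_mg: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.linamarin_nmol + self.lotaustralin_nmol
        object.__setattr__(self, "total_nmol", total)
        object.__setattr__(self, "concentration_nmol_per_mg", total / self.mass_mg)


def extract_eic(
    chrom: Chromatogram, mz: int, rt_center_min: float, window_min: float
) -> tuple[np.ndarray, np.ndarray]:
    """Slice one m/z trace to [rt - window/2, rt + window/2].

    Returns (time, intensity) arrays for the window.
    """
    if mz not in chrom.traces:
        raise KeyError(f"m/z channel {mz} not present; have {sorted(chrom.traces)}")
    lo, hi = rt_center_min - window_min / 2.0, rt_center_min + window_min / 2.0
    mask = (chrom.time_min >= lo) & (chrom.time_min <= hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] min lies outside the time grid")
    return chrom.time_min[mask], chrom.traces[mz][mask]


def integrate_peak(time_min: np.ndarray, intensity: np.ndarray) -> float:
    """Trapezoidal peak area above a linear baseline through the endpoints.

    The baseline models a locally linear background; the area is floored at 0
    so pure-noise windows do not return negative amounts.
    """
    t = np.asarray(time_min, float)
    y = np.asarray(intensity, float)
    if t.size < 3:
        raise ValueError("need at least 3 samples to integrate a peak")
    baseline = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
    return float(max(np.trapezoid(y - baseline, t), 0.0))


def peak_area(
    chrom: Chromatogram, compound: str, window_min: float = DEFAULT_WINDOW_MIN
) -> float:
    """EIC peak area for a named compound at its catalogued m/z and RT."""
    mz, rt = COMPOUNDS[compound]
    return integrate_peak(*extract_eic(chrom, mz, rt, window_min))


def fit_calibration(
    standard_amounts_nmol: np.ndarray, area_ratios: np.ndarray, compound: str = ""
) -> CalibrationCurve:
    """OLS line of IS-normalised area ratio on standard amount."""
    x = np.asarray(standard_amounts_nmol, float)
    y = np.asarray(area_ratios, float)
    if x.size < 3:
        raise ValueError("need at least 3 calibration standards")
    if np.ptp(x) == 0:
        raise ValueError("calibration standards must span a positive amount range")
    res = sps.linregress(x, y)
    return CalibrationCurve(compound, float(res.slope), float(res.intercept), float(res.rvalue**2))


def quantify_specimen(
    chrom: Chromatogram,
    curves: dict[str, CalibrationCurve],
    mass_mg: float,
    window_min: float = DEFAULT_WINDOW_MIN,
) -> ToxinResult:
    """Amounts from IS-normalised EIC areas via calibration; concentration per mg.

    Raises if the internal-standard peak is absent (failed injection).
    """
    if mass_mg <= 0:
        raise ValueError("mass must be positive")
    is_area = peak_area(chrom, "amygdalin", window_min)
    if is_area <= 0:
        raise ValueError("internal-standard peak area is zero: failed injection")
    amounts = {}
    for compound in ("linamarin", "lotaustralin"):
        ratio = peak_area(chrom, compound, window_min) / is_area
        curve = curves[compound]
        amounts[compound] = max((ratio - curve.intercept) / curve.slope, 0.0)
    return ToxinResult(
        chrom.specimen_id, amounts["linamarin"], amounts["lotaustralin"], mass_mg
    )
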