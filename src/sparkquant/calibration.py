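"""Fluorophore concentration calibration.

Two steps link image grey values to protein concentration: Beer-Lambert
quantification of the purified fluorophore stock, and an ordinary
least-squares standard curve fitted to a dilution series imaged under the
acquisition settings used for the cells. Per-cell mean intensities are then
inverted through the curve to nanomolar concentrations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StockConcentration:
    """Beer-Lambert stock quantification result (concentration in µM)."""

    absorbance: float
    extinction_coefficient_per_M_cm: float
    path_length_cm: float
    concentration_uM: float


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear intensity-vs-concentration standard curve.

    slope: counts/pixel per nM; intercept: counts/pixel (camera offset plus
    autofluorescence — fitted, not forced through the origin).
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            return cls(**json.load(fh))


def stock_concentration(
    absorbance: float, extinction_coefficient_per_M_cm: float, path_length_cm: float = 1.0
) -> StockConcentration:
    """Stock concentration from absorbance via Beer-Lambert.

    c = A / (epsilon * L); result reported in µM.
    """
    if absorbance <= 0:
        raise ValueError("absorbance must be positive (no signal)")
    if extinction_coefficient_per_M_cm <= 0 or path_length_cm <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    conc_M = absorbance / (extinction_coefficient_per_M_cm * path_length_cm)
    return StockConcentration(absorbance, extinction_coefficient_per_M_cm,
                              path_length_cm, conc_M * 1e6)


def fit_standard_curve(dilution_table: pd.DataFrame) -> CalibrationCurve:
    """OLS line through the dilution series (concentration_nM, mean_intensity).

    Requires at least two distinct concentrations; returns slope, intercept
    and r^2 as residual diagnostics.
    """
    tbl = pd.DataFrame(dilution_table)
    conc = np.asarray(tbl["concentration_nM"], float)
    inten = np.asarray(tbl["mean_intensity"], float)
    if conc.size < 2:
        raise ValueError("need at least 2 calibration points")
    if np.unique(conc).size < 2:
        raise ValueError("all concentrations identical: calibration is rank-deficient")
    res = stats.linregress(conc, inten)
    r2 = float(res.rvalue**2) if np.std(inten) > 0 else 1.0
    return CalibrationCurve(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=r2, n_points=int(conc.size))


def estimate_cell_concentration(mean_intensity, curve: CalibrationCurve):
    """Invert the standard curve: concentration = (I - intercept) / slope.

    Negative estimates (dim cells pushed below the intercept by read noise)
    are clipped to 0 nM with a warning. Accepts scalars or arrays.
    """
    mean_intensity = np.asarray(mean_intensity, float)
    if np.any(mean_intensity < 0):
        raise ValueError("mean intensity must be >= 0")
    conc = (mean_intensity - curve.intercept) / curve.slope
    if np.any(conc < 0):
        warnings.warn("intensity below calibration intercept; concentration clipped to 0 nM")
        conc = np.clip(conc, 0.0, None)
    return float(conc) if conc.ndim == 0 else conc
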