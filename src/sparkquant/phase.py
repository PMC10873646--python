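"""Phase-separation curve assembly and saturation-concentration estimation.

Across a population of cells the SPARK signal is ~0 below the saturation
concentration c_sat and rises continuously above it. c_sat is estimated by
a hinge changepoint fit: for each candidate breakpoint c the model

    spark(C) = 0                       for C <  c
    spark(C) = a1*x + a2*x^2,  x = 1 - c/C,   for C >= c

is fitted by least squares (linear in a1, a2); the candidate minimising the
residual sum of squares is the estimate. The saturating x = 1 - c/C rise is
the lever-rule form for the protein fraction in the dense phase; the
quadratic term absorbs curvature from the density contrast. Confidence
intervals come from a percentile bootstrap over cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PhaseCurve:
    """Per-cell (concentration, SPARK) table for one condition."""

    table: pd.DataFrame  # columns cell_id, concentration_nM, spark_signal
    condition: str = ""

    def __post_init__(self) -> None:
        t = self.table
        if len(t) == 0:
            raise ValueError("phase curve is empty")
        if np.any(t["concentration_nM"] <= 0):
            raise ValueError("concentrations must be positive")
        s = np.asarray(t["spark_signal"], float)
        if np.any((s < 0) | (s > 1)):
            raise ValueError("spark signals must lie in [0, 1]")

    @property
    def degenerate(self) -> bool:
        """All cells identical — no curve to fit."""
        t = self.table
        return (t["concentration_nM"].nunique() == 1) or (t["spark_signal"].nunique() == 1)


@dataclass(frozen=True)
class CsatEstimate:
    csat_nM: float
    ci_low_nM: float
    ci_high_nM: float
    method: str = "hinge-changepoint"
    n_cells: int = 0


def build_phase_curve(measurements, condition: str = "") -> PhaseCurve:
    """Assemble the per-cell phase curve, sorted by concentration.

    ``measurements`` is a DataFrame (or records) with cell_id,
    concentration_nM and spark_signal columns, typically the output of
    ``detection.measure_cells`` joined with calibration.
    """
    tbl = pd.DataFrame(measurements)
    missing = {"cell_id", "concentration_nM", "spark_signal"} - set(tbl.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    tbl = tbl.sort_values("concentration_nM").reset_index(drop=True)
    return PhaseCurve(table=tbl[["cell_id", "concentration_nM", "spark_signal"]],
                      condition=condition)


def _hinge_fit(conc: np.ndarray, spark: np.ndarray, candidates: np.ndarray):
    """Best hinge breakpoint by grid search; returns (c_hat, sse_min).

    Per candidate c the model spark = b0 + a1*x + a2*x^2 (x = max(0, 1-c/C))
    is linear in its coefficients, so each fit is a tiny least-squares
    solve. The baseline b0 absorbs the measurement floor of sub-threshold
    cells (noise clipped at zero keeps their mean slightly positive).
    """
    best_c, best_sse = np.nan, np.inf
    for c in candidates:
        x = np.clip(1.0 - c / conc, 0.0, None)
        X = np.column_stack([np.ones_like(x), x, x**2])
        coef, _, rank, _ = np.linalg.lstsq(X, spark, rcond=None)
        pred = X @ coef
        sse = float(((spark - pred) ** 2).sum())
        if sse < best_sse - 1e-15:
            best_sse, best_c = sse, float(c)
    return best_c, best_sse


def _candidates(conc: np.ndarray) -> np.ndarray:
    uniq = np.unique(conc)
    if uniq.size > 1:
        uniq = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2])
    return np.sort(uniq)


def _csat_point(conc: np.ndarray, spark: np.ndarray, zero_level: float = 0.02):
    below = spark <= zero_level
    if below.all():
        raise ValueError("unidentifiable: no cells with SPARK signal above zero")
    if not below.any():
        raise ValueError("unidentifiable: no sub-threshold (SPARK ~ 0) cells")
    c_hat, _ = _hinge_fit(conc, spark, _candidates(conc))
    return c_hat


def estimate_csat(curve: PhaseCurve, n_bootstrap: int = 1000, seed: int = 0,
                  zero_level: float = 0.02) -> CsatEstimate:
    """Hinge-changepoint estimate of c_sat with a percentile bootstrap CI.

    Requires cells on both sides of the breakpoint (some with SPARK ~ 0 and
    some clearly above); otherwise the changepoint is unidentifiable.
    Bootstrap resamples cells, not pixels.
    """
    t = curve.table
    if len(t) < 10:
        raise ValueError("need >= 10 cells spanning the breakpoint")
    conc = np.asarray(t["concentration_nM"], float)
    spark = np.asarray(t["spark_signal"], float)
    c_hat = _csat_point(conc, spark, zero_level)  # raises if unidentifiable
    if curve.degenerate:
        raise ValueError("degenerate phase curve: all cells identical")

    rng = np.random.default_rng(seed)
    boots = []
    n = conc.size
    for _ in range(int(n_bootstrap)):
        idx = rng.integers(0, n, n)
        try:
            boots.append(_csat_point(conc[idx], spark[idx], zero_level))
        except ValueError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = c_hat
    # the estimator is grid-valued, so the CI cannot be narrower than the
    # local candidate spacing around the point estimate
    cand = _candidates(conc)
    i = int(np.searchsorted(cand, c_hat))
    gap_lo = (cand[i] - cand[i - 1]) / 2 if i > 0 else 0.0
    gap_hi = (cand[min(i + 1, cand.size - 1)] - cand[i]) / 2 if i < cand.size - 1 else 0.0
    lo = min(lo, c_hat - gap_lo)
    hi = max(hi, c_hat + gap_hi)
    return CsatEstimate(csat_nM=float(c_hat), ci_low_nM=float(lo), ci_high_nM=float(hi),
                        n_cells=n)


def compare_csat(curve_a: PhaseCurve, curve_b: PhaseCurve, n_bootstrap: int = 1000,
                 seed: int = 0) -> dict:
    """Shift in c_sat between two conditions with a paired bootstrap CI.

    Returns a dict with both point estimates, the shift (b - a) and its
    percentile CI; each bootstrap replicate resamples cells within each
    condition independently.
    """
    est_a = estimate_csat(curve_a, n_bootstrap=0)
    est_b = estimate_csat(curve_b, n_bootstrap=0)
    ca = np.asarray(curve_a.table["concentration_nM"], float)
    sa = np.asarray(curve_a.table["spark_signal"], float)
    cb = np.asarray(curve_b.table["concentration_nM"], float)
    sb = np.asarray(curve_b.table["spark_signal"], float)
    rng = np.random.default_rng(seed)
    shifts = []
    for _ in range(int(n_bootstrap)):
        ia = rng.integers(0, ca.size, ca.size)
        ib = rng.integers(0, cb.size, cb.size)
        try:
            shifts.append(_csat_point(cb[ib], sb[ib]) - _csat_point(ca[ia], sa[ia]))
        except ValueError:
            continue
    shift = est_b.csat_nM - est_a.csat_nM
    if shifts:
        lo, hi = np.percentile(shifts, [2.5, 97.5])
    else:
        lo = hi = shift
    return dict(csat_a_nM=est_a.csat_nM, csat_b_nM=est_b.csat_nM,
                shift_nM=float(shift), ci_low_nM=float(min(lo, shift)),
                ci_high_nM=float(max(hi, shift)))
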