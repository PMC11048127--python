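"""Linear calibration of the evaporation-endpoint assay.

The endpoint resonant frequency is an affine function of cell
concentration, y = slope * x + intercept, with y in GHz and x in cells/mL.
This module fits that line to a replicate measurement table by ordinary
least squares, converts the slope to a sensitivity in Hz per cells/mL, and
inverts observed frequencies back to concentration estimates with
first-order (delta-method) inverse-prediction intervals.

The sensor's reported calibration line is

    y = -0.02506e-6 * x - 1.65475            (GHz; x in cells/mL)

whose slope corresponds to a sensitivity of 25.06 Hz per cells/mL for a
1 uL droplet.  :func:`reference_curve` returns this line as a
:class:`CalibrationCurve`.  The curve is treated as an abstract affine map;
no sign convention for the "shift" is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "ConcentrationEstimate",
    "make_measurement_table",
    "fit_line",
    "sensitivity_hz",
    "predict_frequency",
    "invert_concentration",
    "reference_curve",
    "REFERENCE_SLOPE_GHZ",
    "REFERENCE_INTERCEPT_GHZ",
]

#: Reported calibration line of the sensor (GHz per cells/mL; GHz).
REFERENCE_SLOPE_GHZ = -0.02506e-6
REFERENCE_INTERCEPT_GHZ = -1.65475

#: Column names of a measurement table.
CONC_COL = "concentration_cells_per_mL"
FREQ_COL = "f_res_GHz"
REP_COL = "replicate"


def make_measurement_table(
    concentrations, f_res, replicates=None
) -> pd.DataFrame:
    """Assemble a measurement table DataFrame with the canonical columns
    (concentration_cells_per_mL, f_res_GHz, replicate)."""
    conc = np.asarray(concentrations, dtype=float)
    f = np.asarray(f_res, dtype=float)
    if conc.shape != f.shape:
        raise ValueError("concentrations and f_res must have equal length")
    if not np.all(np.isfinite(f)):
        raise ValueError("f_res must be finite")
    if replicates is None:
        replicates = np.zeros(conc.size, dtype=int)
    return pd.DataFrame(
        {CONC_COL: conc, FREQ_COL: f, REP_COL: np.asarray(replicates, dtype=int)}
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted (or reference) concentration -> frequency line.

    ``slope`` is in GHz per cells/mL, ``intercept`` in GHz.  ``x_mean`` and
    ``s_xx`` (the mean and centred sum of squares of the fitted
    concentrations) are carried for inverse-prediction intervals; they are
    NaN for a curve constructed from coefficients alone.
    """

    slope: float
    intercept: float
    r_squared: float = float("nan")
    n_points: int = 0
    residual_sd: float = float("nan")
    x_mean: float = float("nan")
    s_xx: float = float("nan")

    @property
    def sensitivity_hz(self) -> float:
        """|slope| converted from GHz to Hz per cells/mL."""
        return abs(self.slope) * 1e9

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sensitivity_hz"] = self.sensitivity_hz
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        keys = ("slope", "intercept", "r_squared", "n_points", "residual_sd",
                "x_mean", "s_xx")
        return cls(**{k: d[k] for k in keys if k in d})


@dataclass(frozen=True)
class ConcentrationEstimate:
    """An inverse-prediction result: point estimate and confidence interval
    in cells/mL.  ``clipped`` flags a negative raw estimate truncated at 0."""

    estimate: float
    ci_low: float
    ci_high: float
    confidence: float
    clipped: bool = False


def fit_line(
    table: pd.DataFrame, average_replicates: bool = False
) -> CalibrationCurve:
    """Ordinary-least-squares fit of endpoint frequency on concentration.

    Replicates enter the fit individually by default;
    ``average_replicates=True`` regresses per-concentration means instead.
    r^2 is the squared Pearson correlation of fitted vs observed values
    (identical to the coefficient of determination for a simple OLS line).

    Raises
    ------
    ValueError
        If fewer than two distinct concentration values are present.
    """
    if average_replicates:
        table = (
            table.groupby(CONC_COL, as_index=False)[FREQ_COL].mean()
        )
    x = table[CONC_COL].to_numpy(dtype=float)
    y = table[FREQ_COL].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError(
            "calibration requires >= 2 distinct concentrations (rank-deficient fit)"
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    fitted = model.fittedvalues
    if np.allclose(fitted, fitted[0]):
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    df_resid = int(model.df_resid)
    residual_sd = float(np.sqrt(model.ssr / df_resid)) if df_resid > 0 else 0.0
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_points=x.size,
        residual_sd=residual_sd,
        x_mean=float(x.mean()),
        s_xx=float(np.sum((x - x.mean()) ** 2)),
    )


def sensitivity_hz(curve: CalibrationCurve) -> float:
    """Assay sensitivity: |slope| in Hz per cells/mL."""
    return curve.sensitivity_hz


def predict_frequency(curve: CalibrationCurve, x: float) -> float:
    """Predicted endpoint frequency (GHz) at concentration ``x``."""
    if not np.isfinite(x) or x < 0:
        raise ValueError("concentration must be finite and >= 0")
    return curve.slope * x + curve.intercept


#: Slopes with |slope| below this (GHz per cells/mL) are non-invertible.
SLOPE_TOLERANCE = 1e-15


def invert_concentration(
    curve: CalibrationCurve, y_obs: float, confidence: float = 0.95
) -> ConcentrationEstimate:
    """Estimate concentration from an observed endpoint frequency (GHz).

    The point estimate is x_hat = (y_obs - intercept) / slope.  For a
    fitted curve the interval is the first-order inverse-prediction
    interval for a single new observation,

        x_hat +/- t_{n-2} * (s/|m|) * sqrt(1 + 1/n + (x_hat - x_bar)^2/Sxx)

    with s the residual SD, m the slope.  A curve built from coefficients
    alone (no fit statistics) returns a degenerate interval at the point
    estimate.  Negative estimates are clipped to 0 and flagged.
    """
    if abs(curve.slope) <= SLOPE_TOLERANCE:
        raise ZeroDivisionError(
            "calibration curve is non-invertible: |slope| below tolerance"
        )
    x_hat = (y_obs - curve.intercept) / curve.slope
    have_stats = (
        curve.n_points >= 3
        and np.isfinite(curve.residual_sd)
        and np.isfinite(curve.s_xx)
        and curve.s_xx > 0
    )
    if have_stats:
        t = stats.t.ppf(0.5 + confidence / 2.0, curve.n_points - 2)
        se = (
            curve.residual_sd
            / abs(curve.slope)
            * np.sqrt(
                1.0
                + 1.0 / curve.n_points
                + (x_hat - curve.x_mean) ** 2 / curve.s_xx
            )
        )
        lo, hi = x_hat - t * se, x_hat + t * se
    else:
        lo = hi = x_hat
    clipped = x_hat < 0
    return ConcentrationEstimate(
        estimate=max(x_hat, 0.0),
        ci_low=max(lo, 0.0),
        ci_high=max(hi, 0.0),
        confidence=confidence,
        clipped=bool(clipped),
    )


def reference_curve() -> CalibrationCurve:
    """The sensor's reported calibration line (slope -0.02506e-6 GHz per
    cells/mL, intercept -1.65475 GHz) as a coefficients-only curve."""
    return CalibrationCurve(
        slope=REFERENCE_SLOPE_GHZ, intercept=REFERENCE_INTERCEPT_GHZ
    )
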