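"""Device-to-reference calibration: linear fits, prediction intervals, and
mean-difference bias correction.

Two correction schemes are provided, matching how each device metric
relates to its clinical reference:

* :class:`LinearCalibrator` — ordinary least squares predicting the
  reference from the device reading (used for heart rate, where armband
  estimates are correlated with but not 1:1 to fingertip pulse oximetry),
  with R-squared and a 95% prediction interval for a single future
  observation:  y_hat +/- t_{n-1,0.025} * s * sqrt(1 + 1/n).
* :class:`BiasCorrector` — an additive shift equal to the mean
  reference-minus-device difference (used for SpO2 and skin temperature,
  which track the reference closely but sit at a constant offset).

Both are scikit-learn-style estimators (``fit`` / ``predict`` or
``transform``, fitted attributes with trailing underscores) so they compose
with sklearn pipelines; thin module-level functions mirror the estimator
surface for script use.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateDataError

__all__ = [
    "LinearCalibrator",
    "BiasCorrector",
    "fit_linear_calibration",
    "predict_with_interval",
    "estimate_bias",
    "apply_bias",
    "paired_difference_test",
]


def _as_1d(a, name: str) -> np.ndarray:
    out = np.asarray(a, dtype=float)
    if out.ndim == 2 and out.shape[1] == 1:
        out = out.ravel()
    if out.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional (or a single column)")
    return out


class LinearCalibrator(RegressorMixin, BaseEstimator):
    """OLS calibration of a device metric against a reference standard.

    Fits ``reference = slope * device + intercept`` (the device reading is
    the predictor, so a new device value maps directly to an adjusted
    estimate of the true quantity).

    Attributes
    ----------
    slope_, intercept_ : float
        OLS coefficients.
    r_squared_ : float
        Squared sample correlation of device and reference.
    s_ : float
        Sample standard deviation (ddof=1) of the reference series — the
        spread term used in the prediction interval (see Notes).
    s_resid_ : float
        Conventional residual standard error sqrt(SSE / (n - 2)), reported
        alongside for comparison.
    n_ : int
        Number of paired points.
    t_crit_ : float
        Two-sided 97.5% Student-t quantile at n - 1 degrees of freedom.

    Notes
    -----
    The 95% prediction half-width is ``t_{n-1,0.025} * s * sqrt(1 + 1/n)``,
    constant in x, with ``s`` the standard deviation of the original
    (reference) data set and n - 1 degrees of freedom.  This differs from
    the textbook regression prediction interval (residual standard error,
    n - 2 df, x-dependent leverage term); the conventional residual spread
    is exposed as ``s_resid_`` so both are auditable.
    """

    def __init__(self):
        pass

    def fit(self, X, y):
        device = _as_1d(X, "device")
        reference = _as_1d(y, "reference")
        if device.size != reference.size:
            raise ValueError("device and reference series must have equal length")
        n = device.size
        if n < 3:
            raise ValueError("calibration needs at least 3 paired points")
        if np.ptp(device) == 0:
            raise ValueError("device series is constant; slope undefined")
        fit = stats.linregress(device, reference)
        self.slope_ = float(fit.slope)
        self.intercept_ = float(fit.intercept)
        self.r_squared_ = float(fit.rvalue**2)
        self.s_ = float(np.std(reference, ddof=1))
        resid = reference - (self.slope_ * device + self.intercept_)
        self.s_resid_ = float(np.sqrt(np.sum(resid**2) / (n - 2)))
        self.n_ = n
        self.t_crit_ = float(stats.t.ppf(0.975, n - 1))
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = _as_1d(X, "X")
        return self.slope_ * x + self.intercept_

    def predict_interval(self, X):
        """Point estimate and 95% prediction half-width for new readings.

        Returns ``(estimate, half_width)``; the half-width
        ``t_crit * s * sqrt(1 + 1/n)`` is constant across x.
        """
        check_is_fitted(self, "slope_")
        estimate = self.predict(X)
        half_width = self.t_crit_ * self.s_ * np.sqrt(1.0 + 1.0 / self.n_)
        return estimate, float(half_width)

    def to_dict(self) -> dict:
        check_is_fitted(self, "slope_")
        return {
            "slope": self.slope_,
            "intercept": self.intercept_,
            "r_squared": self.r_squared_,
            "s": self.s_,
            "s_resid": self.s_resid_,
            "n": self.n_,
        }


class BiasCorrector(TransformerMixin, BaseEstimator):
    """Additive bias correction: shift device readings by the mean
    reference-minus-device difference.

    After ``fit(device, reference)``, ``transform(values)`` adds
    ``bias_ = mean(reference) - mean(device)`` to each value, so the mean
    of the corrected fitting series equals the reference mean exactly.
    """

    def __init__(self):
        pass

    def fit(self, X, y):
        device = _as_1d(X, "device")
        reference = _as_1d(y, "reference")
        if device.size != reference.size:
            raise ValueError("device and reference series must have equal length")
        if device.size < 1:
            raise ValueError("bias needs at least one paired point")
        self.bias_ = float(reference.mean() - device.mean())
        self.n_pairs_ = device.size
        return self

    def transform(self, X):
        check_is_fitted(self, "bias_")
        return np.asarray(X, dtype=float) + self.bias_


def fit_linear_calibration(device, reference) -> LinearCalibrator:
    """Fit an OLS device-to-reference calibration (thin wrapper)."""
    return LinearCalibrator().fit(device, reference)


def predict_with_interval(model: LinearCalibrator, x_star):
    """Eq.-style point estimate with constant 95% prediction half-width."""
    return model.predict_interval(np.atleast_1d(x_star))


def estimate_bias(device, reference) -> BiasCorrector:
    """Fit a mean-difference bias correction (thin wrapper)."""
    return BiasCorrector().fit(device, reference)


def apply_bias(values, corrector: BiasCorrector):
    """Add the fitted bias to each value (thin wrapper)."""
    return corrector.transform(values)


def paired_difference_test(device, reference, method: str = "wilcoxon") -> float:
    """Two-sided paired test of reference vs (corrected) device values.

    A thin wrapper over scipy's Wilcoxon signed-rank and paired t tests.
    Identical series are degenerate: the t-test returns p = 1.0 by
    convention; the Wilcoxon test raises :class:`DegenerateDataError`
    because its statistic is undefined with no nonzero differences.
    """
    d = _as_1d(device, "device")
    r = _as_1d(reference, "reference")
    if d.size != r.size:
        raise ValueError("device and reference series must have equal length")
    diffs = r - d
    if np.all(diffs == 0):
        if method == "t":
            return 1.0
        raise DegenerateDataError(
            "all paired differences are zero; Wilcoxon statistic undefined"
        )
    if method == "wilcoxon":
        if d.size < 5:
            raise ValueError("Wilcoxon test needs at least 5 pairs")
        return float(stats.wilcoxon(r, d).pvalue)
    if method == "t":
        return float(stats.ttest_rel(r, d).pvalue)
    raise ValueError(f"unknown method {method!r}; use 'wilcoxon' or 't'")
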