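"""Acoustic-field dosimetry: linear dose-responses, calorimetric energy
conversion, the cavitation index and the empirical mass-transfer model.

The sonicated tea suspension responds linearly to acoustic power density
P/V (W mL^-1) in temperature, KI-dosimetry iodine yield, hydroxyl-radical
concentration and (inversely) viscosity.  The normalized solute mass-transfer
coefficient follows the empirical surface

    k_m = k0 + alpha (P/V) + beta (P/V)^2 - gamma eta

where eta is the calorimetric energy-absorption coefficient.  The cavitation
index CI condenses the two chemical dosimeters (iodine yield and hydroxyl
radicals) into one standardized score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "LinearResponse",
    "MassTransferModel",
    "MassTransferRegressor",
    "PRINTED_MASS_TRANSFER",
    "EtaResult",
    "fit_linear_response",
    "energy_conversion_coefficient",
    "cavitation_index",
    "fit_mass_transfer_model",
    "eval_mass_transfer",
]


@dataclass
class LinearResponse:
    """Ordinary least-squares line of a dosimetry endpoint on power density."""

    slope: float  # units per W mL^-1
    intercept: float
    r_squared: float
    p_value: float

    def predict(self, power):
        return self.intercept + self.slope * np.asarray(power, dtype=float)


def fit_linear_response(power, values) -> LinearResponse:
    """OLS fit of a measured endpoint against acoustic power density."""
    x = np.asarray(power, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.unique(x).size < 2:
        raise ValueError("power values are constant; slope is undefined")
    fit = stats.linregress(x, y)
    return LinearResponse(fit.slope, fit.intercept, fit.rvalue ** 2, fit.pvalue)


@dataclass
class EtaResult:
    """Calorimetric energy-conversion coefficient eta = Q_abs / Q_input."""

    eta: float
    slope_k_per_s: float  # initial temperature slope dT/dt
    nonpositive_slope: bool = False


def energy_conversion_coefficient(time_s, temperature_c, mass_g, c_p,
                                  p_input_w, window_s: float = 30.0) -> EtaResult:
    """Estimate eta from the initial slope of a calorimetry trace.

    eta = m c_p (dT/dt)_0 / P_input with the slope taken by least squares
    over the first ``window_s`` seconds (default 30 s, pulse-averaged).

    A nonpositive slope is reported with a flag rather than raised: a flat
    trace legitimately encodes eta = 0.
    """
    t = np.asarray(time_s, dtype=float)
    temp = np.asarray(temperature_c, dtype=float)
    if p_input_w <= 0:
        raise ValueError("input power must be positive")
    mask = t <= window_s
    if mask.sum() < 5:
        raise ValueError("need at least 5 points in the initial window")
    if np.ptp(temp[mask]) == 0:
        slope = 0.0
    else:
        slope = stats.linregress(t[mask], temp[mask]).slope
    eta = mass_g * c_p * slope / p_input_w
    flagged = slope <= 0
    if flagged and slope < 0:
        import warnings

        warnings.warn("nonpositive initial slope; eta reported <= 0")
    return EtaResult(eta, slope, flagged)


def cavitation_index(iodine, oh, calibration) -> np.ndarray | float:
    """Composite cavitation index CI = (z(iodine) + z(OH)) / 2.

    ``calibration`` is ``(iodine_mean, iodine_sd, oh_mean, oh_sd)`` of the
    reference population against which both dosimeters are standardized.
    """
    m_i, s_i, m_o, s_o = calibration
    if s_i <= 0 or s_o <= 0:
        raise ValueError("calibration SDs must be positive")
    z_i = (np.asarray(iodine, dtype=float) - m_i) / s_i
    z_o = (np.asarray(oh, dtype=float) - m_o) / s_o
    ci = 0.5 * (z_i + z_o)
    return ci if ci.ndim else float(ci)


@dataclass
class MassTransferModel:
    """Coefficients of k_m = k0 + alpha (P/V) + beta (P/V)^2 - gamma eta."""

    k0: float
    alpha: float
    beta: float
    gamma: float

    def evaluate(self, power_density, eta):
        p = np.asarray(power_density, dtype=float)
        e = np.asarray(eta, dtype=float)
        out = self.k0 + self.alpha * p + self.beta * p ** 2 - self.gamma * e
        return out if out.ndim else float(out)


#: The empirical model reported for the six-tea dosimetry campaign.
PRINTED_MASS_TRANSFER = MassTransferModel(k0=1.0, alpha=1.1, beta=0.3, gamma=0.15)

_DESIGN_COLUMNS = ("intercept", "P/V", "(P/V)^2", "eta")


class MassTransferRegressor(BaseEstimator, RegressorMixin):
    """Least-squares estimator of the empirical mass-transfer surface.

    Fits k_m on the design {1, P/V, (P/V)^2, eta}; the eta coefficient is
    reported negated as ``gamma_`` so the fitted surface reads
    k0 + alpha P + beta P^2 - gamma eta.

    Parameters
    ----------
    rank_rtol : float
        Relative tolerance for the rank check of the design matrix.

    Attributes
    ----------
    k0_, alpha_, beta_, gamma_ : float
        Fitted coefficients.
    model_ : MassTransferModel
    r_squared_adj_ : float
        Adjusted coefficient of determination.
    """

    def __init__(self, rank_rtol: float = 1e-10):
        self.rank_rtol = rank_rtol

    def _design(self, X):
        X = check_array(X)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: power density and eta")
        p, eta = X[:, 0], X[:, 1]
        return np.column_stack([np.ones_like(p), p, p ** 2, eta])

    def fit(self, X, y):
        A = self._design(X)
        y = np.asarray(y, dtype=float)
        if A.shape[0] < 4:
            raise ValueError("need at least 4 records")
        if np.unique(A[:, 1]).size < 3:
            raise ValueError("need at least 3 distinct power levels")
        rank = np.linalg.matrix_rank(A, tol=self.rank_rtol * np.abs(A).max())
        if rank < A.shape[1]:
            # name the columns involved in the deficiency
            bad = []
            for j in range(1, A.shape[1]):
                sub = np.delete(A, j, axis=1)
                if np.linalg.matrix_rank(sub, tol=self.rank_rtol * np.abs(A).max()) == rank:
                    bad.append(_DESIGN_COLUMNS[j])
            raise ValueError(
                f"rank-deficient design; collinear columns: {bad or list(_DESIGN_COLUMNS)}")
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        self.k0_, self.alpha_, self.beta_ = coef[0], coef[1], coef[2]
        self.gamma_ = -coef[3]
        self.model_ = MassTransferModel(self.k0_, self.alpha_, self.beta_, self.gamma_)
        resid = y - A @ coef
        sst = np.sum((y - y.mean()) ** 2)
        n, k = A.shape[0], A.shape[1] - 1
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 1.0
        self.r_squared_ = r2
        self.r_squared_adj_ = 1.0 - (1.0 - r2) * (n - 1) / max(n - k - 1, 1)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return self.model_.evaluate(X[:, 0], X[:, 1])


def fit_mass_transfer_model(records) -> MassTransferModel:
    """Functional wrapper around :class:`MassTransferRegressor`.

    ``records`` is an iterable of (P/V, eta, k_m) tuples or a DataFrame with
    columns ``power``/``eta``/``k_m``.
    """
    if isinstance(records, pd.DataFrame):
        X = records[["power", "eta"]].to_numpy(dtype=float)
        y = records["k_m"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(records), dtype=float)
        X, y = arr[:, :2], arr[:, 2]
    return MassTransferRegressor().fit(X, y).model_


def eval_mass_transfer(model: MassTransferModel, power_density, eta):
    """Evaluate k_m = k0 + alpha P + beta P^2 - gamma eta."""
    return model.evaluate(power_density, eta)
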