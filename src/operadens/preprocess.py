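"""Transform, covariate-adjust and standardize density measures.

Each raw density measure is power-transformed (Box-Cox, lambda by maximum
likelihood) toward normality, regressed on age and BMI among *controls
only*, and the residuals of all subjects are divided by the control
residual standard deviation.  One unit of the resulting variable is one
"adjusted standard deviation", the scale on which odds ratios per adjusted
SD (OPERA) are defined.  Fitting the adjustment on controls only keeps
case status out of the covariate model.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BoxCoxFit",
    "AdjustedMeasure",
    "boxcox_lambda_mle",
    "boxcox_transform",
    "DensityStandardizer",
    "adjust_and_standardize",
    "average_measurers",
]

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclasses.dataclass
class BoxCoxFit:
    """Box-Cox power parameter fitted by profile maximum likelihood."""

    lam: float
    loglik: float
    shift: float = 0.0

    def transform(self, y) -> np.ndarray:
        return boxcox_transform(np.asarray(y, dtype=float) + self.shift, self.lam)


def boxcox_transform(y, lam: float) -> np.ndarray:
    """(y^lam - 1)/lam, with the log limit at lam = 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise PreprocessError("Box-Cox requires strictly positive values; "
                              "apply a shift before transforming")
    return special.boxcox(y, lam)


def boxcox_lambda_mle(y, shift: float | None = None,
                      bounds: tuple[float, float] = (-3.0, 3.0)) -> BoxCoxFit:
    """Estimate lambda maximizing the Box-Cox profile log-likelihood.

    The profile likelihood is the normal likelihood of the transformed data
    plus the (lambda - 1) * sum(log y) Jacobian term
    (:func:`scipy.stats.boxcox_llf`).  ``shift`` is added to ``y`` first;
    non-positive data with no shift is an error.
    """
    y = np.asarray(y, dtype=float)
    if shift is None:
        shift = 0.0
        if np.any(y <= 0):
            raise PreprocessError(
                f"{int(np.sum(y <= 0))} non-positive values; pass shift= "
                "(e.g. half the smallest positive value)")
    ys = y + shift
    if np.any(ys <= 0):
        raise PreprocessError("values remain non-positive after shift")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, ys),
        bounds=bounds, method="bounded",
        options={"xatol": 1e-6})
    lam = float(res.x)
    return BoxCoxFit(lam=lam, loglik=float(-res.fun), shift=float(shift))


@dataclasses.dataclass
class AdjustedMeasure:
    """A transformed, covariate-adjusted, SD-standardized density measure.

    ``values_standardized`` has control-subset SD exactly 1.  ``coef`` are
    the control-fitted OLS coefficients (intercept, age, BMI) applied to
    every subject.  ``sd_adjusted`` (control residual SD, n-1 denominator)
    is the "adjusted standard deviation" of the OPERA construction; it can
    never exceed ``sd_unadjusted``.
    """

    values_standardized: np.ndarray
    lam: float | None
    coef: np.ndarray
    sd_unadjusted: float
    sd_adjusted: float


class DensityStandardizer(BaseEstimator, TransformerMixin):
    """Box-Cox transform + control-based covariate adjustment + unit-SD scaling.

    ``X`` is ``(n, 3)``: raw density value, age, BMI.  The control mask is
    given at fit time; lambda and the OLS adjustment are estimated on
    controls only and then applied to all rows.

    Parameters
    ----------
    method : "boxcox" to estimate lambda, "none" to skip the power step
        (input already transformed).
    shift : "auto" shifts by half the smallest positive value when zeros
        are present; a float is used as-is; None forbids shifting.
    lambda_bounds : search interval for lambda.
    """

    def __init__(self, method: str = "boxcox", shift="auto",
                 lambda_bounds: tuple[float, float] = (-3.0, 3.0)):
        self.method = method
        self.shift = shift
        self.lambda_bounds = lambda_bounds

    def _resolve_shift(self, v: np.ndarray) -> float:
        if self.shift == "auto":
            if np.all(v > 0):
                return 0.0
            pos = v[v > 0]
            if pos.size == 0:
                raise PreprocessError("all values non-positive; cannot auto-shift")
            s = float(pos.min()) / 2.0
            logger.info("shifting %d non-positive values by %.6g", int((v <= 0).sum()), s)
            return s
        if self.shift is None:
            return 0.0
        return float(self.shift)

    def fit(self, X, y=None, *, controls=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise PreprocessError("X must be (n, 3): value, age, BMI")
        if np.any(~np.isfinite(X)):
            raise PreprocessError("missing or non-finite values; exclude such rows upstream")
        controls = np.ones(X.shape[0], bool) if controls is None else np.asarray(controls, bool)
        if controls.sum() < 3:
            raise PreprocessError("need at least 3 controls to adjust and standardize")
        v, age, bmi = X[:, 0], X[:, 1], X[:, 2]

        if self.method == "boxcox":
            shift = self._resolve_shift(v[controls])
            bc = boxcox_lambda_mle(v[controls], shift=shift, bounds=self.lambda_bounds)
            self.lambda_ = bc.lam
            self.shift_ = bc.shift
            t = boxcox_transform(v + self.shift_, self.lambda_)
        elif self.method == "none":
            self.lambda_ = None
            self.shift_ = 0.0
            t = v.copy()
        else:
            raise PreprocessError(f"unknown transform method {self.method!r}")

        D = np.column_stack([np.ones_like(age), age, bmi])[controls]
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            raise PreprocessError(
                f"covariate design is rank-deficient (rank {rank} < {D.shape[1]}); "
                "age and BMI are collinear")
        coef, *_ = np.linalg.lstsq(D, t[controls], rcond=None)
        self.coef_ = coef
        resid_controls = t[controls] - D @ coef
        self.sd_unadjusted_ = float(np.std(t[controls], ddof=1))
        self.sd_adjusted_ = float(np.std(resid_controls, ddof=1))
        if self.sd_adjusted_ < 1e-12:
            raise PreprocessError("zero adjusted SD: transformed measure is an exact "
                                  "function of age and BMI among controls")
        self.controls_ = controls
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        v, age, bmi = X[:, 0], X[:, 1], X[:, 2]
        if self.lambda_ is not None:
            t = boxcox_transform(v + self.shift_, self.lambda_)
        else:
            t = v
        resid = t - np.column_stack([np.ones_like(age), age, bmi]) @ self.coef_
        return resid / self.sd_adjusted_

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


def adjust_and_standardize(transformed, age, bmi, control_flag) -> AdjustedMeasure:
    """Adjust already-transformed values for age and BMI and scale to unit
    adjusted SD, with the regression fitted on controls only."""
    transformed = np.asarray(transformed, dtype=float)
    X = np.column_stack([transformed, np.asarray(age, float), np.asarray(bmi, float)])
    std = DensityStandardizer(method="none")
    std.fit(X, controls=control_flag)
    values = std.transform(X)
    return AdjustedMeasure(
        values_standardized=values, lam=None, coef=std.coef_,
        sd_unadjusted=std.sd_unadjusted_, sd_adjusted=std.sd_adjusted_)


def average_measurers(standardized_per_measurer, control_flag=None):
    """Element-wise mean of per-measurer standardized values.

    Averaging imperfectly correlated unit-variance measures shrinks the
    control SD to sqrt((1 + (k-1) rbar) / k); the average is therefore
    re-reported with its own control SD rather than assumed to have SD 1.

    Returns ``(averaged values, control SD of the average)``.
    """
    arrays = []
    for m in standardized_per_measurer:
        a = m.values_standardized if isinstance(m, AdjustedMeasure) else np.asarray(m, float)
        arrays.append(a)
    n = {a.shape[0] for a in arrays}
    if len(n) != 1:
        raise PreprocessError(f"measurers cover different subject sets (sizes {sorted(n)})")
    avg = np.mean(arrays, axis=0)
    mask = np.ones(avg.shape[0], bool) if control_flag is None else np.asarray(control_flag, bool)
    return avg, float(np.std(avg[mask], ddof=1))
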