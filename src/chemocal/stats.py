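"""Figures of merit for multivariate calibration validation.

Recovery percent (accuracy), its mean/SD/RSD (precision), root-mean-
square errors (RMSEC on the calibration set, RMSECV under cross-
validation, RMSEP on the validation set), the predicted-versus-actual
regression line, and the two-sample comparison against a reference
method (pooled-variance Student's t and the variance-ratio F test, both
two-sided at P = 0.05).

Conventions validated against the reference workflow's printed tables:
SD uses the n-1 denominator, RMSE uses 1/n with no degrees-of-freedom
correction, samples where the true concentration is zero yield an NA
recovery and are excluded from all summary statistics, and the F
statistic always places the larger variance in the numerator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidParameterError, ShapeError

__all__ = [
    "recovery_percent",
    "recovery_summary",
    "rmse",
    "regress_pred_actual",
    "variance_ratio_f",
    "pooled_t",
    "critical_t",
    "critical_f",
    "EvaluationReport",
    "MethodComparison",
    "evaluation_report",
    "compare_methods",
]

#: Accuracy band: mean recovery within 100 +/- 3 percent.
RECOVERY_BAND = (97.0, 103.0)
#: Precision limit: RSD at most 2 percent.
RSD_LIMIT = 2.0


def _matched(predicted, actual):
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ShapeError("predicted and actual must have the same shape")
    return predicted, actual


def recovery_percent(predicted, actual) -> np.ndarray:
    """100 * predicted / actual; NaN (NA) where the true value is zero."""
    predicted, actual = _matched(predicted, actual)
    out = np.full(actual.shape, np.nan)
    nz = actual != 0
    out[nz] = 100.0 * predicted[nz] / actual[nz]
    return out


def recovery_summary(recoveries) -> tuple[float, float, float]:
    """(mean, sample SD, RSD%) of the non-NA recoveries."""
    r = np.asarray(recoveries, dtype=float)
    r = r[~np.isnan(r)]
    if r.size < 2:
        raise InvalidParameterError("need at least 2 non-NA recoveries")
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    rsd = 100.0 * sd / mean if mean != 0 else float("nan")
    return mean, sd, rsd


def rmse(predicted, actual) -> float:
    """sqrt(mean squared error), 1/n denominator."""
    predicted, actual = _matched(predicted, actual)
    if predicted.size == 0:
        raise InvalidParameterError("rmse needs at least one sample")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


def regress_pred_actual(predicted, actual) -> tuple[float, float, float]:
    """OLS line of predicted on actual: (slope, intercept, Pearson r)."""
    predicted, actual = _matched(predicted, actual)
    if predicted.size < 3:
        raise InvalidParameterError("regression needs at least 3 points")
    if np.ptp(actual) == 0:
        raise InvalidParameterError("actual values must not be constant")
    res = sps.linregress(actual, predicted)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def variance_ratio_f(variance_a: float, variance_b: float) -> float:
    """F statistic: larger variance over smaller (always >= 1)."""
    if variance_a <= 0 or variance_b <= 0:
        raise InvalidParameterError("variances must be positive")
    return max(variance_a, variance_b) / min(variance_a, variance_b)


def pooled_t(
    mean_a: float, var_a: float, n_a: int, mean_b: float, var_b: float, n_b: int
) -> tuple[float, int]:
    """Two-sample pooled-variance |t| and its degrees of freedom."""
    if n_a < 2 or n_b < 2:
        raise InvalidParameterError("each group needs n >= 2")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    t = abs(mean_a - mean_b) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return float(t), df


def critical_t(df: int, alpha: float = 0.05) -> float:
    """Two-sided critical t at significance alpha."""
    return float(sps.t.ppf(1 - alpha / 2, df))


def critical_f(df_num: int, df_den: int, alpha: float = 0.05) -> float:
    """One-sided critical F (larger variance in the numerator)."""
    return float(sps.f.ppf(1 - alpha, df_num, df_den))


@dataclass(frozen=True)
class EvaluationReport:
    """Validation-set figures of merit for one analyte under one model."""

    analyte: str
    model: str
    recovery_percent: np.ndarray
    mean_recovery: float
    sd_recovery: float
    rsd_percent: float
    rmsep: float
    slope: float
    intercept: float
    correlation_r: float
    rmsec: float | None = None
    rmsecv: float | None = None

    def to_dict(self) -> dict:
        d = {
            "analyte": self.analyte,
            "model": self.model,
            "recovery_percent": [
                None if np.isnan(v) else round(float(v), 6) for v in self.recovery_percent
            ],
            "mean_recovery": self.mean_recovery,
            "sd_recovery": self.sd_recovery,
            "rsd_percent": self.rsd_percent,
            "rmsep": self.rmsep,
            "slope": self.slope,
            "intercept": self.intercept,
            "correlation_r": self.correlation_r,
            "rmsec": self.rmsec,
            "rmsecv": self.rmsecv,
        }
        return d


@dataclass(frozen=True)
class MethodComparison:
    """Pooled t / variance-ratio F comparison of two methods' recoveries."""

    mean_a: float
    mean_b: float
    variance_a: float
    variance_b: float
    n_a: int
    n_b: int
    t_statistic: float
    t_df: int
    t_critical: float
    f_statistic: float
    f_critical: float


def evaluation_report(
    predicted,
    actual,
    analyte: str = "",
    model: str = "",
    rmsec: float | None = None,
    rmsecv: float | None = None,
) -> EvaluationReport:
    """Assemble the full validation report for one analyte.

    Zero-concentration samples contribute neither recoveries nor RMSEP
    (their recovery is undefined); the predicted-vs-actual line uses all
    samples.
    """
    predicted, actual = _matched(predicted, actual)
    rec = recovery_percent(predicted, actual)
    mean, sd, rsd = recovery_summary(rec)
    nz = actual != 0
    slope, intercept, r = regress_pred_actual(predicted, actual)
    return EvaluationReport(
        analyte=analyte,
        model=model,
        recovery_percent=rec,
        mean_recovery=mean,
        sd_recovery=sd,
        rsd_percent=rsd,
        rmsep=rmse(predicted[nz], actual[nz]),
        slope=slope,
        intercept=intercept,
        correlation_r=r,
        rmsec=rmsec,
        rmsecv=rmsecv,
    )


def compare_methods(
    mean_a, var_a, n_a, mean_b, var_b, n_b, alpha: float = 0.05
) -> MethodComparison:
    """t/F comparison of two methods from their summary statistics."""
    t, df = pooled_t(mean_a, var_a, n_a, mean_b, var_b, n_b)
    f = variance_ratio_f(var_a, var_b)
    hi, lo = (n_a, n_b) if var_a >= var_b else (n_b, n_a)
    return MethodComparison(
        mean_a=float(mean_a),
        mean_b=float(mean_b),
        variance_a=float(var_a),
        variance_b=float(var_b),
        n_a=int(n_a),
        n_b=int(n_b),
        t_statistic=t,
        t_df=df,
        t_critical=critical_t(df, alpha),
        f_statistic=f,
        f_critical=critical_f(hi - 1, lo - 1, alpha),
    )
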