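"""Cohort-level ICM-to-FCM calibration.

Both instruments measure the same physical quantity (nuclear DNA content)
on different arbitrary scales, so a transfer function mapping
image-cytometry peak locations to flow-cytometry channel units is sought
two ways:

* the *naive* transfer — per sample, the least-squares scale through the
  origin that maps the sample's (2N, 4N) ICM peaks onto its FCM peaks,
  summarized by the arithmetic mean and SD over the cohort; and
* a pooled ordinary-least-squares regression ``fcm = a * icm + b`` over
  the cohort's peak points, with RMSE, R-squared, and a Shapiro-Wilk test
  on the residuals (heterogeneous per-slide illumination leaves the
  residuals visibly non-normal, which is itself a diagnostic).

Low-intensity outlier slides (bleached during scanner-parameter tuning)
are flagged automatically by a modified z-score on the log 2N peak
location; a manual exclusion list can override or augment the rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import PeakPair

logger = logging.getLogger(__name__)

MODIFIED_Z_CUTOFF = -3.5


def per_sample_scale(pair: PeakPair) -> float:
    """Least-squares through-origin scale mapping one sample's ICM peaks
    onto its FCM peaks:

        s = (fcm_2N * icm_2N + fcm_4N * icm_4N) / (icm_2N^2 + icm_4N^2)
    """
    denom = pair.icm_2N**2 + pair.icm_4N**2
    if denom <= 0:
        raise ValueError("ICM peaks must be positive")
    return (pair.fcm_2N * pair.icm_2N + pair.fcm_4N * pair.icm_4N) / denom


def ratio_stats(ratios) -> tuple[float, float]:
    """Cohort mean and sample SD (n-1) of per-sample peak ratios."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 2:
        raise ValueError("need at least 2 samples")
    return float(ratios.mean()), float(ratios.std(ddof=1))


def naive_transfer(scales) -> tuple[float, float]:
    """Mean and sample SD of the per-sample through-origin scales."""
    scales = np.asarray(scales, dtype=float)
    if scales.size < 2:
        raise ValueError("need at least 2 samples")
    return float(scales.mean()), float(scales.std(ddof=1))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    rmse: float
    r_squared: float
    shapiro_stat: float
    shapiro_p: float
    n_points: int
    residuals: np.ndarray = field(repr=False)


def fit_regression(
    icm: np.ndarray, fcm: np.ndarray, exclude: np.ndarray | None = None
) -> RegressionResult:
    """Pooled OLS transfer function ``fcm = slope * icm + intercept``.

    ``exclude`` marks points to drop (outlier samples). RMSE is
    ``sqrt(sum(r^2)/n)``; residual normality is assessed by Shapiro-Wilk.
    """
    icm = np.asarray(icm, dtype=float)
    fcm = np.asarray(fcm, dtype=float)
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        icm, fcm = icm[keep], fcm[keep]
    if icm.size < 3:
        raise ValueError("need at least 3 points after exclusion")
    if np.ptp(icm) == 0:
        raise ValueError("degenerate regression: no variance in ICM peaks")
    res = stats.linregress(icm, fcm)
    resid = fcm - (res.slope * icm + res.intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.allclose(resid, resid[0]):
        sw_stat, sw_p = 1.0, 1.0  # exact fit: residuals are all (near) zero
    else:
        sw = stats.shapiro(resid)
        sw_stat, sw_p = float(sw.statistic), float(sw.pvalue)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        rmse=rmse,
        r_squared=float(res.rvalue**2),
        shapiro_stat=sw_stat,
        shapiro_p=sw_p,
        n_points=int(icm.size),
        residuals=resid,
    )


def flag_intensity_outliers(
    peak_2N: np.ndarray, manual: tuple[int, ...] = ()
) -> np.ndarray:
    """Flag low-intensity samples by modified z-score on the log 2N peak.

    A sample is flagged when ``0.6745 * (log x - median) / MAD < -3.5``
    (robust one-sided rule for dim slides). ``manual`` indices (0-based)
    are always flagged in addition, mirroring exclusion by visual
    inspection. With fewer than 5 samples or zero MAD only the manual
    list applies (warned).
    """
    peak_2N = np.asarray(peak_2N, dtype=float)
    n = peak_2N.size
    flags = np.zeros(n, dtype=bool)
    for idx in manual:
        if not 0 <= idx < n:
            raise IndexError(f"manual exclusion index {idx} out of range")
        flags[idx] = True
    if n < 5:
        raise ValueError("need at least 5 samples for the automatic rule")
    logx = np.log(peak_2N)
    med = np.median(logx)
    mad = np.median(np.abs(logx - med))
    if mad == 0:
        logger.warning("zero MAD; automatic outlier rule disabled, manual list only")
        return flags
    modz = 0.6745 * (logx - med) / mad
    return flags | (modz < MODIFIED_Z_CUTOFF)


class CohortCalibrator(BaseEstimator):
    """Fit the cohort-level ICM-to-FCM transfer function.

    ``fit`` consumes a list of :class:`PeakPair` (one per sample) and
    computes: per-sample through-origin scales, the naive mean-scale
    transfer, intensity-outlier flags, and pooled OLS regressions both
    with and without the flagged samples.

    Parameters
    ----------
    pooling : "both_peaks" (default; each sample contributes its 2N and
        4N peak as two regression points) or "2N_only".
    manual_exclusions : 0-based sample indices always treated as outliers.

    Attributes (after ``fit``)
    --------------------------
    scales_, naive_scale_, naive_sd_ : naive transfer.
    outlier_flags_ : per-sample boolean flags.
    regression_all_, regression_excl_ : :class:`RegressionResult` before
        and after outlier exclusion (``regression_excl_`` is None when
        nothing is flagged).
    """

    def __init__(
        self,
        pooling: str = "both_peaks",
        manual_exclusions: tuple[int, ...] = (),
    ) -> None:
        self.pooling = pooling
        self.manual_exclusions = manual_exclusions

    def fit(self, pairs: list[PeakPair], y=None) -> "CohortCalibrator":
        if self.pooling not in ("both_peaks", "2N_only"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")
        if len(pairs) < 2:
            raise ValueError("need at least 2 samples")
        self.sample_ids_ = [p.sample_id for p in pairs]
        self.scales_ = np.array([per_sample_scale(p) for p in pairs])
        self.naive_scale_, self.naive_sd_ = naive_transfer(self.scales_)
        if len(pairs) >= 5:
            self.outlier_flags_ = flag_intensity_outliers(
                np.array([p.icm_2N for p in pairs]), manual=self.manual_exclusions
            )
        else:
            logger.warning(
                "fewer than 5 samples: automatic outlier rule skipped, manual "
                "exclusions only"
            )
            self.outlier_flags_ = np.zeros(len(pairs), dtype=bool)
            for idx in self.manual_exclusions:
                self.outlier_flags_[idx] = True

        if self.pooling == "both_peaks":
            icm = np.array([[p.icm_2N, p.icm_4N] for p in pairs]).ravel()
            fcm = np.array([[p.fcm_2N, p.fcm_4N] for p in pairs]).ravel()
            excl = np.repeat(self.outlier_flags_, 2)
        else:
            icm = np.array([p.icm_2N for p in pairs])
            fcm = np.array([p.fcm_2N for p in pairs])
            excl = self.outlier_flags_
        self.regression_all_ = fit_regression(icm, fcm)
        self.regression_excl_ = (
            fit_regression(icm, fcm, exclude=excl) if excl.any() else None
        )
        return self

    def predict(self, icm_peaks) -> np.ndarray:
        """Map ICM peak locations to FCM channel units (outlier-cleaned
        regression when available, otherwise the all-sample fit)."""
        reg = self.regression_excl_ or self.regression_all_
        return reg.slope * np.asarray(icm_peaks, dtype=float) + reg.intercept

    def report(self) -> dict:
        """JSON-ready summary of the fitted calibration."""
        def _reg(r):
            return None if r is None else {
                "slope": r.slope,
                "intercept": r.intercept,
                "rmse": r.rmse,
                "r_squared": r.r_squared,
                "shapiro_stat": r.shapiro_stat,
                "shapiro_p": r.shapiro_p,
                "n_points": r.n_points,
            }

        return {
            "naive_scale": self.naive_scale_,
            "naive_scale_sd": self.naive_sd_,
            "per_sample_scales": dict(zip(self.sample_ids_, self.scales_.tolist())),
            "outliers": [
                sid for sid, f in zip(self.sample_ids_, self.outlier_flags_) if f
            ],
            "regression_all": _reg(self.regression_all_),
            "regression_outliers_excluded": _reg(self.regression_excl_),
        }
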