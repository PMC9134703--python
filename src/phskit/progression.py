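"""Amyloid progression curve and age-of-onset imputation.

Amyloid burden on the Centiloid (CL) scale is treated as a monotone function
of a latent "disease time" shared across individuals.  The curve is built
from longitudinal scans with a slope-vs-level construction: each individual
contributes an accumulation rate (least-squares slope of CL against age) at
their mean CL level; a constrained quadratic is fitted to rate as a function
of level; integrating ``dCL/dtau = f(CL)`` outward from the abnormality
threshold (20 CL, where disease time tau = 0) yields the progression curve
``CL(tau)`` and its inverse ``tau(CL)``.

An individual's onset age is then imputed as their mean longitudinal scan
age minus the disease time their mean longitudinal CL level corresponds to;
individuals whose mean CL never reaches the threshold are censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from sklearn.base import BaseEstimator

__all__ = [
    "classify_abnormal",
    "ProgressionCurve",
    "fit_progression_curve",
    "estimate_onset_age",
    "OnsetEstimate",
    "AmyloidProgressionModel",
]

REGIONS = ("neocortex", "frontal", "posterior_cingulate")


def classify_abnormal(cl_value, threshold: float = 20.0):
    """True where the Centiloid value is at or above the abnormality threshold.

    The boundary is inclusive: CL equal to the threshold is abnormal.
    """
    cl = np.asarray(cl_value, dtype=float)
    if not np.all(np.isfinite(cl)):
        raise ValueError("non-finite Centiloid value")
    out = cl >= threshold
    return bool(out) if np.isscalar(cl_value) else out


@dataclass
class ProgressionCurve:
    """Monotone Centiloid-vs-disease-time curve anchored at the threshold.

    ``cl_grid`` is strictly increasing over the valid range (floor, ceiling)
    and ``tau_grid`` holds the corresponding disease times, with
    ``tau(threshold) = 0``.  Outside the grid, both directions continue
    linearly with the terminal slope (extrapolation is flagged by
    ``in_range``).
    """

    cl_grid: np.ndarray
    tau_grid: np.ndarray
    threshold: float
    floor: float
    ceiling: float

    def tau(self, cl):
        """Disease time at a Centiloid level (vectorised, linear extrapolation)."""
        cl = np.asarray(cl, dtype=float)
        tau = np.interp(cl, self.cl_grid, self.tau_grid)
        # np.interp clamps; extend linearly with terminal slopes instead
        lo_slope = (self.tau_grid[1] - self.tau_grid[0]) / (self.cl_grid[1] - self.cl_grid[0])
        hi_slope = (self.tau_grid[-1] - self.tau_grid[-2]) / (self.cl_grid[-1] - self.cl_grid[-2])
        tau = np.where(cl < self.cl_grid[0], self.tau_grid[0] + (cl - self.cl_grid[0]) * lo_slope, tau)
        tau = np.where(cl > self.cl_grid[-1], self.tau_grid[-1] + (cl - self.cl_grid[-1]) * hi_slope, tau)
        return float(tau) if tau.ndim == 0 else tau

    def cl(self, tau):
        """Centiloid level at a disease time (inverse of ``tau``)."""
        tau = np.asarray(tau, dtype=float)
        cl = np.interp(tau, self.tau_grid, self.cl_grid)
        lo_slope = (self.cl_grid[1] - self.cl_grid[0]) / (self.tau_grid[1] - self.tau_grid[0])
        hi_slope = (self.cl_grid[-1] - self.cl_grid[-2]) / (self.tau_grid[-1] - self.tau_grid[-2])
        cl = np.where(tau < self.tau_grid[0], self.cl_grid[0] + (tau - self.tau_grid[0]) * lo_slope, cl)
        cl = np.where(tau > self.tau_grid[-1], self.cl_grid[-1] + (tau - self.tau_grid[-1]) * hi_slope, cl)
        return float(cl) if cl.ndim == 0 else cl

    def in_range(self, cl):
        cl = np.asarray(cl, dtype=float)
        return (cl >= self.cl_grid[0]) & (cl <= self.cl_grid[-1])

    def to_csv(self, path) -> None:
        pd.DataFrame({"tau": self.tau_grid, "centiloid": self.cl_grid}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, threshold: float = 20.0) -> "ProgressionCurve":
        t = pd.read_csv(path)
        cl = t["centiloid"].to_numpy()
        return cls(cl, t["tau"].to_numpy(), threshold, float(cl[0]), float(cl[-1]))


def _per_individual_rates(series: pd.DataFrame) -> pd.DataFrame:
    """Least-squares CL-vs-age slope and mean CL per individual (>= 2 scans)."""
    rows = []
    for pid, g in series.groupby("participant_id", sort=False):
        if len(g) < 2:
            continue
        ages = g["age"].to_numpy(dtype=float)
        cl = g["centiloid"].to_numpy(dtype=float)
        slope = np.polyfit(ages, cl, 1)[0]
        rows.append((pid, slope, cl.mean()))
    return pd.DataFrame(rows, columns=["participant_id", "rate", "level"])


def fit_progression_curve(
    series: pd.DataFrame,
    threshold: float = 20.0,
    floor: float = 0.0,
    ceiling: float = 100.0,
    grid_step: float = 0.25,
    min_rate: float = 1e-3,
) -> ProgressionCurve:
    """Fit the Centiloid progression curve from longitudinal scan series.

    ``series`` is long-format with columns ``participant_id``, ``age``,
    ``centiloid`` (a single region). Requires at least 20 individuals with
    two or more scans. The rate-vs-level relation is fitted as a quadratic
    and clipped to ``min_rate`` where non-positive (with a warning), keeping
    the integrated curve strictly increasing.
    """
    rates = _per_individual_rates(series)
    if len(rates) < 20:
        raise ValueError(
            f"progression curve needs >= 20 individuals with >= 2 scans (got {len(rates)})"
        )
    if np.all(np.abs(rates["rate"]) < 1e-9):
        raise ValueError("no progression signal: all individual rates are ~0")

    # quadratic fit of accumulation rate as a function of CL level; the
    # rate is floored at a small fraction of its fitted maximum so the
    # integrated disease time cannot blow up where the fit decays to zero
    coeffs = np.polyfit(rates["level"], rates["rate"], 2)
    eps = 0.5
    grid = np.arange(floor + eps, ceiling - eps + grid_step / 2, grid_step)
    f = np.polyval(coeffs, grid)
    min_rate = max(min_rate, 0.05 * float(np.max(f)))
    if np.any(f <= min_rate):
        # keep only the contiguous positive-rate interval around the
        # threshold; tau extrapolates linearly beyond it
        warnings.warn(
            "fitted rate function non-positive over part of the CL range; "
            "curve restricted to the positive-rate interval",
            stacklevel=2,
        )
        k = int(np.argmin(np.abs(grid - threshold)))
        if f[k] <= min_rate:
            raise ValueError("no progression signal at the abnormality threshold")
        lo = k
        while lo > 0 and f[lo - 1] > min_rate:
            lo -= 1
        hi = k
        while hi < len(grid) - 1 and f[hi + 1] > min_rate:
            hi += 1
        grid, f = grid[lo : hi + 1], f[lo : hi + 1]

    # integrate d(tau) = dCL / f(CL), then anchor tau(threshold) = 0
    tau = cumulative_trapezoid(1.0 / f, grid, initial=0.0)
    tau = tau - np.interp(threshold, grid, tau)
    return ProgressionCurve(grid, tau, threshold, floor, ceiling)


@dataclass
class OnsetEstimate:
    participant_id: str
    onset_age: float | None
    status: str                 # "event" | "censored"
    censor_reason: str | None   # "never_abnormal" | "withdrew" | "end_of_followup"
    mean_cl: float
    mean_age: float
    extrapolated: bool = False


def estimate_onset_age(
    series: pd.DataFrame,
    curve: ProgressionCurve,
    threshold: float = 20.0,
) -> OnsetEstimate:
    """Impute one individual's amyloid onset age from their scan series.

    The elapsed disease time between crossing the threshold and reaching the
    individual's mean longitudinal CL level is read off the progression curve
    and subtracted from their mean longitudinal scan age. A mean level below
    the threshold yields a censored estimate (reason ``never_abnormal``).
    """
    if series.empty:
        raise ValueError("empty Centiloid series")
    pid = str(series["participant_id"].iloc[0])
    cl = series["centiloid"].to_numpy(dtype=float)
    ages = series["age"].to_numpy(dtype=float)
    mean_cl = float(cl.mean())
    mean_age = float(ages.mean())

    if mean_cl < threshold:
        return OnsetEstimate(pid, None, "censored", "never_abnormal", mean_cl, mean_age)

    extrapolated = False
    level = mean_cl
    if level >= curve.ceiling:
        warnings.warn(
            f"{pid}: mean CL {level:.1f} at/above curve ceiling; clamped", stacklevel=2
        )
        level = curve.ceiling - 1e-6
        extrapolated = True
    elif not bool(np.all(curve.in_range(level))):
        extrapolated = True

    elapsed = curve.tau(level) - curve.tau(threshold)
    return OnsetEstimate(pid, mean_age - elapsed, "event", None, mean_cl, mean_age, extrapolated)


class AmyloidProgressionModel(BaseEstimator):
    """Estimator wrapper: fit the progression curve, predict onset ages.

    Parameters
    ----------
    threshold : float
        Centiloid abnormality threshold (CL >= threshold is abnormal).
    region : str
        Region whose series drive the curve and onset imputation
        (whole neocortex by default).
    floor, ceiling : float
        Valid Centiloid range of the curve.

    Attributes
    ----------
    curve_ : ProgressionCurve
    """

    def __init__(
        self,
        threshold: float = 20.0,
        region: str = "neocortex",
        floor: float = 0.0,
        ceiling: float = 100.0,
        grid_step: float = 0.25,
    ):
        self.threshold = threshold
        self.region = region
        self.floor = floor
        self.ceiling = ceiling
        self.grid_step = grid_step

    def _select(self, X: pd.DataFrame) -> pd.DataFrame:
        if "region" in X.columns:
            known = set(X["region"].unique())
            if not known <= set(REGIONS):
                raise ValueError(f"unknown region label(s): {sorted(known - set(REGIONS))}")
            return X[X["region"] == self.region]
        return X

    def fit(self, X: pd.DataFrame, y=None):
        """Fit the curve from a long-format scan table
        (participant_id, [region], age, centiloid)."""
        self.curve_ = fit_progression_curve(
            self._select(X),
            threshold=self.threshold,
            floor=self.floor,
            ceiling=self.ceiling,
            grid_step=self.grid_step,
        )
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-individual onset estimates as a tidy DataFrame."""
        sub = self._select(X)
        out = [
            estimate_onset_age(g, self.curve_, self.threshold)
            for _, g in sub.groupby("participant_id", sort=False)
        ]
        return pd.DataFrame(
            {
                "participant_id": [e.participant_id for e in out],
                "onset_age": [e.onset_age if e.onset_age is not None else np.nan for e in out],
                "status": [e.status for e in out],
                "censor_reason": [e.censor_reason for e in out],
                "mean_cl": [e.mean_cl for e in out],
                "mean_age": [e.mean_age for e in out],
                "extrapolated": [e.extrapolated for e in out],
            }
        )
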