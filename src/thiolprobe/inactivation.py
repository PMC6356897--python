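"""Iodoacetamide inactivation analysis for thioredoxin activity data.

Covers the activity-based side of the pKa story: converting DTNB-assay
absorbance slopes to TNB formation rates, fitting pseudo-first-order
inactivation constants from semilog activity time courses, and predicting
the pH profile of residual activity under the single-site model in which
activity loss is caused entirely by alkylation of the low-pKa attacking
cysteine (the resolving cysteine stays protonated in the assayed range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alkylation_kinetics import CysSite, thiolate_fraction

__all__ = [
    "ActivityTimecourse",
    "InactivationFit",
    "TNB_EXTINCTION_412",
    "rate_from_abs_slope",
    "fit_inactivation",
    "predict_residual_activity",
]

#: molar extinction coefficient of TNB- at 412 nm, M^-1 cm^-1
TNB_EXTINCTION_412 = 14150.0


@dataclass
class ActivityTimecourse:
    """Residual activity (fraction of untreated control) over time."""

    times: np.ndarray
    activities: np.ndarray
    pH: float | None = None
    IAM_M: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.times.shape != self.activities.shape:
            raise ValueError("times and activities must be equal-length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(self.activities < 0):
            raise ValueError("activities must be >= 0")


@dataclass
class InactivationFit:
    """Pseudo-first-order inactivation constant from a semilog regression."""

    k_inact: float  # min^-1
    intercept: float  # ln(activity) at t = 0
    r_squared: float
    window_min: float
    n_points: int


def rate_from_abs_slope(dA412_per_min: float, path_cm: float = 1.0) -> float:
    """TNB formation rate (M min^-1) from an A412 slope via Beer-Lambert.

    Negative slopes are passed through as negative rates with a warning:
    correcting for the reference rate without enzyme is the caller's job.
    """
    if path_cm <= 0:
        raise ValueError("path length must be > 0")
    if dA412_per_min < 0:
        warnings.warn("negative A412 slope; did you subtract the reference "
                      "rate the wrong way round?", stacklevel=2)
    return dA412_per_min / (TNB_EXTINCTION_412 * path_cm)


def fit_inactivation(
    tc: ActivityTimecourse, linear_window_min: float = 3.0
) -> InactivationFit:
    """OLS of ln(activity) on time within the linear window; k = -slope.

    Points with zero activity inside the window are dropped with a warning
    (their logarithm is undefined); at least 3 usable points are required.
    """
    mask = tc.times <= linear_window_min
    t = tc.times[mask]
    a = tc.activities[mask]
    zero = a <= 0
    if zero.any():
        warnings.warn(f"dropped {int(zero.sum())} zero-activity point(s) "
                      "inside the fit window", stacklevel=2)
        t, a = t[~zero], a[~zero]
    if len(t) < 3:
        raise ValueError(f"need >= 3 positive-activity points within "
                         f"{linear_window_min} min, got {len(t)}")
    y = np.log(a)
    slope, intercept = np.polyfit(t, y, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return InactivationFit(
        k_inact=float(-slope), intercept=float(intercept),
        r_squared=r2, window_min=linear_window_min, n_points=len(t),
    )


def predict_residual_activity(
    pH_grid,
    site: CysSite,
    IAM0: float,
    t: float,
    anchor: tuple[float, float] | None = None,
) -> list[tuple[float, float]]:
    """Residual activity vs pH under single-site Poisson survival.

    residual(pH) = exp(-k_int * alpha(pH, pKa) * IAM0 * t), attributing all
    activity loss to alkylation of the attacking cysteine. If ``anchor`` is
    given as (pH_a, residual_a), k_int is first solved from that point, so
    the profile's shape (not its absolute rate) is the prediction.
    """
    site_k = site.k_int
    if anchor is not None:
        pH_a, res_a = anchor
        if not 0.0 < res_a < 1.0:
            raise ValueError("anchor residual must lie strictly in (0, 1)")
        alpha_a = float(thiolate_fraction(pH_a, site.pKa))
        site_k = -np.log(res_a) / (alpha_a * IAM0 * t)
    alphas = thiolate_fraction(np.asarray(pH_grid, dtype=float), site.pKa)
    residuals = np.exp(-site_k * alphas * IAM0 * t)
    return [(float(p), float(r)) for p, r in zip(np.atleast_1d(pH_grid), np.atleast_1d(residuals))]
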