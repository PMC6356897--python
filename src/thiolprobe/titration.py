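"""Henderson-Hasselbalch sigmoid fitting of pH-fraction titration series.

The observable is the fraction of a protein species that disappears as pH
rises (non-alkylated protein in stage 1, monoalkylated in stage 2):

    F(pH) = bottom + (top - bottom) / (1 + 10**(pH - pKa))

so F(pKa) is the plateau midpoint and the inflection locates the cysteine's
pKa. Fitting is unweighted nonlinear least squares (Levenberg-Marquardt);
either plateau may be fixed, which is how the partial-sigmoid stage-2 series
(data stop short of the lower plateau) stays identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationSeries",
    "HHFitResult",
    "hh_model",
    "fit_hh",
    "pka_summary",
    "fit_per_replicate",
]


def hh_model(pH, pKa, top=1.0, bottom=0.0):
    """Fraction of the acid-side species at ``pH`` (decreasing sigmoid)."""
    pH = np.asarray(pH, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (pH - pKa))


@dataclass
class TitrationSeries:
    """(pH, fraction, replicate) points for one protocol stage."""

    pH: np.ndarray
    fraction: np.ndarray
    replicate: np.ndarray
    stage: str = "step1"

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if not (self.pH.shape == self.fraction.shape == self.replicate.shape):
            raise ValueError("pH, fraction and replicate must be equal-length")
        if np.any((self.fraction < -1e-9) | (self.fraction > 1 + 1e-9)):
            raise ValueError("fractions must lie in [0, 1]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stage: str | None = None) -> "TitrationSeries":
        if stage is not None and "stage" in df.columns:
            df = df[df["stage"] == stage]
        if df.empty:
            raise ValueError(f"no titration rows for stage {stage!r}")
        rep = df["replicate"] if "replicate" in df.columns else np.zeros(len(df), int)
        return cls(df["pH"].to_numpy(), df["fraction"].to_numpy(),
                   np.asarray(rep), stage or "step1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pH": self.pH, "fraction": self.fraction,
            "replicate": self.replicate, "stage": self.stage,
        })

    @property
    def n_distinct_pH(self) -> int:
        return len(np.unique(self.pH))


@dataclass
class HHFitResult:
    """Fitted pKa with plateaus, uncertainty, and fit diagnostics."""

    pKa: float
    pKa_se: float
    top: float
    bottom: float
    rss: float
    converged: bool
    n_iter: int
    pKa_replicate_sd: float | None = None
    n_points: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pKa": self.pKa, "pKa_se": self.pKa_se,
            "pKa_replicate_sd": self.pKa_replicate_sd,
            "top": self.top, "bottom": self.bottom, "rss": self.rss,
            "converged": self.converged, "n_iter": self.n_iter,
            "n_points": self.n_points,
        }


def _initial_pka(pH: np.ndarray, frac: np.ndarray) -> float:
    """pH at the half-range fraction, by linear interpolation of sorted means."""
    order = np.argsort(pH)
    x, y = pH[order], frac[order]
    ux = np.unique(x)
    uy = np.array([y[x == v].mean() for v in ux])
    half = (uy.max() + uy.min()) / 2.0
    # uy decreases with pH; find the bracketing pair
    below = np.nonzero(uy <= half)[0]
    if below.size == 0 or below[0] == 0:
        return float(ux[len(ux) // 2])
    j = below[0]
    x0, x1, y0, y1 = ux[j - 1], ux[j], uy[j - 1], uy[j]
    if y0 == y1:
        return float((x0 + x1) / 2)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def fit_hh(
    series: TitrationSeries,
    fix_top: float | None = None,
    fix_bottom: float | None = None,
    init: dict | None = None,
    max_iter: int = 200,
) -> HHFitResult:
    """Least-squares Henderson-Hasselbalch fit of one titration series.

    Free parameters are (pKa, top, bottom) minus any fixed plateau. The pKa
    standard error comes from the Gauss-Newton covariance (J^T J)^-1 scaled
    by the residual variance. Replicate points enter individually.
    """
    pH, frac = series.pH, series.fraction
    init = init or {}
    names = ["pKa"]
    p0 = [init.get("pKa", _initial_pka(pH, frac))]
    if fix_top is None:
        names.append("top")
        p0.append(init.get("top", float(frac.max())))
    if fix_bottom is None:
        names.append("bottom")
        p0.append(init.get("bottom", float(frac.min())))
    if len(pH) < len(names):
        raise ValueError(
            f"{len(pH)} points cannot constrain {len(names)} free parameters"
        )

    def unpack(params):
        d = dict(zip(names, params))
        top = fix_top if fix_top is not None else d["top"]
        bottom = fix_bottom if fix_bottom is not None else d["bottom"]
        return d["pKa"], top, bottom

    def residuals(params):
        pKa, top, bottom = unpack(params)
        return hh_model(pH, pKa, top, bottom) - frac

    sol = least_squares(residuals, p0, method="lm", xtol=1e-12, ftol=1e-12,
                        gtol=1e-12, max_nfev=max_iter * (len(names) + 1))
    pKa, top, bottom = unpack(sol.x)
    rss = float(2.0 * sol.cost)
    dof = max(len(pH) - len(names), 1)
    s2 = rss / dof
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        pKa_se = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        pKa_se = float("nan")

    warns: list[str] = []
    converged = bool(sol.status > 0)
    # sanity: a converged pKa should sit near the sampled pH range
    if converged and not (pH.min() - 2.0 <= pKa <= pH.max() + 2.0):
        converged = False
        warns.append(f"pKa {pKa:.2f} outside data pH hull +/- 2")
    if converged and np.isfinite(pKa_se) and pKa_se > 0.3:
        warns.append(
            f"pKa SE {pKa_se:.2f} > 0.3: partial-sigmoid data poorly "
            "constrain the fit; consider fixing a plateau"
        )
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return HHFitResult(
        pKa=float(pKa), pKa_se=pKa_se, top=float(top), bottom=float(bottom),
        rss=rss, converged=converged, n_iter=int(sol.nfev),
        n_points=len(pH), warnings=warns,
    )


def fit_per_replicate(series: TitrationSeries, **kwargs) -> list[HHFitResult]:
    """Fit each replicate separately (for across-replicate pKa scatter)."""
    out = []
    for rep in np.unique(series.replicate):
        mask = series.replicate == rep
        sub = TitrationSeries(series.pH[mask], series.fraction[mask],
                              series.replicate[mask], series.stage)
        out.append(fit_hh(sub, **kwargs))
    return out


def pka_summary(fits: list[HHFitResult]) -> tuple[float, float]:
    """Mean and sample SD of pKa over converged replicate fits."""
    used = [f for f in fits if f.converged]
    dropped = len(fits) - len(used)
    if dropped:
        warnings.warn(f"excluded {dropped} non-converged replicate fit(s)",
                      stacklevel=2)
    if len(used) < 2:
        raise ValueError("need >= 2 converged replicate fits for a summary")
    vals = np.array([f.pKa for f in used])
    return float(vals.mean()), float(vals.std(ddof=1))
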