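"""Cohort-level statistics: regression of sampled vs reference LI, and
power-law fits of the coefficient of error against proliferation level.

Two fits recur throughout the analysis:

* ordinary least squares of the single-subsample estimate on the
  whole-region reference LI, reported as R² per (estimator × core count ×
  heterogeneity class) — how representative one punch-once TMA draw is;
* the relative-error law CE = a·x⁻ᵇ, with x the LI in percent, fitted by
  OLS on the log-log scale.  For counts of independent nuclei the exact CE
  of a proportion is sqrt((1−p)/(n·p)) ∝ p^(−1/2) for small p, so b near
  0.5 is the counting-statistics benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RegressionResult",
    "PowerLawFit",
    "RequiredSampling",
    "cohort_regression",
    "fit_power_law",
    "required_sampling",
]


@dataclass(frozen=True)
class RegressionResult:
    r2: float
    slope: float
    intercept: float
    p_value: float
    n_cases: int
    estimator: Optional[str] = None
    hexn: Optional[int] = None
    het_class: Optional[str] = None


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of ce = a · x⁻ᵇ (x in percent LI)."""

    a: float
    b: float
    n_points: int
    n_dropped: int = 0
    scope: Optional[str] = None
    key: Optional[int] = None
    het_class: Optional[str] = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(x, float) ** (-self.b)


@dataclass(frozen=True)
class RequiredSampling:
    """Smallest sampling key whose mean CE meets the target."""

    reached: bool
    key: Optional[float]
    min_ce: float


def cohort_regression(
    pairs: pd.DataFrame,
    estimator: Optional[str] = None,
    hexn: Optional[int] = None,
    het_class: Optional[str] = None,
) -> RegressionResult:
    """OLS of the subsampled estimate ``li_hat`` on the reference ``T``.

    ``pairs`` needs columns ``li_hat`` and ``T`` (one row per case).
    Requires ≥ 3 cases and a non-degenerate predictor.
    """
    li_hat = pairs["li_hat"].to_numpy(float)
    T = pairs["T"].to_numpy(float)
    if len(T) < 3:
        raise ValueError("regression needs at least 3 cases")
    if np.ptp(T) == 0:
        raise ValueError("degenerate predictor: all reference LI values identical")
    res = stats.linregress(T, li_hat)
    return RegressionResult(
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n_cases=len(T),
        estimator=estimator,
        hexn=hexn,
        het_class=het_class,
    )


def fit_power_law(
    li_percent: np.ndarray,
    ce: np.ndarray,
    refine: bool = False,
    **labels,
) -> PowerLawFit:
    """Fit CE = a·x⁻ᵇ by least squares on log CE vs log x.

    Points with non-positive LI or CE carry no log-scale information and are
    dropped (count reported in the result); at least 3 must survive.  With
    ``refine=True`` a nonlinear least-squares pass (direct scale) polishes
    the log-log solution; on exactly power-law data both agree.
    """
    x = np.asarray(li_percent, dtype=float)
    y = np.asarray(ce, dtype=float)
    keep = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"power-law fit needs ≥ 3 valid points, got {len(x)}")
    res = stats.linregress(np.log(x), np.log(y))
    a = float(np.exp(res.intercept))
    b = float(-res.slope)
    if refine:
        try:
            popt, _ = optimize.curve_fit(
                lambda xx, aa, bb: aa * xx ** (-bb), x, y, p0=(a, b), maxfev=10_000
            )
            a, b = float(popt[0]), float(popt[1])
        except RuntimeError:  # keep the log-log solution
            pass
    if b <= 0:
        warnings.warn(f"power-law exponent b = {b:.4g} ≤ 0: CE does not decrease "
                      "with LI on these points", stacklevel=2)
    return PowerLawFit(a=a, b=b, n_points=len(x), n_dropped=n_dropped, **labels)


def required_sampling(
    curve: Mapping[float, float] | pd.Series,
    target_ce: float,
) -> RequiredSampling:
    """Smallest key (core count or nuclei-bin midpoint) with mean CE ≤ target.

    If the curve never meets the target, ``reached`` is False and ``min_ce``
    reports the best error attained.
    """
    if target_ce <= 0:
        raise ValueError("target_ce must be positive")
    items = sorted(dict(curve).items())
    if not items:
        raise ValueError("empty CE curve")
    min_ce = min(v for _, v in items)
    for k, v in items:
        if v <= target_ce:
            return RequiredSampling(reached=True, key=k, min_ce=min_ce)
    return RequiredSampling(reached=False, key=None, min_ce=min_ce)
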