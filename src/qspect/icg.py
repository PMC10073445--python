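"""Indocyanine-green (ICG) clearance kinetics.

ICG is injected intravenously (0.3 mg/kg) and cleared exclusively by the
liver; serial blood samples (0, 5, 10, 15, 20 min) follow a mono-exponential
decay C(t) = C0 * exp(-k t).  Two derived quantities summarize hepatic
function:

* R15 — percent of the initial concentration retained at 15 min,
  100 * exp(-15 k) under the fit;
* PDR — plasma disappearance rate, 100 * k (percent per minute).

Blood concentrations are read off a spectrophotometric standard dilution
curve (absorbance at 805 nm vs known concentration).  Clinical reference:
R15 below 10% and PDR above 18.0 are normal; boundary values count as
abnormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "R15_NORMAL_BELOW",
    "PDR_NORMAL_ABOVE",
    "DilutionStandard",
    "DilutionCurve",
    "ICGSampleSeries",
    "ICGResult",
    "fit_dilution_curve",
    "fit_icg_kinetics",
    "classify_icg",
    "DEFAULT_SAMPLE_TIMES_MIN",
]

R15_NORMAL_BELOW = 10.0  # % at 15 min; strict inequality
PDR_NORMAL_ABOVE = 18.0  # numeric threshold on PDR; strict inequality

DEFAULT_SAMPLE_TIMES_MIN = (0.0, 5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class DilutionStandard:
    """Known concentrations (mg/L) and their absorbances at 805 nm."""

    concentrations: tuple[float, ...]
    absorbances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.absorbances):
            raise ValueError("concentrations and absorbances must have equal length")
        if len(self.concentrations) < 2:
            raise ValueError("need at least 2 standards")
        if len(set(self.concentrations)) < 2:
            raise ValueError("degenerate design: all standard concentrations identical")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("standard concentrations must be >= 0")


@dataclass(frozen=True)
class DilutionCurve:
    """Fitted Beer-Lambert line A = slope * C + intercept with its inverse."""

    slope: float
    intercept: float
    fit_r: float

    def to_absorbance(self, concentration):
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept

    def to_concentration(self, absorbance):
        """Inverse prediction of an unknown's concentration from absorbance."""
        out = (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope
        return float(out) if out.ndim == 0 else out


def fit_dilution_curve(std: DilutionStandard) -> DilutionCurve:
    """OLS of absorbance on concentration (Beer-Lambert is linear)."""
    res = _sps.linregress(std.concentrations, std.absorbances)
    if res.slope == 0:
        raise ValueError("degenerate dilution curve: zero slope")
    r = float(res.rvalue) if math.isfinite(res.rvalue) else 1.0
    return DilutionCurve(slope=float(res.slope), intercept=float(res.intercept), fit_r=r)


@dataclass(frozen=True)
class ICGSampleSeries:
    """Timed blood concentrations (mg/L) after ICG injection."""

    times_min: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        if len(self.times_min) != len(self.concentrations):
            raise ValueError("times and concentrations must have equal length")
        if t[0] != 0.0:
            raise ValueError("first sample must be at t = 0")
        if not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")


@dataclass(frozen=True)
class ICGResult:
    k_per_min: float
    r15_pct: float
    pdr: float
    method: str
    abnormal_r15: bool = False
    abnormal_pdr: bool = False


def fit_icg_kinetics(series: ICGSampleSeries, method: str = "log_linear",
                     exclude_t0: bool = False) -> ICGResult:
    """Estimate the clearance constant k and derive R15 and PDR.

    ``log_linear`` (default) fits ln C(t) = ln C0 - k t by OLS over all
    samples — robust to noise in any single draw.  ``ratio`` is the bedside
    shortcut R15 = 100 * C(15)/C(0), requiring samples at both 0 and 15 min;
    its k is back-derived from R15.  Abnormality flags follow the clinical
    reference thresholds (see :func:`classify_icg`).

    ``exclude_t0`` drops the t=0 sample before fitting (mixing-phase
    exclusion); off by default since the sampling protocol collects it.
    """
    t = np.asarray(series.times_min, dtype=float)
    c = np.asarray(series.concentrations, dtype=float)
    if method == "log_linear":
        if exclude_t0:
            t, c = t[1:], c[1:]
        if np.any(c <= 0):
            raise ValueError("log-linear fit requires strictly positive concentrations")
        if t.size < 3:
            raise ValueError("log-linear fit requires at least 3 samples")
        res = _sps.linregress(t, np.log(c))
        k = -float(res.slope)
        r15 = 100.0 * math.exp(-15.0 * k)
    elif method == "ratio":
        if 15.0 not in t:
            raise ValueError("ratio method requires a sample at t = 15 min")
        c0 = c[t == 0.0][0]
        c15 = c[t == 15.0][0]
        if c0 <= 0:
            raise ValueError("ratio method requires positive C(0)")
        r15 = 100.0 * c15 / c0
        k = -math.log(r15 / 100.0) / 15.0 if r15 > 0 else math.inf
    else:
        raise ValueError(f"unknown method {method!r}")
    result = ICGResult(k_per_min=k, r15_pct=r15, pdr=100.0 * k, method=method)
    return classify_icg(result)


def classify_icg(result: ICGResult) -> ICGResult:
    """Apply the clinical reference thresholds (strict inequalities).

    R15 < 10.0% is normal retention; PDR > 18.0 is normal clearance.
    Boundary values are abnormal.
    """
    return replace(
        result,
        abnormal_r15=not (result.r15_pct < R15_NORMAL_BELOW),
        abnormal_pdr=not (result.pdr > PDR_NORMAL_ABOVE),
    )


def concentrations_from_absorbances(curve: DilutionCurve, times_min: Sequence[float],
                                    absorbances: Sequence[float]) -> ICGSampleSeries:
    """Build a sample series by inverse prediction through the dilution curve."""
    conc = curve.to_concentration(np.asarray(absorbances, dtype=float))
    return ICGSampleSeries(times_min=tuple(float(x) for x in times_min),
                           concentrations=tuple(float(x) for x in np.atleast_1d(conc)))
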