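"""Counts-per-cc <-> activity-concentration calibration and activity unit handling.

A quantitative SPECT reconstruction reports counts per voxel.  Converting
those to physical tracer concentration (uCi/mL) requires a scanner-specific
linear calibration obtained from phantom scans of known concentration:

    counts/cc = slope * concentration(uCi/cc) + intercept

The intercept absorbs the reconstruction's background plateau (scatter,
reconstruction bias), so a zero-concentration region still reads a nonzero
count density.  Canonical internal units are uCi/mL for concentration, mL
for volume and raw counts for image values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "CalibrationPoint",
    "CalibrationModel",
    "fit_calibration",
    "counts_to_concentration",
    "convert_activity",
    "REFERENCE_SLOPE",
    "REFERENCE_INTERCEPT",
    "reference_calibration",
]

# Published calibration line for an attenuation-corrected Siemens Symbia
# reconstruction; used as the default forward model in simulations.
REFERENCE_SLOPE = 6807.3  # counts/cc per uCi/cc
REFERENCE_INTERCEPT = 39.0  # counts/cc

_BQ_PER_UNIT = {
    "Bq": 1.0,
    "kBq": 1.0e3,
    "MBq": 1.0e6,
    "GBq": 1.0e9,
    "uCi": 3.7e4,  # 1 uCi = 37 kBq exactly
    "μCi": 3.7e4,
    "mCi": 3.7e7,
    "Ci": 3.7e10,
}

_VOLUME_SUFFIXES = {"mL", "ml", "cc"}


@dataclass(frozen=True)
class CalibrationPoint:
    """One phantom measurement: mean reconstructed count density vs truth."""

    mean_counts_per_cc: float
    concentration_uCi_per_mL: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean_counts_per_cc) and math.isfinite(self.concentration_uCi_per_mL)):
            raise ValueError("calibration point values must be finite")
        if self.concentration_uCi_per_mL < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class CalibrationModel:
    """Linear map between counts/cc and concentration (uCi/cc).

    ``slope`` has units counts/cc per uCi/cc, ``intercept`` counts/cc.
    ``n_clamped`` accumulates how many values fell below the intercept during
    inversion and were clamped to zero concentration.
    """

    slope: float
    intercept: float
    fit_r: float = 1.0
    fit_p: float = 0.0
    n_points: int = 0
    threshold_pct: float | None = None  # iso-contour threshold used to extract the points
    n_clamped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")
        if not -1.0 <= self.fit_r <= 1.0:
            raise ValueError("fit_r must lie in [-1, 1]")

    def predict_counts(self, concentration_uCi_per_mL):
        """Forward model: concentration (uCi/cc) -> expected counts/cc."""
        return self.slope * np.asarray(concentration_uCi_per_mL, dtype=float) + self.intercept

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "fit_r": self.fit_r,
            "fit_p": self.fit_p,
            "n_points": self.n_points,
            "threshold_pct": self.threshold_pct,
            "units": {"counts": "counts/cc", "concentration": "uCi/mL"},
        }
        payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            fit_r=d.get("fit_r", 1.0),
            fit_p=d.get("fit_p", 0.0),
            n_points=d.get("n_points", 0),
            threshold_pct=d.get("threshold_pct"),
        )


def reference_calibration() -> CalibrationModel:
    """The published regression line as a ready-made model."""
    return CalibrationModel(slope=REFERENCE_SLOPE, intercept=REFERENCE_INTERCEPT)


def fit_calibration(points: Iterable[CalibrationPoint] | Sequence[tuple[float, float]],
                    threshold_pct: float | None = None) -> CalibrationModel:
    """Ordinary least squares of count density on concentration.

    Parameters
    ----------
    points
        CalibrationPoint instances or ``(mean_counts_per_cc, concentration)``
        pairs; at least two points with at least two distinct concentrations.
    threshold_pct
        Optional record of the iso-contour threshold used to extract the mean
        count densities; stored on the model for provenance.
    """
    pts = [p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p) for p in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 calibration points")
    conc = np.array([p.concentration_uCi_per_mL for p in pts], dtype=float)
    counts = np.array([p.mean_counts_per_cc for p in pts], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("degenerate design: all concentrations identical")
    res = _sps.linregress(conc, counts)
    # For a perfect 2-point fit linregress reports r=nan p=nan in edge cases; guard.
    r = float(res.rvalue) if math.isfinite(res.rvalue) else 1.0
    p = float(res.pvalue) if math.isfinite(res.pvalue) else 0.0
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_r=r,
        fit_p=p,
        n_points=len(pts),
        threshold_pct=threshold_pct,
    )


def counts_to_concentration(model: CalibrationModel, counts_per_cc) -> np.ndarray | float:
    """Invert the calibration: counts/cc -> concentration in uCi/cc.

    Values below the intercept imply a negative concentration and are clamped
    to 0; the number of clamped values is accumulated on ``model.n_clamped``.
    """
    if model.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    arr = np.asarray(counts_per_cc, dtype=float)
    conc = (arr - model.intercept) / model.slope
    clamped = conc < 0
    n_clamped = int(np.count_nonzero(clamped))
    if n_clamped:
        model.n_clamped += n_clamped
        conc = np.where(clamped, 0.0, conc)
    if np.isscalar(counts_per_cc) or arr.ndim == 0:
        return float(conc)
    return conc


def _parse_unit(unit: str) -> tuple[float, bool]:
    """Return (Bq-equivalent factor, is_per_mL) for an activity unit string."""
    base, per_ml = unit, False
    if "/" in unit:
        base, suffix = unit.split("/", 1)
        if suffix not in _VOLUME_SUFFIXES:
            raise ValueError(f"unknown unit {unit!r}")
        per_ml = True
    if base not in _BQ_PER_UNIT:
        raise ValueError(f"unknown unit {unit!r}")
    return _BQ_PER_UNIT[base], per_ml


def convert_activity(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between activity (or activity-concentration) units.

    Supported units: Bq, kBq, MBq, GBq, uCi (or μCi), mCi, Ci, each optionally
    per mL/cc (e.g. ``"kBq/mL"``).  Plain and per-volume units cannot be mixed.
    Uses the exact definition 1 uCi = 37 kBq.
    """
    f_from, per_from = _parse_unit(from_unit)
    f_to, per_to = _parse_unit(to_unit)
    if per_from != per_to:
        raise ValueError(f"cannot convert between {from_unit!r} and {to_unit!r}: per-volume mismatch")
    return value * f_from / f_to
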