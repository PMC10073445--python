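"""Digital phantom simulator for post-reconstruction SPECT volumes.

Emulates a fillable Jaszczak-style phantom series: hot inserts (spheres or
cylinders) of known volume and activity concentration inside a voxel grid,
mapped to count densities through a calibration forward model, degraded by a
Gaussian system point-spread function and Poisson counting noise.  No
projection-space physics is modelled — the output stands in for an already
reconstructed, attenuation-corrected volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from scipy import ndimage

from .calibration import CalibrationModel, reference_calibration

__all__ = [
    "GridSpec",
    "Sphere",
    "Cylinder",
    "PhantomSpec",
    "ActivityVolume",
    "sphere_for_volume",
    "rasterize_phantom",
    "apply_system_blur",
    "add_poisson_noise",
    "generate_phantom_series",
    "default_grid",
    "DEFAULT_FWHM_MM",
    "DEFAULT_VOLUME_RANGES",
    "DEFAULT_RANGE_VOLUMES_ML",
    "DEFAULT_CONCENTRATIONS_UCI_PER_ML",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.3548

#: Reconstruction-space grid matching a 128x128 clinical acquisition matrix
#: at zoom 1.5 (3.3 mm isotropic voxels).
DEFAULT_SHAPE = (128, 128, 128)
DEFAULT_SPACING_MM = (3.3, 3.3, 3.3)
DEFAULT_FWHM_MM = 10.0

#: The three standardization volume ranges (mL).
DEFAULT_VOLUME_RANGES = ((6.0, 30.0), (500.0, 1500.0), (2400.0, 3200.0))
#: Default insert volumes covering each range.
DEFAULT_RANGE_VOLUMES_ML = (
    (6.0, 12.0, 20.0, 30.0),
    (500.0, 1000.0, 1500.0),
    (2400.0, 2800.0, 3200.0),
)
#: Concentration span 28.5-151.33 kBq/mL expressed in canonical uCi/mL.
DEFAULT_CONCENTRATIONS_UCI_PER_ML = (28.5 / 37.0, 74.0 / 37.0, 151.33 / 37.0)


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid geometry: shape (voxels per axis) and spacing (mm/voxel)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("GridSpec is 3-D: shape and spacing need 3 entries")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError("grid shape entries must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacings must be > 0")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_mL(self) -> float:
        """Voxel volume in mL (1 mL = 1000 mm^3)."""
        return self.spacing[0] * self.spacing[1] * self.spacing[2] / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center_mm(self) -> tuple[float, float, float]:
        return tuple(e / 2.0 for e in self.extent_mm)

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        return (np.arange(self.shape[axis], dtype=float) + 0.5) * self.spacing[axis]


def default_grid() -> GridSpec:
    return GridSpec(DEFAULT_SHAPE, DEFAULT_SPACING_MM)


@dataclass(frozen=True)
class Sphere:
    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("sphere radius must be > 0")

    @property
    def volume_mL(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_mm**3 / 1000.0

    def bounds_mm(self) -> list[tuple[float, float]]:
        return [(c - self.radius_mm, c + self.radius_mm) for c in self.center_mm]

    def contains(self, zz, yy, xx):
        cz, cy, cx = self.center_mm
        return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius_mm**2


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned circular cylinder (axis along the first grid axis)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.height_mm <= 0:
            raise ValueError("cylinder radius and height must be > 0")

    @property
    def volume_mL(self) -> float:
        return math.pi * self.radius_mm**2 * self.height_mm / 1000.0

    def bounds_mm(self) -> list[tuple[float, float]]:
        cz, cy, cx = self.center_mm
        return [
            (cz - self.height_mm / 2.0, cz + self.height_mm / 2.0),
            (cy - self.radius_mm, cy + self.radius_mm),
            (cx - self.radius_mm, cx + self.radius_mm),
        ]

    def contains(self, zz, yy, xx):
        cz, cy, cx = self.center_mm
        radial = (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius_mm**2
        axial = np.abs(zz - cz) <= self.height_mm / 2.0
        return radial & axial


def sphere_for_volume(volume_mL: float,
                      center_mm: tuple[float, float, float]) -> Sphere:
    """Sphere of the requested volume: r = (3V/4pi)^(1/3)."""
    if volume_mL <= 0:
        raise ValueError("volume must be > 0")
    radius = (3.0 * volume_mL * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return Sphere(center_mm=center_mm, radius_mm=radius)


@dataclass(frozen=True)
class PhantomSpec:
    """Ground truth for one hot insert.

    Concentrations are in canonical uCi/mL.  ``true_volume_mL`` must agree
    with the analytic volume of the geometry to better than 0.1%.
    """

    geometry: Sphere | Cylinder
    concentration: float
    background_concentration: float = 0.0
    true_volume_mL: float | None = None

    def __post_init__(self) -> None:
        analytic = self.geometry.volume_mL
        if self.true_volume_mL is None:
            object.__setattr__(self, "true_volume_mL", analytic)
        elif abs(self.true_volume_mL - analytic) > 1e-3 * analytic:
            raise ValueError(
                f"true_volume_mL {self.true_volume_mL:.4f} inconsistent with analytic "
                f"geometry volume {analytic:.4f} mL (>0.1%)"
            )
        if self.background_concentration < 0:
            raise ValueError("background concentration must be >= 0")
        if self.concentration < self.background_concentration:
            raise ValueError("insert concentration must be >= background")

    def to_dict(self) -> dict:
        g = self.geometry
        geom = {"kind": type(g).__name__.lower(), "center_mm": list(g.center_mm),
                "radius_mm": g.radius_mm}
        if isinstance(g, Cylinder):
            geom["height_mm"] = g.height_mm
        return {
            "geometry": geom,
            "true_volume_mL": self.true_volume_mL,
            "concentration_uCi_per_mL": self.concentration,
            "background_concentration_uCi_per_mL": self.background_concentration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        g = d["geometry"]
        if g["kind"] == "sphere":
            geom: Sphere | Cylinder = Sphere(tuple(g["center_mm"]), g["radius_mm"])
        elif g["kind"] == "cylinder":
            geom = Cylinder(tuple(g["center_mm"]), g["radius_mm"], g["height_mm"])
        else:
            raise ValueError(f"unknown geometry kind {g['kind']!r}")
        return cls(
            geometry=geom,
            concentration=d["concentration_uCi_per_mL"],
            background_concentration=d.get("background_concentration_uCi_per_mL", 0.0),
            true_volume_mL=d.get("true_volume_mL"),
        )


@dataclass
class ActivityVolume:
    """A reconstructed count map: voxel grid plus per-voxel counts."""

    grid: GridSpec
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite")
        if self.values.min() < 0:
            raise ValueError("activity values must be non-negative")

    @property
    def total_counts(self) -> float:
        return float(self.values.sum())


def _coordinate_grids(grid: GridSpec):
    z = grid.axis_centers_mm(0)[:, None, None]
    y = grid.axis_centers_mm(1)[None, :, None]
    x = grid.axis_centers_mm(2)[None, None, :]
    return z, y, x


def rasterize_phantom(spec: PhantomSpec, grid: GridSpec,
                      forward_model: CalibrationModel | None = None) -> ActivityVolume:
    """Paint a noiseless, unblurred count map of one phantom insert.

    Voxels whose *centers* fall inside the geometry get the count density of
    the insert concentration under the forward model; all other voxels get
    the background's.  Partial-volume effects come later from the blur step,
    not from sub-voxel weighting.
    """
    if forward_model is None:
        forward_model = reference_calibration()
    axis_names = ("z", "y", "x")
    for ax, (lo, hi) in enumerate(spec.geometry.bounds_mm()):
        if lo < 0 or hi > grid.extent_mm[ax]:
            raise ValueError(
                f"phantom geometry exceeds grid extent on axis {axis_names[ax]}: "
                f"[{lo:.1f}, {hi:.1f}] mm vs [0, {grid.extent_mm[ax]:.1f}] mm"
            )
    zz, yy, xx = _coordinate_grids(grid)
    inside = spec.geometry.contains(zz, yy, xx)
    vox_cc = grid.voxel_volume_mL  # 1 cc == 1 mL
    hot = float(forward_model.predict_counts(spec.concentration)) * vox_cc
    bg = float(forward_model.predict_counts(spec.background_concentration)) * vox_cc
    values = np.where(inside, hot, bg)
    return ActivityVolume(grid=grid, values=values,
                          meta={"fwhm_mm": 0.0, "noise": False, "seed": None})


def apply_system_blur(vol: ActivityVolume, fwhm_mm: float) -> ActivityVolume:
    """Convolve with the isotropic Gaussian system PSF (reflective boundaries).

    sigma = fwhm / 2.3548 per axis, expressed in voxels through the grid
    spacing.  Reflection padding keeps total counts conserved to <0.1%.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return ActivityVolume(vol.grid, vol.values.copy(), dict(vol.meta))
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in vol.grid.spacing]
    blurred = ndimage.gaussian_filter(vol.values, sigma=sigma_vox, mode="reflect")
    meta = dict(vol.meta)
    meta["fwhm_mm"] = fwhm_mm
    return ActivityVolume(vol.grid, np.clip(blurred, 0.0, None), meta)


def add_poisson_noise(vol: ActivityVolume, seed: int) -> ActivityVolume:
    """Replace each voxel by a Poisson draw with that voxel as its mean."""
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(vol.values).astype(np.float64)
    meta = dict(vol.meta)
    meta.update(noise=True, seed=int(seed))
    return ActivityVolume(vol.grid, noisy, meta)


def generate_phantom_series(
    volumes_mL: Sequence[float],
    concentrations: Sequence[float],
    grid: GridSpec | None = None,
    fwhm_mm: float = DEFAULT_FWHM_MM,
    noise: bool = True,
    seed: int = 0,
    background_concentration: float = 0.0,
    forward_model: CalibrationModel | None = None,
) -> list[tuple[PhantomSpec, ActivityVolume]]:
    """Simulate one spherical insert per (volume, concentration) pair.

    The Cartesian product of ``volumes_mL`` and ``concentrations`` is taken;
    each insert is centered in the grid, blurred with the system PSF and
    (optionally) degraded with Poisson noise using per-phantom child seeds so
    the series is reproducible as a whole.
    """
    if len(volumes_mL) == 0 or len(concentrations) == 0:
        raise ValueError("volumes and concentrations must be non-empty")
    if grid is None:
        grid = default_grid()
    if forward_model is None:
        forward_model = reference_calibration()
    pairs = list(product(volumes_mL, concentrations))
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   np.random.SeedSequence(seed).spawn(len(pairs))]
    series: list[tuple[PhantomSpec, ActivityVolume]] = []
    for (vol_mL, conc), child in zip(pairs, child_seeds):
        spec = PhantomSpec(
            geometry=sphere_for_volume(vol_mL, grid.center_mm),
            concentration=conc,
            background_concentration=background_concentration,
        )
        av = rasterize_phantom(spec, grid, forward_model)
        av = apply_system_blur(av, fwhm_mm)
        if noise:
            av = add_poisson_noise(av, child)
        series.append((spec, av))
    return series
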