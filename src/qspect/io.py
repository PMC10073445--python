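"""NIfTI volume I/O, run configuration and provenance stamping.

Volumes are exchanged as NIfTI-1 with the voxel spacing in the header and
counts stored as 32-bit float; masks as uint8.  Every pipeline artifact
embeds a provenance record (configuration hash, seed, package version) so a
run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import ActivityVolume, GridSpec

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "RunConfig",
    "provenance",
]


def write_volume(vol: ActivityVolume, path: str | Path) -> None:
    """Write counts as float32 NIfTI with spacing in the header."""
    affine = np.diag([*vol.grid.spacing, 1.0])
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    affine = np.diag([*grid.spacing, 1.0])
    img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ActivityVolume:
    """Read a 3-D NIfTI count map; rejects non-3-D data and bad spacings."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {data.ndim}-D: {path}")
    zooms = img.header.get_zooms()[:3]
    if any((z is None) or (z <= 0) for z in zooms):
        raise ValueError(f"missing or non-positive voxel spacing in {path}")
    grid = GridSpec(shape=tuple(data.shape), spacing=tuple(float(z) for z in zooms))
    return ActivityVolume(grid=grid, values=np.asarray(data, dtype=np.float64))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips through JSON."""

    seed: int = 0
    decay_correction: bool = True
    threshold_min: float = 19.0
    threshold_max: float = 52.0
    threshold_step: float = 1.0
    calibration_threshold_pct: float = 38.0
    volume_ranges: list = field(default_factory=lambda: [[6.0, 30.0], [500.0, 1500.0], [2400.0, 3200.0]])
    range_volumes_mL: list = field(default_factory=lambda: [
        [6.0, 12.0, 20.0, 30.0], [500.0, 1000.0, 1500.0], [2400.0, 2800.0, 3200.0]])
    concentrations_uCi_per_mL: list = field(default_factory=lambda: [28.5 / 37.0, 74.0 / 37.0, 151.33 / 37.0])
    fwhm_mm: float = 10.0
    noise: bool = True
    cohort_n: int = 109
    cohort_preset: str = "table3_followup"
    verbosity: int = 1

    def thresholds(self) -> np.ndarray:
        return np.arange(self.threshold_min, self.threshold_max + self.threshold_step / 2,
                         self.threshold_step)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def provenance(config: RunConfig) -> dict:
    from . import __version__
    return {"config_hash": config.hash(), "seed": config.seed, "version": __version__}
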