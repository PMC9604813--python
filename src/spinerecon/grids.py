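"""Occupancy grids: cubic voxel label/probability volumes in world space."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import GridSpec

__all__ = ["OccupancyGrid"]


@dataclass(frozen=True)
class OccupancyGrid:
    """Probabilities (or binary labels) on a cubic world-embedded grid.

    ``values[i, j, k]`` corresponds to world point
    ``grid.origin + grid.spacing * (i, j, k)``.
    """

    values: np.ndarray
    grid: GridSpec
    binary: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        r = self.grid.resolution
        if v.shape != (r, r, r):
            raise ValueError(f"values shape {v.shape} does not match grid {r}")
        if self.binary:
            v = v.astype(bool)
        else:
            v = v.astype(np.float32)
            if v.min() < 0 or v.max() > 1:
                raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def binarize(self, threshold: float = 0.5) -> "OccupancyGrid":
        return OccupancyGrid(self.values >= threshold, self.grid, binary=True)

    def occupancy_fraction(self) -> float:
        return float(np.count_nonzero(self.values >= 0.5) / self.values.size)

    def _affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.eye(3) * self.grid.spacing
        aff[:3, 3] = self.grid.origin
        return aff

    def save(self, path: str | Path) -> None:
        data = self.values.astype(np.uint8 if self.binary else np.float32)
        img = nib.Nifti1Image(data, self._affine())
        img.header["descrip"] = f"res={self.grid.resolution};sp={self.grid.spacing:.6g}"
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "OccupancyGrid":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = float(np.abs(img.affine[0, 0]))
        origin = tuple(img.affine[:3, 3])
        spec = GridSpec(data.shape[0], origin, spacing)
        if data.dtype == np.uint8:
            return cls(data.astype(bool), spec, binary=True)
        return cls(data.astype(np.float32), spec, binary=False)
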