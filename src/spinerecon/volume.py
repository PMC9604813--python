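"""3D attenuation volumes with optional per-vertebra label channels."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["AttenuationVolume"]


@dataclass(frozen=True)
class AttenuationVolume:
    """A scalar attenuation field on a regular grid in world mm.

    ``values[i, j, k]`` lives at world position ``origin + spacing * (i, j, k)``
    (axes x, y, z); attenuation is per mm.  ``labels`` (if present) holds
    integer vertebra levels, 0 = background, aligned voxel-for-voxel.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("attenuation must be finite and non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape != v.shape:
                raise ValueError("labels must match values shape")
            object.__setattr__(self, "labels", lab.astype(np.int16))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def center(self) -> np.ndarray:
        """World position of the volume center."""
        return (np.asarray(self.origin)
                + (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0)

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin) - np.asarray(self.spacing) / 2.0
        hi = lo + np.asarray(self.shape) * np.asarray(self.spacing)
        return lo, hi

    def present_levels(self) -> list[int]:
        if self.labels is None:
            return []
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)

    def _affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def save(self, image_path: str | Path, label_path: str | Path | None = None) -> None:
        nib.save(nib.Nifti1Image(self.values, self._affine()), str(image_path))
        if label_path is not None and self.labels is not None:
            nib.save(nib.Nifti1Image(self.labels, self._affine()), str(label_path))

    @classmethod
    def load(cls, image_path: str | Path,
             label_path: str | Path | None = None) -> "AttenuationVolume":
        img = nib.load(str(image_path))
        aff = img.affine
        spacing = tuple(np.abs(np.diag(aff)[:3]))
        origin = tuple(aff[:3, 3])
        labels = None
        if label_path is not None:
            labels = np.asarray(nib.load(str(label_path)).dataobj)
        return cls(np.asarray(img.dataobj, dtype=np.float32), spacing, origin, labels)
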