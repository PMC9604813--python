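"""Pinhole projection geometry for calibrated X-ray views.

A calibrated radiograph is described by a 3x4 projection matrix

    P = K R [I | -t]

with intrinsics ``K`` (focal length in pixels, principal point), a
world-to-camera rotation ``R`` and the camera (X-ray source) center ``t``
in world millimetres.  Cropping a radiograph to a vertebral bounding box
shifts pixel coordinates by the crop corner ``(tx, ty)``; the adjusted
matrix is ``P_hat = Q P`` where ``Q`` is the unit upper-triangular pixel
shift.  Reconstruction grids are cubic voxel lattices embedded in world
space through a :class:`GridSpec`.

Conventions: pixels are 0-based with centers on integer coordinates and
the origin at the top-left; the world frame is right-handed, in mm, with
the patient supine and +z pointing toward the head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Intrinsics",
    "Extrinsics",
    "CropOffset",
    "ProjectionMatrix",
    "GridSpec",
    "InvalidExtrinsicsError",
    "PointAtInfinityError",
    "compose_projection",
    "adjust_for_crop",
    "scale_pixels",
    "project_point",
    "project_points",
    "world_from_grid_index",
    "grid_index_from_world",
    "perturb_focal",
]


class InvalidExtrinsicsError(ValueError):
    """Rotation is not a proper orthonormal matrix."""


class PointAtInfinityError(ValueError):
    """Homogeneous w of a projected point is numerically zero."""


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics: focal length and principal point in pixels."""

    focal_length: float
    principal_point: tuple[float, float] = (112.0, 112.0)
    image_size: tuple[int, int] = (224, 224)

    def __post_init__(self) -> None:
        if not self.focal_length > 0:
            raise ValueError("focal_length must be positive")
        w, h = self.image_size
        px, py = self.principal_point
        if not (0 <= px < w and 0 <= py < h):
            raise ValueError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        f = self.focal_length
        px, py = self.principal_point
        return np.array([[f, 0.0, px], [0.0, f, py], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class Extrinsics:
    """Camera pose: world-to-camera rotation and source center (mm)."""

    rotation: np.ndarray
    camera_center: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.camera_center, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidExtrinsicsError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise InvalidExtrinsicsError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise InvalidExtrinsicsError("rotation determinant must be +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "camera_center", t)


@dataclass(frozen=True)
class CropOffset:
    """Top-left corner (pixels) of a bounding-box crop in the full image."""

    tx: float
    ty: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tx) and np.isfinite(self.ty)):
            raise ValueError("crop offsets must be finite")

    @property
    def Q(self) -> np.ndarray:
        return np.array(
            [[1.0, 0.0, -self.tx], [0.0, 1.0, -self.ty], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class ProjectionMatrix:
    """A 3x4 projection matrix with optional calibration provenance."""

    P: np.ndarray
    intrinsics: Intrinsics | None = None
    extrinsics: Extrinsics | None = None
    crop: CropOffset | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (3, 4):
            raise ValueError("P must be 3x4")
        if np.linalg.matrix_rank(P) != 3:
            raise ValueError("P must have rank 3")
        object.__setattr__(self, "P", P)

    @property
    def has_provenance(self) -> bool:
        return self.intrinsics is not None and self.extrinsics is not None

    @property
    def source(self) -> np.ndarray:
        """World position of the X-ray source (camera center)."""
        if self.extrinsics is not None:
            return self.extrinsics.camera_center
        # null space of P: P [c; 1] = 0
        _, _, vt = np.linalg.svd(self.P)
        c = vt[-1]
        if abs(c[3]) < 1e-12:
            raise ValueError("camera center at infinity")
        return c[:3] / c[3]

    def to_json(self) -> str:
        d: dict = {"P": self.P.tolist()}
        if self.intrinsics is not None:
            d["K"] = self.intrinsics.K.tolist()
            d["image_size"] = list(self.intrinsics.image_size)
        if self.extrinsics is not None:
            d["R"] = self.extrinsics.rotation.tolist()
            d["t"] = self.extrinsics.camera_center.tolist()
        if self.crop is not None:
            d["crop"] = [self.crop.tx, self.crop.ty]
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ProjectionMatrix":
        d = json.loads(text)
        intr = extr = crop = None
        if "K" in d:
            K = np.asarray(d["K"], dtype=float)
            size = tuple(d.get("image_size", (224, 224)))
            intr = Intrinsics(float(K[0, 0]), (float(K[0, 2]), float(K[1, 2])), size)
        if "R" in d and "t" in d:
            extr = Extrinsics(np.asarray(d["R"], float), np.asarray(d["t"], float))
        if "crop" in d:
            crop = CropOffset(*d["crop"])
        return cls(np.asarray(d["P"], float), intr, extr, crop)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ProjectionMatrix":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class GridSpec:
    """Cubic reconstruction grid embedded in world space.

    ``origin`` is the world position (mm) of the *center* of voxel
    (0, 0, 0); ``spacing`` is isotropic in mm per voxel.
    """

    resolution: int
    origin: tuple[float, float, float]
    spacing: float

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def side_length(self) -> float:
        """Physical side length of the grid cube in mm."""
        return self.resolution * self.spacing

    @property
    def center(self) -> np.ndarray:
        o = np.asarray(self.origin)
        return o + (self.resolution - 1) * self.spacing / 2.0

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (res**3, 3).

        Ordering is C order over index (i, j, k) -> (x, y, z).
        """
        r = self.resolution
        idx = np.stack(
            np.meshgrid(np.arange(r), np.arange(r), np.arange(r), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return np.asarray(self.origin) + self.spacing * idx

    @classmethod
    def around_center(cls, center, side_length: float, resolution: int) -> "GridSpec":
        spacing = side_length / resolution
        c = np.asarray(center, dtype=float)
        origin = c - side_length / 2.0 + spacing / 2.0
        return cls(resolution, tuple(origin), spacing)

    def to_dict(self) -> dict:
        return {
            "resolution": self.resolution,
            "origin": list(self.origin),
            "spacing": self.spacing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(int(d["resolution"]), tuple(d["origin"]), float(d["spacing"]))


def compose_projection(K: Intrinsics, E: Extrinsics) -> ProjectionMatrix:
    """Compose P = K R [I | -t] from intrinsics and extrinsics."""
    Rt = np.hstack([np.eye(3), -E.camera_center.reshape(3, 1)])
    P = K.K @ E.rotation @ Rt
    return ProjectionMatrix(P, intrinsics=K, extrinsics=E)


def adjust_for_crop(P: ProjectionMatrix, c: CropOffset) -> ProjectionMatrix:
    """Apply the pixel-shift homography for a crop: P_hat = Q P.

    Pixels under the returned matrix equal pixels under ``P`` minus
    ``(tx, ty)``.  Successive adjustments add their offsets.
    """
    prev = P.crop
    total = CropOffset(c.tx + (prev.tx if prev else 0.0), c.ty + (prev.ty if prev else 0.0))
    return ProjectionMatrix(c.Q @ P.P, P.intrinsics, P.extrinsics, total)


def scale_pixels(P: ProjectionMatrix, sx: float, sy: float | None = None,
                 offset: tuple[float, float] = (0.0, 0.0)) -> ProjectionMatrix:
    """Left-multiply by an affine pixel scaling ``u' = s*u + offset``.

    Used when an image is resized: for a resize by factor ``s`` with the
    pixel-centers-on-integers convention the exact mapping is
    ``u' = (u + 0.5) * s - 0.5``, i.e. ``offset = (s - 1) / 2``.
    """
    if sy is None:
        sy = sx
    S = np.array([[sx, 0.0, offset[0]], [0.0, sy, offset[1]], [0.0, 0.0, 1.0]])
    return ProjectionMatrix(S @ P.P, P.intrinsics, P.extrinsics, P.crop)


def project_point(P: ProjectionMatrix, X) -> tuple[np.ndarray, bool]:
    """Project one world point; returns (pixel, in_front_of_camera)."""
    Xh = np.append(np.asarray(X, dtype=float).reshape(3), 1.0)
    x = P.P @ Xh
    if abs(x[2]) < 1e-12:
        raise PointAtInfinityError("projected point at infinity")
    return x[:2] / x[2], bool(x[2] > 0)


def project_points(P: ProjectionMatrix, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized projection of (n, 3) world points.

    Returns (pixels (n, 2), depth w (n,)); points with w <= 0 are behind
    the camera and their pixel coordinates are not meaningful.
    """
    X = np.asarray(X, dtype=float).reshape(-1, 3)
    x = X @ P.P[:, :3].T + P.P[:, 3]
    w = x[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        pix = x[:, :2] / w[:, None]
    return pix, w


def world_from_grid_index(g: GridSpec, idx) -> np.ndarray:
    """World coordinates (mm) of the center of voxel ``idx``."""
    idx = np.asarray(idx)
    if np.any(idx < 0) or np.any(idx >= g.resolution):
        raise IndexError(f"grid index {idx} out of range for resolution {g.resolution}")
    return np.asarray(g.origin) + g.spacing * idx


def perturb_focal(P: ProjectionMatrix, delta: float) -> ProjectionMatrix:
    """Recompose a (possibly cropped/rescaled) matrix with focal f + delta.

    Emulates a calibration error: the accumulated pixel-space transform
    (crop shift, resize) is recovered from the stored matrix and
    reapplied on top of intrinsics with the perturbed focal length.
    ``delta = 0`` returns ``P`` unchanged.
    """
    if delta == 0:
        return P
    if not P.has_provenance:
        raise ValueError("perturbation requires calibration provenance")
    K, E = P.intrinsics, P.extrinsics
    base = compose_projection(K, E)
    A = P.P[:, :3] @ np.linalg.inv(base.P[:, :3])
    K2 = Intrinsics(K.focal_length + delta, K.principal_point, K.image_size)
    P2 = compose_projection(K2, E)
    return ProjectionMatrix(A @ P2.P, K2, E, P.crop)


def grid_index_from_world(g: GridSpec, X) -> np.ndarray:
    """Inverse of :func:`world_from_grid_index` (nearest voxel index)."""
    X = np.asarray(X, dtype=float)
    return np.rint((X - np.asarray(g.origin)) / g.spacing).astype(int)
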