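"""Procedural lumbar-spine phantoms with per-vertebra labels.

Each phantom is a CT-like attenuation volume containing five stacked
vertebra-like bodies embedded in a soft-tissue torso.  A vertebra is
built from simple solids in its local frame:

* an elliptic-cylinder body with a denser cortical shell,
* a posterior ring (pedicles/lamina) with a spinal-canal hole,
* one spinous process and two transverse processes.

All bone voxels of one level share a single label (1..n_levels) and
form one connected component.  Geometry is drawn per level from
configurable ranges so that every seed yields a different spine.

The module also implements the elastic augmentation used for training:
a dense displacement field interpolated with cubic B-splines from a
coarse 6x6x6 control grid whose control points are displaced by up to
18 voxels, applied to the 3D volume before radiograph rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import AttenuationVolume

__all__ = ["PhantomConfig", "DeformationSpec", "make_phantom", "elastic_deform"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and attenuation ranges for one phantom draw.

    Lengths are mm; attenuations are linear coefficients per mm,
    roughly matching water (~0.02/mm) and cortical bone (~0.06/mm)
    at fluoroscopy energies.
    """

    n_levels: int = 5
    shape: tuple[int, int, int] = (144, 144, 224)
    spacing: float = 0.9
    body_radius_range: tuple[float, float] = (14.0, 19.0)
    body_height_range: tuple[float, float] = (20.0, 26.0)
    canal_radius_range: tuple[float, float] = (4.5, 6.5)
    process_length_range: tuple[float, float] = (16.0, 26.0)
    disc_gap: float = 5.0
    attenuation_bone: float = 0.06
    attenuation_soft_tissue: float = 0.02
    trabecular_fraction: float = 0.55
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.attenuation_bone > self.attenuation_soft_tissue > 0):
            raise ValueError("need bone attenuation > soft tissue attenuation > 0")
        for rng in (self.body_radius_range, self.body_height_range,
                    self.canal_radius_range, self.process_length_range):
            if not (0 < rng[0] <= rng[1]):
                raise ValueError(f"invalid range {rng}")

    def validate_fit(self) -> None:
        """Raise if the tallest possible spine cannot fit in the volume."""
        z_extent = self.shape[2] * self.spacing
        needed = self.n_levels * (self.body_height_range[1] + self.disc_gap) + 10.0
        if needed > z_extent:
            raise ValueError(
                f"levels would overlap or overflow: need {needed:.0f} mm, "
                f"volume is {z_extent:.0f} mm along z"
            )


@dataclass(frozen=True)
class DeformationSpec:
    """Coarse-grid B-spline elastic deformation.

    ``control_points`` per axis (default 6); each control point is
    displaced per axis by a random amount in [0, max_displacement]
    voxels; the dense field is the cubic-spline interpolation of the
    control grid.
    """

    control_points: int = 6
    max_displacement: float = 18.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.max_displacement:
            raise ValueError("max_displacement must be >= 0")
        if self.control_points < 4:
            raise ValueError("cubic splines need >= 4 control points")


def _ellipse_mask(xx, yy, cx, cy, rx, ry):
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _vertebra_masks(xx, yy, zz, z_center, p):
    """Boolean (bone, canal) masks of one vertebra in world mm coords.

    Local frame: x left-right, y anterior(-)->posterior(+), z caudal->cranial.
    """
    half_h = p["height"] / 2.0
    in_slab = np.abs(zz - z_center) <= half_h
    thin_slab = np.abs(zz - z_center) <= half_h * 0.55

    rx, ry = p["radius"], p["radius"] * 0.82
    body = _ellipse_mask(xx, yy, 0.0, -6.0, rx, ry) & in_slab

    cr = p["canal_radius"]
    # posterior ring overlaps the body by 3 mm so the vertebra is connected
    y0 = ry - 9.0
    ring_cy = y0 + cr + 3.5
    ring_out = _ellipse_mask(xx, yy, 0.0, ring_cy, cr + 3.5, cr + 3.5)
    canal = _ellipse_mask(xx, yy, 0.0, ring_cy, cr, cr) & ~body
    ring = ring_out & ~canal & in_slab

    y_ring_back = y0 + 2 * cr + 7.0
    spinous = (
        (np.abs(xx) <= 3.5)
        & (yy >= y_ring_back - 4.0)
        & (yy <= y_ring_back + p["process_length"])
        & thin_slab
    )
    transverse = (
        (np.abs(yy - ring_cy) <= 3.5)
        & (np.abs(xx) <= cr + 4.0 + p["process_length"] * 0.8)
        & ~_ellipse_mask(xx, yy, 0.0, ring_cy, cr, cr)
        & thin_slab
    )
    bone = body | ring | spinous | transverse
    return bone, (canal & in_slab) & ~bone


def make_phantom(cfg: PhantomConfig) -> AttenuationVolume:
    """Generate one seeded phantom volume with per-level labels."""
    cfg.validate_fit()
    rng = np.random.default_rng(cfg.rng_seed)
    nx, ny, nz = cfg.shape
    sp = cfg.spacing
    # world origin at the volume center
    origin = -np.array([nx - 1, ny - 1, nz - 1]) * sp / 2.0
    xs = origin[0] + sp * np.arange(nx)
    ys = origin[1] + sp * np.arange(ny)
    zs = origin[2] + sp * np.arange(nz)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")

    values = np.zeros(cfg.shape, dtype=np.float32)
    labels = np.zeros(cfg.shape, dtype=np.int16)

    # soft-tissue torso: elliptic cylinder filling most of the cross-section
    torso = _ellipse_mask(xx, yy, 0.0, 0.0, xs[-1] * 0.92, ys[-1] * 0.85)
    values[torso, :] = cfg.attenuation_soft_tissue

    pitch_budget = nz * sp - 10.0
    pitch = min(cfg.body_height_range[1] + cfg.disc_gap,
                pitch_budget / cfg.n_levels)
    z0 = -(cfg.n_levels - 1) * pitch / 2.0
    zz3 = zs[None, None, :]
    xx3 = xx[:, :, None]
    yy3 = yy[:, :, None]
    for level in range(1, cfg.n_levels + 1):
        p = {
            "radius": rng.uniform(*cfg.body_radius_range),
            "height": min(rng.uniform(*cfg.body_height_range), pitch - 2.0),
            "canal_radius": rng.uniform(*cfg.canal_radius_range),
            "process_length": rng.uniform(*cfg.process_length_range),
        }
        jitter = rng.uniform(-1.5, 1.5, size=2)
        z_center = z0 + (level - 1) * pitch
        bone, canal = _vertebra_masks(xx3 - jitter[0], yy3 - jitter[1], zz3,
                                      z_center, p)
        shell = bone & ~ndimage.binary_erosion(bone, iterations=2)
        values[bone] = cfg.attenuation_bone * cfg.trabecular_fraction
        values[shell] = cfg.attenuation_bone
        values[canal] = cfg.attenuation_soft_tissue * 0.5
        labels[bone] = level

    return AttenuationVolume(values, spacing=(sp, sp, sp),
                             origin=tuple(origin), labels=labels)


def elastic_deform(vol: AttenuationVolume, spec: DeformationSpec) -> AttenuationVolume:
    """Warp a volume (and its labels) by a smooth random displacement field.

    Displacements are drawn per control point and axis uniformly in
    [0, max_displacement] voxels on a coarse control grid and upsampled
    to a dense field with cubic spline interpolation; image values are
    pulled with trilinear interpolation, labels with nearest-neighbour,
    using the same field for both.
    """
    if min(vol.values.shape) < 8:
        raise ValueError("volume too small to deform")
    rng = np.random.default_rng(spec.rng_seed)
    shape = vol.values.shape
    n = spec.control_points
    coords = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                         indexing="ij")
    warped = list(coords)
    if spec.max_displacement > 0:
        for ax in range(3):
            ctrl = rng.uniform(0.0, spec.max_displacement, size=(n, n, n))
            zoom = [s / n for s in shape]
            dense = ndimage.zoom(ctrl, zoom, order=3, mode="nearest",
                                 grid_mode=True)
            warped[ax] = coords[ax] + dense
    values = ndimage.map_coordinates(vol.values, warped, order=1, mode="constant",
                                     cval=0.0).astype(np.float32)
    labels = None
    if vol.labels is not None:
        labels = ndimage.map_coordinates(vol.labels, warped, order=0,
                                         mode="constant", cval=0)
    return AttenuationVolume(values, spacing=vol.spacing, origin=vol.origin,
                             labels=labels)
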