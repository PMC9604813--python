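"""Reconstruction quality metrics.

Volume overlap (F1/Dice, IoU) on binary occupancy grids, and surface
metrics computed between meshes extracted from prediction and ground
truth: the surface score

    S(d) = 2 * Precision(d) * Recall(d) / (Precision(d) + Recall(d)),

where Precision(d) is the fraction of predicted-surface sample points
whose nearest ground-truth point lies closer than d (strict inequality)
and Recall(d) the converse, with d defaulting to 1% of the
reconstruction-volume side length; plus the robust 95th-percentile
Hausdorff distance (HD95) and the average surface distance (ASD) over
the pooled symmetric nearest-neighbour distances, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage import measure

from .grids import OccupancyGrid

__all__ = [
    "SurfacePoints",
    "MetricsReport",
    "overlap_scores",
    "occupancy_to_mesh",
    "sample_surface",
    "surface_precision",
    "surface_recall",
    "surface_score",
    "distance_scores",
    "compare_grids",
    "perturb_focal_sweep",
    "export_distance_colored_mesh",
    "DEFAULT_SURFACE_POINTS",
]

DEFAULT_SURFACE_POINTS = 10_000


@dataclass(frozen=True)
class SurfacePoints:
    """Points sampled uniformly by area from one mesh surface."""

    points: np.ndarray  # (n, 3) world mm
    source: str  # "R" (prediction) or "G" (ground truth)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(pts) < 1:
            raise ValueError("need at least one surface point")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class MetricsReport:
    """All scores for one reconstruction; distances in mm."""

    f1: float
    iou: float
    precision_d: float
    recall_d: float
    surface_score: float
    hd95: float
    asd: float
    d: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def overlap_scores(pred: OccupancyGrid, gt: OccupancyGrid) -> tuple[float, float]:
    """(F1, IoU) of two binary grids; two empty grids score 1."""
    if pred.values.shape != gt.values.shape:
        raise ValueError("grid shapes differ")
    p = pred.values >= 0.5 if not pred.binary else pred.values
    g = gt.values >= 0.5 if not gt.binary else gt.values
    tp = np.count_nonzero(p & g)
    fp = np.count_nonzero(p & ~g)
    fn = np.count_nonzero(~p & g)
    if tp + fp + fn == 0:
        return 1.0, 1.0
    f1 = 2 * tp / (2 * tp + fp + fn)
    iou = tp / (tp + fp + fn)
    return float(f1), float(iou)


def occupancy_to_mesh(grid: OccupancyGrid) -> trimesh.Trimesh:
    """Extract the iso-0.5 surface as a triangle mesh in world mm.

    The grid is zero-padded by one voxel so surfaces touching the grid
    boundary close up (watertight solids for solid occupancies).
    """
    vol = grid.values.astype(np.float32)
    if not np.any(vol >= 0.5):
        raise ValueError("empty occupancy grid has no surface")
    padded = np.pad(vol, 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * grid.grid.spacing + np.asarray(grid.grid.origin)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def sample_surface(mesh: trimesh.Trimesh, n_points: int,
                   rng_seed: int = 0, source: str = "R") -> SurfacePoints:
    """Area-uniform random points on a mesh surface (seeded)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(rng_seed)
    areas = mesh.area_faces
    probs = areas / areas.sum()
    face_idx = rng.choice(len(areas), size=n_points, p=probs)
    tri = mesh.triangles[face_idx]
    r1 = np.sqrt(rng.random(n_points))
    r2 = rng.random(n_points)
    pts = ((1 - r1)[:, None] * tri[:, 0]
           + (r1 * (1 - r2))[:, None] * tri[:, 1]
           + (r1 * r2)[:, None] * tri[:, 2])
    return SurfacePoints(pts, source)


def _nn_dists(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    return cKDTree(dst).query(src)[0]


def surface_precision(R: SurfacePoints, G: SurfacePoints, d: float) -> float:
    """Fraction of prediction points within (strictly) d of the target."""
    return float(np.mean(_nn_dists(R.points, G.points) < d))


def surface_recall(R: SurfacePoints, G: SurfacePoints, d: float) -> float:
    """Fraction of target points within (strictly) d of the prediction."""
    return float(np.mean(_nn_dists(G.points, R.points) < d))


def surface_score(R: SurfacePoints, G: SurfacePoints, d: float) -> float:
    """Harmonic mean of surface precision and recall at threshold d."""
    p = surface_precision(R, G, d)
    r = surface_recall(R, G, d)
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def distance_scores(R: SurfacePoints, G: SurfacePoints) -> tuple[float, float]:
    """(HD95, ASD) in mm over pooled bidirectional NN distances."""
    d_rg = _nn_dists(R.points, G.points)
    d_gr = _nn_dists(G.points, R.points)
    pooled = np.concatenate([d_rg, d_gr])
    return float(np.percentile(pooled, 95)), float(pooled.mean())


def compare_grids(
    pred: OccupancyGrid,
    gt: OccupancyGrid,
    d_fraction: float = 0.01,
    n_points: int = DEFAULT_SURFACE_POINTS,
    rng_seed: int = 0,
) -> MetricsReport:
    """Full metric suite between a predicted and a target grid.

    ``d_fraction`` sets the surface-score threshold as a fraction of the
    reconstruction volume's side length (default 1%).
    """
    f1, iou = overlap_scores(pred, gt)
    d = d_fraction * gt.grid.side_length
    pred_bin = pred if pred.binary else pred.binarize()
    if not np.any(pred_bin.values) or not np.any(gt.values >= 0.5):
        # no surface on one side: surface metrics degenerate
        big = gt.grid.side_length
        return MetricsReport(f1, iou, 0.0, 0.0, 0.0, big, big, d)
    mesh_r = occupancy_to_mesh(pred_bin)
    mesh_g = occupancy_to_mesh(gt)
    # same seed for both: identical meshes then yield identical samples,
    # so a perfect prediction scores exactly zero distance
    R = sample_surface(mesh_r, n_points, rng_seed, "R")
    G = sample_surface(mesh_g, n_points, rng_seed, "G")
    p = surface_precision(R, G, d)
    r = surface_recall(R, G, d)
    s = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    hd95, asd = distance_scores(R, G)
    return MetricsReport(f1, iou, p, r, s, hd95, asd, d)


def export_distance_colored_mesh(mesh: trimesh.Trimesh,
                                 other: SurfacePoints,
                                 path,
                                 d_max: float) -> np.ndarray:
    """Write a PLY with per-vertex distance-to-other-surface colouring.

    Each vertex is coloured on a green-to-red ramp by its nearest
    distance to the other surface's sample points, saturating (black)
    beyond ``d_max`` — a visual precision/recall map.  Returns the
    per-vertex distances.
    """
    dists = _nn_dists(mesh.vertices, other.points)
    frac = np.clip(dists / d_max, 0.0, 1.0)
    colors = np.zeros((len(dists), 4), dtype=np.uint8)
    colors[:, 0] = (255 * frac).astype(np.uint8)
    colors[:, 1] = (255 * (1 - frac)).astype(np.uint8)
    colors[:, 3] = 255
    colors[dists > d_max] = (0, 0, 0, 255)
    out = mesh.copy()
    out.visual.vertex_colors = colors
    out.export(path)
    return dists


def perturb_focal_sweep(
    model,
    samples,
    view_subset: str = "lateral",
    deltas=(0.0, 10.0, 20.0, 30.0, 40.0, 50.0),
    d_fraction: float = 0.01,
    n_points: int = 2000,
    rng_seed: int = 0,
) -> list[dict]:
    """Calibration-sensitivity sweep: perturb the focal length parameter.

    For each delta, the projection matrices of the chosen view category
    ("AP" or "lateral") are recomposed with focal length f + delta
    (images unchanged — a pure calibration error), reconstructions are
    recomputed and the mean metrics reported per delta.
    """
    from .geometry import perturb_focal

    wanted = {"AP": "AP", "lateral": "lateral"}.get(view_subset)
    if wanted is None:
        raise ValueError("view_subset must be 'AP' or 'lateral'")
    if not any(wanted == str(c.value) for s in samples for c in s.view_categories):
        raise ValueError(f"no {wanted} views present in the samples")
    curve = []
    for delta in deltas:
        f1s, scores = [], []
        for s in samples:
            p_hats = [
                perturb_focal(ph, delta) if str(c.value) == wanted else ph
                for ph, c in zip(s.p_hats, s.view_categories)
            ]
            _, binary = model.reconstruct(s.images, p_hats, s.grid)
            rep = compare_grids(binary, s.gt, d_fraction=d_fraction,
                                n_points=n_points, rng_seed=rng_seed)
            f1s.append(rep.f1)
            scores.append(rep.surface_score)
        curve.append({"delta": float(delta),
                      "f1": float(np.mean(f1s)),
                      "surface_score": float(np.mean(scores))})
    return curve
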