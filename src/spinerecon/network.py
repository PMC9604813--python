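"""Projection-geometry-aware multi-view reconstruction network.

The model follows the learnt-stereo-machine idea: a shared 2D encoder
turns each normalized vertebra crop into a feature map at half the
input resolution; every voxel of a world-embedded cubic grid is
projected into each view with its adjusted projection matrix and reads
its feature vector by differentiable bilinear interpolation; the
per-view feature grids are fused by an elementwise average (memory-
friendly replacement for recurrent fusion); a 3D UNet refiner turns the
fused grid into per-voxel occupancy logits, squashed by a sigmoid.

Default dimensions: 224x224 inputs, 32 feature maps of 112x112,
128^3 grids.  A ``desk`` preset scales everything down for CPU work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import GridSpec, ProjectionMatrix, project_points, scale_pixels
from .grids import OccupancyGrid

__all__ = [
    "ModelConfig",
    "Encoder2D",
    "Refiner3D",
    "ReconstructionNet",
    "backproject",
    "fuse_average",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_channels`` lists the contracting-path widths of the
    truncated 2D UNet (input has 1 channel); the expanding path stops
    one level above the input resolution and a 1x1 projection emits
    ``n_feature_channels`` maps.  ``refiner_channels`` lists the 3D UNet
    widths.  ``grid_resolution`` must be a power of two >= 16.
    """

    encoder_channels: tuple[int, ...] = (32, 64, 128, 256)
    refiner_channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    n_feature_channels: int = 32
    grid_resolution: int = 128
    input_size: int = 224
    rng_seed: int = 0

    def __post_init__(self) -> None:
        r = self.grid_resolution
        if r < 16 or (r & (r - 1)) != 0:
            raise ValueError("grid_resolution must be a power of two >= 16")
        depth = len(self.refiner_channels)
        if self.grid_resolution < 2 ** (depth - 1):
            raise ValueError("refiner too deep for the grid resolution")

    @classmethod
    def desk(cls, rng_seed: int = 0) -> "ModelConfig":
        """CPU-scale preset: 64^2 inputs, 32^3 grids, slimmer UNets."""
        return cls(
            encoder_channels=(16, 32, 64),
            refiner_channels=(8, 16, 32),
            grid_resolution=32,
            input_size=64,
            rng_seed=rng_seed,
        )

    @property
    def feature_size(self) -> int:
        return self.input_size // 2


def _he_conv(rng, cout, cin, k, ndim) -> tuple[Tensor, Tensor]:
    fan_in = cin * k**ndim
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                   size=(cout, cin) + (k,) * ndim).astype(np.float32)
    return Tensor(w, requires_grad=True), Tensor(np.zeros(cout, np.float32),
                                                 requires_grad=True)


class _ConvBlock:
    """conv-relu-conv-relu, shared between the 2D and 3D paths."""

    def __init__(self, rng, cin, cout, ndim):
        self.w1, self.b1 = _he_conv(rng, cout, cin, 3, ndim)
        self.w2, self.b2 = _he_conv(rng, cout, cout, 3, ndim)
        self.conv = ad.conv2d if ndim == 2 else ad.conv3d

    def __call__(self, x: Tensor) -> Tensor:
        x = ad.relu(self.conv(x, self.w1, self.b1))
        return ad.relu(self.conv(x, self.w2, self.b2))

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2]


class Encoder2D:
    """Truncated UNet: image (1, S, S) -> features (C_f, S/2, S/2)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = cfg.encoder_channels
        self.down = []
        cin = 1
        for c in ch:
            self.down.append(_ConvBlock(rng, cin, c, 2))
            cin = c
        # expanding path back to S/2 (one level above the input)
        self.up = []
        for i in range(len(ch) - 2, 0, -1):
            self.up.append(_ConvBlock(rng, ch[i + 1] + ch[i], ch[i], 2))
        self.wp, self.bp = _he_conv(rng, cfg.n_feature_channels, ch[1], 1, 0)
        self.wp.data = self.wp.data.reshape(cfg.n_feature_channels, ch[1])

    def __call__(self, image: np.ndarray) -> Tensor:
        s = self.cfg.input_size
        if image.shape != (s, s):
            raise ValueError(f"expected a {s}x{s} image, got {image.shape}")
        x = Tensor(image[None], requires_grad=False)
        skips = []
        for i, block in enumerate(self.down):
            x = block(x)
            if i < len(self.down) - 1:
                skips.append(x)
                x = ad.maxpool2d(x)
        for block, skip in zip(self.up, reversed(skips[1:])):
            x = ad.upsample2d(x)
            x = block(ad.concat([x, skip]))
        return ad.channel_proj(x, self.wp, self.bp)

    def parameters(self):
        ps = [p for blk in self.down + self.up for p in blk.parameters()]
        return ps + [self.wp, self.bp]


class Refiner3D:
    """3D UNet: fused grid (C_f, R, R, R) -> occupancy logits (R, R, R)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = cfg.refiner_channels
        self.down = []
        cin = cfg.n_feature_channels
        for c in ch:
            self.down.append(_ConvBlock(rng, cin, c, 3))
            cin = c
        self.up = []
        for i in range(len(ch) - 2, -1, -1):
            self.up.append(_ConvBlock(rng, ch[i + 1] + ch[i], ch[i], 3))
        self.wo, self.bo = _he_conv(rng, 1, ch[0], 1, 0)
        self.wo.data = self.wo.data.reshape(1, ch[0])

    def __call__(self, fused: Tensor) -> Tensor:
        x = fused
        skips = []
        for i, block in enumerate(self.down):
            x = block(x)
            if i < len(self.down) - 1:
                skips.append(x)
                x = ad.maxpool3d(x)
        for block, skip in zip(self.up, reversed(skips)):
            x = ad.upsample3d(x)
            x = block(ad.concat([x, skip]))
        logits = ad.channel_proj(x, self.wo, self.bo)
        return ad.reshape(logits, logits.shape[1:])

    def parameters(self):
        ps = [p for blk in self.down + self.up for p in blk.parameters()]
        return ps + [self.wo, self.bo]


def backproject(fmap: Tensor, p_hat_feat: ProjectionMatrix,
                grid: GridSpec, return_mask: bool = False):
    """Lift a 2D feature map into a world-embedded 3D feature grid.

    Every voxel center of ``grid`` is projected with ``p_hat_feat`` —
    a projection matrix already expressed at the feature-map pixel
    scale — and reads the bilinearly interpolated feature vector at the
    resulting continuous pixel.  Voxels behind the camera or outside
    the map receive zeros.  Differentiable with respect to ``fmap``.
    With ``return_mask`` also returns the in-frustum boolean grid.
    """
    pts = grid.voxel_centers()
    uv, depth = project_points(p_hat_feat, pts)
    valid = depth > 0
    uv = np.where(valid[:, None], uv, 0.0)
    feats = ad.bilinear_gather(fmap, uv, valid)
    r = grid.resolution
    out = ad.reshape(feats, (fmap.shape[0], r, r, r))
    if not return_mask:
        return out
    _, hf, wf = fmap.shape
    in_frame = (valid & (uv[:, 0] > -1) & (uv[:, 0] < wf)
                & (uv[:, 1] > -1) & (uv[:, 1] < hf))
    return out, in_frame.reshape(r, r, r)


def fuse_average(grids: list[Tensor],
                 masks: list[np.ndarray] | None = None) -> Tensor:
    """Elementwise mean of per-view feature grids (order-independent).

    By default out-of-frustum voxels contribute zeros to the average;
    passing per-view in-frustum ``masks`` switches to a masked mean
    over the views that actually see each voxel.
    """
    if not grids:
        raise ValueError("need at least one feature grid")
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValueError("feature grids must share one shape")
    if masks is not None:
        return ad.masked_mean_stack(grids, masks)
    return ad.mean_stack(grids)


class ReconstructionNet:
    """Encoder + back-projection + averaging fusion + refiner."""

    def __init__(self, cfg: ModelConfig | None = None):
        self.cfg = cfg or ModelConfig()
        rng = np.random.default_rng(self.cfg.rng_seed)
        self.encoder = Encoder2D(self.cfg, rng)
        self.refiner = Refiner3D(self.cfg, rng)

    # -- stages -----------------------------------------------------------
    def encode(self, image: np.ndarray) -> Tensor:
        """2D features of one normalized [0, 1] crop."""
        if image.min() < 0 or image.max() > 1:
            raise ValueError("input image must be normalized to [0, 1]")
        return self.encoder(np.asarray(image, dtype=np.float32))

    def feature_projection(self, p_hat: ProjectionMatrix) -> ProjectionMatrix:
        """Rescale an image-space P-hat to the half-resolution feature space."""
        s = self.cfg.feature_size / self.cfg.input_size
        return scale_pixels(p_hat, s, s)

    def forward(self, images, p_hats, grid: GridSpec) -> Tensor:
        """Occupancy logits for a set of calibrated views."""
        if len(images) != len(p_hats):
            raise ValueError("images and projection matrices must pair up")
        view_grids = []
        for img, ph in zip(images, p_hats):
            fmap = self.encode(img)
            view_grids.append(backproject(fmap, self.feature_projection(ph), grid))
        return self.refiner(fuse_average(view_grids))

    def refine(self, fused: Tensor) -> OccupancyGrid:
        """Run only the refiner; returns sigmoid probabilities."""
        logits = self.refiner(fused)
        probs = ad.sigmoid(logits).data
        r = probs.shape[0]
        spec = GridSpec(r, (0.0, 0.0, 0.0), 1.0)
        return OccupancyGrid(np.clip(probs, 1e-7, 1 - 1e-7), spec)

    def reconstruct(self, images, p_hats, grid: GridSpec,
                    threshold: float = 0.5) -> tuple[OccupancyGrid, OccupancyGrid]:
        """Full inference: probability grid plus its binarized copy."""
        logits = self.forward(images, p_hats, grid)
        probs = ad.sigmoid(logits).data
        prob_grid = OccupancyGrid(probs, grid)
        return prob_grid, prob_grid.binarize(threshold)

    # -- parameters & checkpoints ----------------------------------------
    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.refiner.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def save(self, path: str | Path) -> None:
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.cfg.__dict__.items()}
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez_compressed(path, config=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ReconstructionNet":
        with np.load(path, allow_pickle=False) as z:
            cfg_d = json.loads(str(z["config"]))
            cfg = ModelConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                 for k, v in cfg_d.items()})
            net = cls(cfg)
            for i, p in enumerate(net.parameters()):
                p.data = z[f"p{i}"].astype(np.float32)
        return net
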