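"""Seeded synthetic focal stacks with known all-in-focus ground truth.

A scene is a band-limited random texture overlaid with high-contrast arcs
and lines (mimicking angle structures) plus a smooth depth map receding
along the rows.  A focal stack is rendered by blurring the truth with a
depth-dependent Gaussian per plane — depth is discretized into bands and
each band blurred once per frame, which is fast and accurate for smooth
depth maps — then adding seeded Gaussian noise.  Everything is deterministic
per seed, so the generator doubles as a test fixture factory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import FocalStack, RGBImage, save_image

__all__ = ["SyntheticScene", "StackParams", "generate_scene", "render_focal_stack", "write_stack"]

#: Blur sigmas below this (in px) are rendered as no blur at all.
MIN_BLUR_SIGMA = 0.3


@dataclass
class SyntheticScene:
    """All-in-focus ground truth plus a depth map in [0, 1] (0 = foreground)."""

    truth: RGBImage
    depth: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.shape != (self.truth.height, self.truth.width):
            raise ValueError("depth map must match truth dimensions")
        if self.depth.min() < 0 or self.depth.max() > 1:
            raise ValueError("depth values must lie in [0, 1]")


@dataclass
class StackParams:
    """Rendering parameters for :func:`render_focal_stack`."""

    n_planes: int = 15
    blur_gain: float = 2.0
    noise_sigma: float = 2.0
    n_layers: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.blur_gain < 0:
            raise ValueError("blur_gain must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


def _draw_arc(canvas: np.ndarray, center: tuple[float, float], radius: float, thickness: float, value: float) -> None:
    h, w = canvas.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - center[0], xx - center[1])
    band = np.abs(dist - radius) < thickness
    canvas[band] = value


def _draw_line(canvas: np.ndarray, point: tuple[float, float], angle: float, thickness: float, value: float) -> None:
    h, w = canvas.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    nx, ny = np.cos(angle), np.sin(angle)
    dist = np.abs((xx - point[1]) * nx + (yy - point[0]) * ny)
    canvas[dist < thickness] = value


def generate_scene(height: int, width: int, seed: int) -> SyntheticScene:
    """Deterministic textured scene with arcs/lines and a smooth depth map.

    Truth values always span at least [30, 220] (dark lines at 20, bright
    arcs at 235 over a [40, 210] texture).  The depth map is a monotone
    row gradient plus a low-frequency perturbation, clipped to [0, 1].
    """
    if height < 64 or width < 64:
        raise ValueError("height and width must both be >= 64")
    rng = np.random.default_rng(seed)

    # coarse shading plus a fine-grain component: in-focus texture must carry
    # real high-frequency energy or defocus would barely register in |dI|
    coarse = ndimage.gaussian_filter(rng.standard_normal((height, width)), sigma=3.0)
    fine = ndimage.gaussian_filter(rng.standard_normal((height, width)), sigma=0.7)
    base = coarse / coarse.std() + 0.8 * fine / fine.std()
    lo, hi = base.min(), base.max()
    base = 40.0 + (base - lo) / (hi - lo) * (210.0 - 40.0)

    n_arcs = int(rng.integers(3, 6))
    for _ in range(n_arcs):
        center = (rng.uniform(0, height), rng.uniform(0, width))
        radius = rng.uniform(0.1, 0.45) * min(height, width)
        _draw_arc(base, center, radius, thickness=rng.uniform(1.0, 2.5), value=235.0)
    n_lines = int(rng.integers(2, 4))
    for _ in range(n_lines):
        point = (rng.uniform(0, height), rng.uniform(0, width))
        _draw_line(base, point, angle=rng.uniform(0, np.pi), thickness=rng.uniform(0.8, 1.8), value=20.0)

    gains = (1.0, 0.97, 0.92)  # mild warm cast so channels are not identical
    truth = np.clip(np.stack([base * g for g in gains], axis=-1), 0.0, 255.0)

    rows = np.linspace(0.0, 1.0, height)[:, None] * np.ones((1, width))
    perturb = ndimage.gaussian_filter(rng.standard_normal((height, width)), sigma=min(height, width) / 8.0)
    pmax = np.abs(perturb).max()
    if pmax > 0:
        perturb *= 0.15 / pmax
    depth = np.clip(rows + perturb, 0.0, 1.0)
    return SyntheticScene(truth=RGBImage(truth), depth=depth, seed=seed)


def focal_depths(n_planes: int) -> np.ndarray:
    """Evenly spaced focal depths on [0, 1] for planes 0..n_planes-1."""
    return np.linspace(0.0, 1.0, n_planes) if n_planes > 1 else np.array([0.0])


def render_focal_stack(scene: SyntheticScene, params: StackParams) -> FocalStack:
    """Render the scene at each focal plane with depth-dependent defocus.

    Per-pixel blur is ``blur_gain * |depth - d_f|``.  Depth is discretized
    into ``n_layers`` bands; each occupied band is blurred once per frame at
    the sigma of its mean member depth, and frames are composited by band
    membership.  Seeded Gaussian noise is added per frame.
    """
    truth = scene.truth.pixels
    depth = scene.depth
    depths = focal_depths(params.n_planes)
    edges = np.linspace(0.0, 1.0, params.n_layers + 1)
    band_idx = np.clip(np.digitize(depth, edges[1:-1]), 0, params.n_layers - 1)
    occupied = np.unique(band_idx)
    # representative depth per band: mean of member depths (exact for
    # constant maps, within half a band width otherwise)
    reps = {b: float(depth[band_idx == b].mean()) for b in occupied}
    masks = {b: (band_idx == b) for b in occupied}

    rng = np.random.default_rng(params.seed)
    frames = []
    for d_f in depths:
        frame = np.empty_like(truth)
        for b in occupied:
            sigma = params.blur_gain * abs(reps[b] - d_f)
            if sigma < MIN_BLUR_SIGMA:
                layer = truth
            else:
                layer = np.stack(
                    [ndimage.gaussian_filter(truth[..., c], sigma=sigma, mode="nearest") for c in range(3)],
                    axis=-1,
                )
            frame[masks[b]] = layer[masks[b]]
        if params.noise_sigma > 0:
            frame = frame + rng.normal(0.0, params.noise_sigma, size=frame.shape)
        frames.append(RGBImage(np.clip(frame, 0.0, 255.0)))
    return FocalStack(frames=frames)


def write_stack(stack: FocalStack, directory: str | os.PathLike) -> None:
    """Write one PNG per frame with zero-padded names fixing focal order."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    ndigits = max(2, len(str(len(stack) - 1)))
    for i, frame in enumerate(stack.frames):
        save_image(frame, os.path.join(directory, f"plane_{i:0{ndigits}d}.png"))
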