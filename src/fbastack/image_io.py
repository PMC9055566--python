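"""Raster image and focal-stack I/O plus color-to-grayscale conversion.

All pixel data is held as ``float64`` on the 0-255 intensity scale so that
downstream focus measures come out on a scale comparable across bit depths.
Focal order within a stack is defined purely by lexicographic filename order
(index 0 = foreground, nearest the objective); no metadata is consulted.
"""

from __future__ import annotations

import glob as _glob
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

#: Rec. 601 luma weights (R, G, B) — the common still-image convention.
REC601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class RGBImage:
    """True-color image, ``(height, width, 3)`` float pixels in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"RGBImage requires (H, W, 3) pixels, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("RGBImage requires height >= 1 and width >= 1")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("RGBImage pixel values must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GrayImage:
    """Single-channel image, ``(height, width)`` float pixels in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"GrayImage requires (H, W) pixels, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("GrayImage requires height >= 1 and width >= 1")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("GrayImage pixel values must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class FocalStack:
    """Ordered frames of one sector at increasing focal depth.

    Index 0 is the foreground plane (nearest the objective).  All frames must
    share identical dimensions and ``focal_indices`` must be strictly
    increasing.
    """

    frames: list[RGBImage]
    focal_indices: list[int] = field(default_factory=list)
    sector_id: int | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("FocalStack requires at least one frame")
        if not self.focal_indices:
            self.focal_indices = list(range(len(self.frames)))
        if len(self.focal_indices) != len(self.frames):
            raise ValueError("focal_indices length must match number of frames")
        if any(b <= a for a, b in zip(self.focal_indices, self.focal_indices[1:])):
            raise ValueError("focal_indices must be strictly increasing")
        h, w = self.frames[0].height, self.frames[0].width
        for i, f in enumerate(self.frames):
            if (f.height, f.width) != (h, w):
                raise ValueError(
                    f"frame {i} has size {f.height}x{f.width}, expected {h}x{w}"
                )
        if self.sector_id is not None and not 1 <= self.sector_id <= 16:
            raise ValueError("sector_id must be in 1..16")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def height(self) -> int:
        return self.frames[0].height

    @property
    def width(self) -> int:
        return self.frames[0].width


def load_image(path: str | os.PathLike) -> RGBImage:
    """Read a PNG/TIFF/JPEG file as an :class:`RGBImage` on the 0-255 scale.

    Grayscale files are replicated across three channels; an alpha channel,
    if present, is dropped.  16-bit data is rescaled to 0-255; bit depths
    other than 8 and 16 are rejected.
    """
    path = os.fspath(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise IOError(f"cannot read image {path!r}: {exc}") from exc
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64)
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    else:
        raise IOError(
            f"unsupported bit depth in {path!r}: dtype {arr.dtype} (only 8-bit and 16-bit accepted)"
        )
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"unsupported image layout in {path!r}: shape {arr.shape}")
    return RGBImage(arr)


def save_image(image: RGBImage | GrayImage, path: str | os.PathLike) -> None:
    """Write an image as 8-bit PNG or TIFF, rounding to the nearest integer.

    Values are clipped to [0, 255] before rounding, so a lossless format
    round-trips integer-valued images exactly.
    """
    path = os.fspath(path)
    data = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    try:
        iio.imwrite(path, data)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write image {path!r}: {exc}") from exc


def to_grayscale(image: RGBImage, weights: tuple[float, float, float] = REC601_WEIGHTS) -> GrayImage:
    """Convert to luminance with Rec. 601 weights (configurable)."""
    r, g, b = weights
    lum = r * image.pixels[:, :, 0] + g * image.pixels[:, :, 1] + b * image.pixels[:, :, 2]
    return GrayImage(np.clip(lum, 0.0, 255.0))


def load_stack(
    directory: str | os.PathLike,
    pattern: str = "*.png",
    sector_id: int | None = None,
) -> FocalStack:
    """Load a focal stack from a directory of per-plane image files.

    Lexicographic filename order defines focal order; index 0 is the
    foreground plane.  All frames must share identical dimensions.
    """
    directory = os.fspath(directory)
    paths = sorted(_glob.glob(os.path.join(directory, pattern)))
    if not paths:
        raise IOError(f"no files matching {pattern!r} in {directory!r}")
    frames = [load_image(p) for p in paths]
    h, w = frames[0].height, frames[0].width
    bad = [p for p, f in zip(paths, frames) if (f.height, f.width) != (h, w)]
    if bad:
        raise ValueError(
            f"frames with dimensions differing from {h}x{w} ({paths[0]!r}): " + ", ".join(bad)
        )
    return FocalStack(frames=frames, focal_indices=list(range(len(frames))), sector_id=sector_id)
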