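"""Laplacian-based focus measures and pairwise sharper-image decisions.

The sharpness score is the "energy of the Laplacian": the mean absolute
discrete second derivative |dI| of a grayscale image on the 0-255 intensity
scale.  Clearer images yield larger values, which drives both best-frame
selection within a focal stack and the forced-choice comparison between a
merged image and its single-frame baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import FocalStack, GrayImage, to_grayscale

__all__ = [
    "FocusMeasureMap",
    "laplacian_map",
    "laplacian_energy",
    "select_best_frame",
    "compare_pair",
]

#: 4-neighbor discrete Laplacian (the canonical choice).
KERNEL_LAP4 = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)
#: 8-neighbor variant, available via ``kernel="lap8"``.
KERNEL_LAP8 = np.array([[1, 1, 1], [1, -8, 1], [1, 1, 1]], dtype=np.float64)

_KERNELS = {"lap4": KERNEL_LAP4, "lap8": KERNEL_LAP8}


@dataclass
class FocusMeasureMap:
    """Per-pixel |dI| of a grayscale image; all values nonnegative."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("FocusMeasureMap requires (H, W) values")
        if self.values.min() < 0:
            raise ValueError("FocusMeasureMap values must be nonnegative")


def laplacian_map(image: GrayImage, kernel: str = "lap4") -> FocusMeasureMap:
    """Absolute discrete Laplacian with replicate (edge-clamp) padding.

    Replicate padding makes locally constant borders contribute zero second
    derivative, so the full-image average is well defined over all pixels.
    """
    if kernel not in _KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; expected one of {sorted(_KERNELS)}")
    response = ndimage.convolve(image.pixels, _KERNELS[kernel], mode="nearest")
    return FocusMeasureMap(np.abs(response))


def laplacian_energy(image: GrayImage, kernel: str = "lap4") -> float:
    """Mean of |dI| over all pixels (larger = sharper)."""
    return float(laplacian_map(image, kernel=kernel).values.mean())


def select_best_frame(stack: FocalStack, kernel: str = "lap4") -> int:
    """Index of the frame with maximal Laplacian energy; ties break low."""
    if len(stack) == 0:
        raise ValueError("stack must be nonempty")
    energies = [laplacian_energy(to_grayscale(f), kernel=kernel) for f in stack.frames]
    return int(np.argmax(energies))


def compare_pair(image_a: GrayImage, image_b: GrayImage, kernel: str = "lap4") -> str:
    """Forced-choice sharper image: ``"A"`` iff energy(A) > energy(B), else ``"B"``.

    Exact ties go to B, the conservative choice toward the baseline arm.
    """
    if (image_a.height, image_a.width) != (image_b.height, image_b.width):
        raise ValueError("images must share identical dimensions")
    ea = laplacian_energy(image_a, kernel=kernel)
    eb = laplacian_energy(image_b, kernel=kernel)
    return "A" if ea > eb else "B"
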