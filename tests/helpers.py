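"""Small shared helpers for the test suite."""

import numpy as np

from fbastack import FocalStack, RGBImage


def constant_stack(value: float, n_frames: int, height: int = 40, width: int = 48) -> FocalStack:
    frame = np.full((height, width, 3), value, dtype=np.float64)
    return FocalStack(frames=[RGBImage(frame.copy()) for _ in range(n_frames)])


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((np.asarray(a) - np.asarray(b)) ** 2).mean()))
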