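"""Hounsfield-unit windowing and fixed-size resizing for CTA slices.

A CT window maps the HU band ``[level - width/2, level + width/2]``
linearly onto [0, 1] with clamping outside the band. Model inputs are
built as a three-channel composite of two windows and their mean. Shipped
presets use conventional radiology settings (brain L40/W80, lung
L-600/W1500, bone L400/W1800); all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = ["WindowSpec", "WINDOW_PRESETS", "apply_window",
           "three_channel_composite", "resize_to"]


@dataclass(frozen=True)
class WindowSpec:
    """A CT display window: center ``level`` and ``width`` in HU."""

    level: float
    width: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


WINDOW_PRESETS = {
    "brain": WindowSpec(level=40.0, width=80.0, name="brain"),
    "lung": WindowSpec(level=-600.0, width=1500.0, name="lung"),
    "bone": WindowSpec(level=400.0, width=1800.0, name="bone"),
}


def apply_window(image: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Window an HU image to [0, 1]: linear ramp over the band, clamped."""
    img = np.asarray(image, dtype=float)
    low = spec.level - spec.width / 2
    return np.clip((img - low) / spec.width, 0.0, 1.0)


def three_channel_composite(
    image: np.ndarray, spec_a: WindowSpec, spec_b: WindowSpec
) -> np.ndarray:
    """Stack two windows and their pixel-wise mean into an (h, w, 3) array."""
    ch1 = apply_window(image, spec_a)
    ch2 = apply_window(image, spec_b)
    return np.stack([ch1, ch2, (ch1 + ch2) / 2.0], axis=-1)


def resize_to(
    grid: np.ndarray, target: tuple[int, int] = (300, 300), *, is_mask: bool = False
) -> np.ndarray:
    """Resize a 2-D or (h, w, c) grid to ``target`` height/width.

    Intensity grids use bilinear interpolation; masks use nearest-neighbor
    (``is_mask=True``), which preserves the value set {0, 1} exactly.
    """
    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError(f"target size must be positive, got {target}")
    if grid.shape[:2] == (th, tw):
        return grid
    out_shape = (th, tw) + grid.shape[2:]
    if is_mask:
        out = resize(grid, out_shape, order=0, preserve_range=True,
                     anti_aliasing=False)
        return out.astype(grid.dtype)
    return resize(grid, out_shape, order=1, preserve_range=True,
                  anti_aliasing=False)
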