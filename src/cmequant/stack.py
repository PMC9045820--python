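"""Image stack container and TIFF I/O.

An :class:`ImageStack` is a time-lapse intensity grid, ``(t, y, x)`` or
``(t, z, y, x)``, carrying the physical pixel size and frame interval so
downstream measurements can report lengths in micrometres and times in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """Time-lapse image data with physical calibration.

    Parameters
    ----------
    data :
        Intensity array, shape ``(t, y, x)`` or ``(t, z, y, x)``.
    pixel_size_um :
        Lateral pixel size in micrometres per pixel.
    frame_interval_s :
        Time between consecutive frames in seconds.
    """

    data: np.ndarray
    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (t, y, x) or (t, z, y, x)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def sum_project_z(self) -> "ImageStack":
        """Pixel-wise sum across z-slices; identity for 2-D stacks."""
        if not self.has_z:
            return self
        return ImageStack(self.data.sum(axis=1), self.pixel_size_um,
                          self.frame_interval_s)


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a multi-page 16-bit TIFF (values clipped to range)."""
    data = np.clip(np.round(stack.data), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16), imagej=True,
                     resolution=(1.0 / stack.pixel_size_um,
                                 1.0 / stack.pixel_size_um),
                     metadata={"unit": "um",
                               "finterval": stack.frame_interval_s})


def read_stack(path, pixel_size_um: float = 0.1,
               frame_interval_s: float = 1.0) -> ImageStack:
    """Read a multi-page TIFF as a float ImageStack."""
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data, pixel_size_um, frame_interval_s)
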