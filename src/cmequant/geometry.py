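"""Capsule (spherocylinder) geometry helpers shared by the synthetic-scene
generator and the per-cell counting module."""

from __future__ import annotations

import numpy as np


def capsule_mask(shape: tuple, length_px: float, radius_px: float,
                 center: tuple | None = None) -> np.ndarray:
    """Boolean mask of a horizontal capsule (rod cell seen in projection).

    ``length_px`` is the total tip-to-tip length; the mask is the set of
    pixels within ``radius_px`` of the central axis segment.
    """
    ny, nx = shape
    cy, cx = center if center is not None else ((ny - 1) / 2, (nx - 1) / 2)
    half_axis = max(length_px / 2 - radius_px, 0.0)
    yy, xx = np.mgrid[0:ny, 0:nx]
    dx = np.clip(xx - cx, -half_axis, half_axis)
    dist2 = (xx - cx - dx) ** 2 + (yy - cy) ** 2
    return dist2 <= radius_px ** 2


def capsule_polygon(length_px: float, radius_px: float,
                    center: tuple, n_arc: int = 32) -> np.ndarray:
    """Polygon outline (rows of (y, x) in px) of the same capsule."""
    cy, cx = center
    half_axis = max(length_px / 2 - radius_px, 0.0)
    th_right = np.linspace(-np.pi / 2, np.pi / 2, n_arc)
    th_left = np.linspace(np.pi / 2, 3 * np.pi / 2, n_arc)
    right = np.column_stack([cy + radius_px * np.sin(th_right),
                             cx + half_axis + radius_px * np.cos(th_right)])
    left = np.column_stack([cy + radius_px * np.sin(th_left),
                            cx - half_axis + radius_px * np.cos(th_left)])
    return np.vstack([right, left])
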