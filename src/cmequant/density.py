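"""Ratiometric counting of concurrent endocytic events per cell.

The whole-cell fluorescence attributable to endocytic patches (after
subtracting extracellular and cytoplasmic contributions) divided by the
time-averaged intensity of a single endocytic event gives the number of
concurrent events; dividing by the cell length gives the linear density
of endocytosis, and combining with the event lifetime and vesicle size
gives membrane-turnover rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from skimage.draw import polygon2mask

from .stack import ImageStack
from .tracking import detect_spots
from .alignment import AlignedEnsemble


@dataclass
class DensityResult:
    """Real-valued concurrent event count and linear density for one cell."""

    n_events: float
    density_per_um: float
    length_um: float
    a_event: float
    cytoplasm_level: float
    extracellular_level: float


def unit_event_intensity(ensemble: AlignedEnsemble) -> float:
    """Time-averaged intensity of one endocytic event over its lifetime
    (the denominator of the ratiometric count).  Uses the portion of the
    ensemble where the mean is positive."""
    pos = ensemble.mean > 0
    if not pos.any():
        raise ValueError("ensemble has no positive intensity")
    return float(ensemble.mean[pos].mean())


def _spot_exclusion_mask(img: np.ndarray, radius_px: int = 5) -> np.ndarray:
    """Boolean mask of pixels near detected spots (excluded from the
    cytoplasm estimate)."""
    from scipy import ndimage
    spots = detect_spots(img)
    mask = np.zeros(img.shape, dtype=bool)
    for y, x in np.round(spots).astype(int):
        mask[max(y - 1, 0):y + 2, max(x - 1, 0):x + 2] = True
    if mask.any():
        mask = ndimage.binary_dilation(mask, iterations=radius_px)
    return mask


def endocytic_density(stack_or_image: Union[ImageStack, np.ndarray],
                      outline_px: Optional[np.ndarray],
                      a_event: float,
                      pixel_size_um: float = 0.1,
                      length_um: Optional[float] = None,
                      mask: Optional[np.ndarray] = None) -> DensityResult:
    """Ratiometric count of concurrent endocytic events in one cell.

    Parameters
    ----------
    stack_or_image :
        Sum-projected corrected stack (averaged over time) or a single
        2-D image.
    outline_px :
        Cell outline polygon, rows of (y, x) in pixels; alternatively a
        precomputed boolean ``mask`` may be given.
    a_event :
        Time-averaged corrected intensity of one endocytic event, same
        units as the image.
    length_um :
        Cell length along the long axis; defaults to the outline's
        larger bounding-box extent.
    """
    if a_event <= 0:
        raise ValueError("unit event intensity must be positive")
    if isinstance(stack_or_image, ImageStack):
        img = stack_or_image.sum_project_z().data.mean(axis=0)
        pixel_size_um = stack_or_image.pixel_size_um
    else:
        img = np.asarray(stack_or_image, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=0)

    if mask is None:
        if outline_px is None:
            raise ValueError("need an outline polygon or a mask")
        outline_px = np.asarray(outline_px, dtype=float)
        if outline_px.ndim != 2 or len(outline_px) < 3:
            raise ValueError("degenerate outline")
        mask = polygon2mask(img.shape, outline_px)
    if mask.sum() == 0:
        raise ValueError("degenerate outline: empty mask")

    if length_um is None:
        ys, xs = np.nonzero(mask)
        length_um = (max(ys.ptp(), xs.ptp()) + 1) * pixel_size_um
    if length_um <= 0:
        raise ValueError("cell length must be positive")

    from scipy import ndimage

    # medium level: median far outside the cell (clear of the PSF skirt)
    far_outside = ~ndimage.binary_dilation(mask, iterations=6)
    extra = float(np.median(img[far_outside])) if far_outside.any() else 0.0
    corrected = img - extra

    # cytoplasmic level: median of spot-free interior pixels, eroded away
    # from the boundary so the PSF blur does not bias it low
    interior = ndimage.binary_erosion(mask, iterations=4)
    if not interior.any():
        interior = mask
    spot_mask = _spot_exclusion_mask(corrected)
    cyto_pixels = corrected[interior & ~spot_mask]
    if cyto_pixels.size == 0:
        cyto_pixels = corrected[interior]
    cyto = float(np.median(cyto_pixels))

    # blurring conserves photons, so summing the whole image captures the
    # boundary skirt; the cytoplasm contributes cyto x (outline area)
    patch_total = float(corrected.sum()) - cyto * int(mask.sum())
    n_events = max(patch_total, 0.0) / a_event
    return DensityResult(n_events=n_events,
                         density_per_um=n_events / length_um,
                         length_um=float(length_um), a_event=float(a_event),
                         cytoplasm_level=cyto, extracellular_level=extra)


def membrane_turnover(n_events: float, lifetime_s: float,
                      vesicle_diameter_um: float,
                      cell_area_um2: float) -> dict:
    """Membrane internalization rate from the concurrent event count.

    events/min = n·(60/lifetime); each vesicle removes a sphere's worth
    of membrane, πd²; percent/min expresses that relative to the cell
    surface area.
    """
    if min(n_events, lifetime_s, vesicle_diameter_um, cell_area_um2) <= 0 \
            and n_events != 0:
        if lifetime_s <= 0 or vesicle_diameter_um <= 0 or cell_area_um2 <= 0:
            raise ValueError("all inputs must be positive")
    events_per_min = n_events * 60.0 / lifetime_s
    area_per_min = events_per_min * math.pi * vesicle_diameter_um ** 2
    return {
        "events_per_min": events_per_min,
        "area_per_min_um2": area_per_min,
        "percent_per_min": 100.0 * area_per_min / cell_area_um2,
    }
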