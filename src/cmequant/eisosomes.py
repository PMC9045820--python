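"""Eisosome density and disassembly kinetics.

Eisosome-bound fluorescence is isolated from the cytosolic pool with an
intensity threshold, sum-projected over z, and normalized by the cell
surface area (sphere for protoplasts).  After a hypotonic shock the
fraction of the membrane covered by eisosomes decays; a single
exponential (optionally with a plateau for partial disassembly)
summarizes the kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stack import ImageStack


@dataclass
class EisosomeDensity:
    membrane_intensity: float     # thresholded, z-summed (a.u.)
    surface_area_um2: float
    density_au_per_um2: float


@dataclass
class DecayFit:
    rate_per_min: float
    plateau: float
    amplitude: float
    r_squared: float


def eisosome_density(zstack: ImageStack, radius_um: float,
                     cytosol_threshold: float,
                     mask: Optional[np.ndarray] = None) -> EisosomeDensity:
    """Membrane-bound intensity per unit protoplast surface area.

    Subtracts the cytosolic level (``cytosol_threshold``) from every
    pixel, clips at zero, sums all z-slices, totals the result within the
    cell outline, and divides by the spherical surface area 4πR².
    """
    if radius_um <= 0:
        raise ValueError("cell radius must be positive")
    data = zstack.data.astype(float)
    if data.ndim == 3:      # single (z, y, x) stack stored as 3-D
        zsum = np.clip(data - cytosol_threshold, 0, None).sum(axis=0)
    else:
        zsum = np.clip(data - cytosol_threshold, 0, None).sum(axis=(0, 1))
    total = float(zsum[mask].sum()) if mask is not None else float(zsum.sum())
    area = 4.0 * math.pi * radius_um ** 2
    return EisosomeDensity(total, area, total / area)


def cytosol_threshold_from_region(image: np.ndarray, region_mask: np.ndarray,
                                  percentile: float = 95.0) -> float:
    """Threshold separating cytosolic from eisosome-bound signal, taken
    as a high percentile of pixel values in a user-marked cytosol-only
    region."""
    return float(np.percentile(np.asarray(image)[region_mask], percentile))


def area_fraction_timecourse(stack: ImageStack,
                             threshold: float) -> pd.DataFrame:
    """Above-threshold area per frame, normalized to the first frame.

    Input is a single-z time lapse of the membrane plane; f(0) = 1 by
    construction.
    """
    data = stack.sum_project_z().data
    areas = (data > threshold).sum(axis=(1, 2)).astype(float)
    if areas[0] == 0:
        raise ValueError("no above-threshold area in the first frame")
    t_min = stack.times_s() / 60.0
    return pd.DataFrame({"t_min": t_min, "area_fraction": areas / areas[0]})


def fit_eisosome_decay(t_min: np.ndarray, area_fraction: np.ndarray,
                       fit_plateau: bool = False) -> DecayFit:
    """Least-squares single-exponential fit of the normalized decay,
    f(t) = plateau + (1 − plateau)·exp(−rate·t).

    ``fit_plateau=False`` (default) forces plateau = 0, i.e. complete
    disassembly at long times; enable the plateau for partial
    disassembly.
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(area_fraction, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in the series")

    if fit_plateau:
        def model(tt, rate, plateau):
            return plateau + (1.0 - plateau) * np.exp(-rate * tt)
        p0 = (0.1, 0.0)
        bounds = ([0.0, 0.0], [np.inf, 1.0])
    else:
        def model(tt, rate):
            return np.exp(-rate * tt)
        p0 = (0.1,)
        bounds = ([0.0], [np.inf])
    popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=10000)
    rate = float(popt[0])
    plateau = float(popt[1]) if fit_plateau else 0.0
    resid = y - model(t, *popt)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(rate_per_min=rate, plateau=plateau,
                    amplitude=1.0 - plateau, r_squared=float(r2))
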