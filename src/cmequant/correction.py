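"""Flat-field / dark-frame correction and photobleaching handling.

Uneven illumination is estimated from a movie of a uniform dye solution;
camera offset from a dark movie.  Photobleaching is estimated from the
decay of cytoplasmic regions devoid of spots and undone multiplicatively.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .stack import ImageStack


@dataclass
class CorrectionFields:
    """Multiplicative illumination map (mean 1) and additive dark offset."""

    illumination: np.ndarray
    dark: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.illumination = np.asarray(self.illumination, dtype=float)
        if np.any(self.illumination <= 0):
            raise ValueError("illumination field must be strictly positive")
        if self.dark is not None:
            self.dark = np.asarray(self.dark, dtype=float)
            if self.dark.shape != self.illumination.shape:
                raise ValueError("dark and illumination shapes differ")


@dataclass
class BleachFit:
    """Single-exponential bleach fit I(t) = I0·exp(−λt)."""

    rate_per_s: float
    amplitude: float
    residual_rms: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"rate_per_s": self.rate_per_s,
                       "amplitude": self.amplitude,
                       "residual_rms": self.residual_rms}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BleachFit":
        with open(path) as fh:
            return cls(**json.load(fh))


def estimate_illumination(dye_stack: ImageStack,
                          smooth_sigma_px: float = 10.0) -> np.ndarray:
    """Illumination field from a uniform-dye movie.

    Temporal mean, Gaussian-smoothed (SD ``smooth_sigma_px`` to suppress
    dye shot noise without flattening vignetting), rescaled to mean 1.
    """
    data = dye_stack.sum_project_z().data
    if data.shape[0] == 0:
        raise ValueError("empty stack")
    mean_img = data.mean(axis=0)
    smooth = ndimage.gaussian_filter(mean_img, smooth_sigma_px)
    if np.any(smooth <= 0):
        raise ValueError("smoothed illumination image has non-positive pixels")
    return smooth / smooth.mean()


def correct_stack(raw: ImageStack, fields: CorrectionFields) -> ImageStack:
    """(raw − dark)/illumination, clipped at 0 (intensities are counts)."""
    data = raw.data.astype(float)
    if fields.illumination.shape != data.shape[-2:]:
        raise ValueError("correction field shape does not match frames")
    if fields.dark is not None:
        data = data - fields.dark
    data = data / fields.illumination
    return ImageStack(np.clip(data, 0, None), raw.pixel_size_um,
                      raw.frame_interval_s)


def fit_photobleaching(trace: np.ndarray,
                       times_s: Optional[np.ndarray] = None,
                       frame_interval_s: float = 1.0) -> BleachFit:
    """Fit I0·exp(−λt) to a cytoplasmic background trace.

    Fits in log space when the trace is strictly positive (linear in the
    parameters, robust for the near-exponential decays seen in practice)
    and falls back to nonlinear least squares when it touches zero.
    A fitted negative rate is clamped to 0 with a warning: bleaching
    cannot brighten a fluorophore.
    """
    y = np.asarray(trace, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 samples to fit bleaching")
    if np.all(y == 0):
        raise ValueError("all-zero trace")
    t = (np.asarray(times_s, dtype=float) if times_s is not None
         else np.arange(y.size) * frame_interval_s)

    if np.all(y > 0):
        slope, intercept = np.polyfit(t, np.log(y), 1)
        rate, amp = -slope, float(np.exp(intercept))
    else:
        p0 = (max(y[0], y.max() * 0.5), 0.01)
        (amp, rate), _ = optimize.curve_fit(
            lambda tt, a, lam: a * np.exp(-lam * tt), t, y, p0=p0,
            maxfev=10000)
    if rate < 0:
        if rate < -1e-10:      # a float-noise slope is not worth a warning
            warnings.warn("fitted bleach rate was negative; clamped to 0")
            amp = float(y.mean())
        rate = 0.0
    resid = y - amp * np.exp(-rate * t)
    return BleachFit(rate_per_s=float(rate), amplitude=float(amp),
                     residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def debleach(trace: np.ndarray, fit: BleachFit,
             times_s: Optional[np.ndarray] = None,
             frame_interval_s: float = 1.0) -> np.ndarray:
    """Undo photobleaching: out(t) = in(t)·exp(+λt)."""
    y = np.asarray(trace, dtype=float)
    t = (np.asarray(times_s, dtype=float) if times_s is not None
         else np.arange(y.size) * frame_interval_s)
    return y * np.exp(fit.rate_per_s * t)


def cytoplasm_background_trace(stack: ImageStack,
                               mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-frame median intensity of cytoplasmic pixels.

    The median inside the cell mask is insensitive to the sparse bright
    endocytic spots, making it a usable stand-in for manually chosen
    spot-free ROIs.
    """
    data = stack.sum_project_z().data
    if mask is None:
        return np.median(data.reshape(data.shape[0], -1), axis=1)
    return np.array([np.median(frame[mask]) for frame in data])
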