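"""Synthetic-data generators with known ground truth.

Every analysis stage in this package is validated against data produced
here: time-lapse movies of endocytic patches in a capsule-shaped cell,
FM4-64 staining traces, eisosome area-fraction decays, micropipette
aspiration series, and survival tables.  The generators encode the
statistical structure the analyses assume — a rise-then-fall spot
intensity profile that is stationary until the peak (vesicle scission)
and diffusive afterwards, cytoplasmic and extracellular background,
global photobleaching, multiplicative uneven illumination, and additive
(EMCCD-like) Gaussian camera noise — and return the ground truth needed
to score recovery.

Defaults mirror the acquisition they emulate: 0.1 µm/px, one frame per
second for 60 s, a ~10 s assembly to a peak of 830 molecules followed by
a ~10 s disassembly, and a 12 µm × 1.75 µm-radius capsule cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .stack import ImageStack
from .geometry import capsule_mask
from .exocytosis import FMTrace

_PSF_SIGMA_PX = 1.3  # sub-diffraction spot rendered as a 2-D Gaussian


@dataclass
class PatchSceneParams:
    """Parameters of a synthetic endocytic-patch movie."""

    n_events: int = 20
    rise_s: float = 10.0
    fall_s: float = 10.0
    peak_molecules: float = 830.0
    intensity_per_molecule: float = 1.0
    diffusion_step_px: float = 1.0
    cytoplasm_level: float = 30.0
    extracellular_level: float = 5.0
    bleach_rate: float = 0.0
    noise_sd: float = 0.0
    illumination_field: Optional[np.ndarray] = None
    cell_length_um: float = 12.0
    cell_radius_um: float = 1.75
    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.0
    n_frames: int = 60
    margin_px: int = 8
    seed: int = 0

    def validate(self) -> None:
        non_negative = dict(
            n_events=self.n_events, rise_s=self.rise_s, fall_s=self.fall_s,
            peak_molecules=self.peak_molecules,
            intensity_per_molecule=self.intensity_per_molecule,
            diffusion_step_px=self.diffusion_step_px,
            cytoplasm_level=self.cytoplasm_level,
            extracellular_level=self.extracellular_level,
            bleach_rate=self.bleach_rate, noise_sd=self.noise_sd)
        for name, value in non_negative.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.rise_s + self.fall_s <= 0:
            raise ValueError("event lifetime must be positive")
        # the cell must be able to hold at least one 7-px measurement ROI
        if 2 * self.cell_radius_um / self.pixel_size_um < 7:
            raise ValueError("cell capsule smaller than one measurement ROI")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["illumination_field"] = (None if self.illumination_field is None
                                   else np.asarray(
                                       self.illumination_field).tolist())
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PatchSceneParams":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("illumination_field") is not None:
            d["illumination_field"] = np.asarray(d["illumination_field"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-event and per-scene truth for a synthetic patch movie."""

    start_frames: np.ndarray           # first frame with nonzero intensity
    lifetimes_s: np.ndarray
    peak_molecules: np.ndarray
    positions_px: List[np.ndarray]     # per event: (n_frames, 2) (y, x)
    intensities_au: List[np.ndarray]   # per event: unbleached profile
    cell_mask: np.ndarray
    cell_length_um: float
    mean_concurrent_events: float
    density_per_um: float
    bleach_rate: float

    @property
    def n_events(self) -> int:
        return len(self.positions_px)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "event": np.arange(self.n_events),
            "start_frame": self.start_frames,
            "lifetime_s": self.lifetimes_s,
            "peak_molecules": self.peak_molecules,
            "y0_px": [p[0, 0] for p in self.positions_px],
            "x0_px": [p[0, 1] for p in self.positions_px],
        })


def _event_profile(times_s: np.ndarray, start_s: float, rise_s: float,
                   fall_s: float, peak_au: float) -> np.ndarray:
    """Piecewise-linear rise-then-fall intensity profile (a.u.)."""
    rel = times_s - start_s
    up = peak_au * rel / rise_s if rise_s > 0 else np.full_like(rel, peak_au)
    down = peak_au * (1.0 - (rel - rise_s) / fall_s) if fall_s > 0 else 0.0
    prof = np.where(rel <= rise_s, up, down)
    prof[(rel < 0) | (rel > rise_s + fall_s)] = 0.0
    return np.clip(prof, 0.0, None)


def _render_gaussian(frame: np.ndarray, y: float, x: float,
                     integral: float, sigma: float) -> None:
    """Add a 2-D Gaussian of given integrated intensity in place."""
    if integral <= 0:
        return
    half = int(math.ceil(5 * sigma))
    ny, nx = frame.shape
    y0, y1 = max(int(y) - half, 0), min(int(y) + half + 1, ny)
    x0, x1 = max(int(x) - half, 0), min(int(x) + half + 1, nx)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    g = np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma ** 2))
    frame[y0:y1, x0:x1] += integral * g / (2 * math.pi * sigma ** 2)


def _place_positions(rng: np.random.Generator, mask: np.ndarray, n: int,
                     margin_px: int, min_sep_px: float = 10.0) -> np.ndarray:
    """Rejection-sample spot anchor positions inside the eroded cell mask,
    keeping events mutually separated so tracks never merge."""
    from scipy import ndimage
    interior = ndimage.binary_erosion(mask, iterations=margin_px)
    ys, xs = np.nonzero(interior)
    if ys.size == 0:
        raise ValueError("cell interior too small for spot placement")
    chosen: list = []
    sep = min_sep_px
    attempts = 0
    while len(chosen) < n:
        i = rng.integers(ys.size)
        cand = np.array([ys[i], xs[i]], dtype=float)
        if all(np.hypot(*(cand - c)) >= sep for c in chosen):
            chosen.append(cand)
        attempts += 1
        if attempts > 20000:      # relax separation for crowded scenes
            sep *= 0.8
            attempts = 0
    return np.array(chosen)


def synth_patch_movie(params: PatchSceneParams):
    """Render a time-lapse movie of endocytic patches in one capsule cell.

    Returns ``(ImageStack, GroundTruth)``.  Spots follow a linear
    rise/fall intensity profile, stay stationary until the peak and
    random-walk afterwards (RMS step ``diffusion_step_px``); the whole
    frame is bleached by exp(−λt), multiplied by the illumination field,
    and Gaussian camera noise is added last.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    radius_px = params.cell_radius_um / params.pixel_size_um
    length_px = params.cell_length_um / params.pixel_size_um
    ny = int(math.ceil(2 * radius_px)) + 4 * params.margin_px
    nx = int(math.ceil(length_px)) + 4 * params.margin_px
    mask = capsule_mask((ny, nx), length_px, radius_px)

    times = np.arange(params.n_frames) * params.frame_interval_s
    lifetime_s = params.rise_s + params.fall_s
    lifetime_f = lifetime_s / params.frame_interval_s
    max_start = max(params.n_frames - 1 - lifetime_f, 0)

    anchors = (_place_positions(rng, mask, params.n_events, params.margin_px)
               if params.n_events else np.zeros((0, 2)))
    start_frames = (np.sort(rng.uniform(0, max_start, params.n_events))
                    if params.n_events else np.zeros(0))

    peak_au = params.peak_molecules * params.intensity_per_molecule
    positions, profiles = [], []
    for e in range(params.n_events):
        start_s = start_frames[e] * params.frame_interval_s
        prof = _event_profile(times, start_s, params.rise_s, params.fall_s,
                              peak_au)
        pos = np.tile(anchors[e], (params.n_frames, 1))
        peak_f = int(round((start_s + params.rise_s)
                           / params.frame_interval_s))
        # post-scission diffusion: per-axis step SD gives the stated RMS step
        step_sd = params.diffusion_step_px / math.sqrt(2)
        for f in range(peak_f + 1, params.n_frames):
            pos[f] = pos[f - 1] + rng.normal(0, step_sd, 2)
            pos[f, 0] = np.clip(pos[f, 0], 1, ny - 2)
            pos[f, 1] = np.clip(pos[f, 1], 1, nx - 2)
        positions.append(pos)
        profiles.append(prof)

    data = np.empty((params.n_frames, ny, nx))
    # the optics blur the cytoplasm/exterior step by the PSF too
    from scipy import ndimage as _ndi
    base = _ndi.gaussian_filter(
        params.cytoplasm_level * mask.astype(float)
        + params.extracellular_level * (~mask).astype(float), _PSF_SIGMA_PX)
    for f in range(params.n_frames):
        frame = base.copy()
        for e in range(params.n_events):
            if profiles[e][f] > 0:
                _render_gaussian(frame, positions[e][f, 0],
                                 positions[e][f, 1], profiles[e][f],
                                 _PSF_SIGMA_PX)
        frame *= math.exp(-params.bleach_rate * times[f])
        data[f] = frame
    if params.illumination_field is not None:
        illum = np.asarray(params.illumination_field, dtype=float)
        if illum.shape != (ny, nx):
            raise ValueError("illumination_field shape must match the scene "
                             f"({ny}, {nx})")
        data *= illum
    if params.noise_sd > 0:
        data += rng.normal(0, params.noise_sd, data.shape)

    concurrent = np.zeros(params.n_frames)
    for prof in profiles:
        concurrent += prof > 0
    mean_concurrent = float(concurrent.mean())
    truth = GroundTruth(
        start_frames=np.asarray(start_frames),
        lifetimes_s=np.full(params.n_events, lifetime_s),
        peak_molecules=np.full(params.n_events, params.peak_molecules),
        positions_px=positions,
        intensities_au=profiles,
        cell_mask=mask,
        cell_length_um=params.cell_length_um,
        mean_concurrent_events=mean_concurrent,
        density_per_um=mean_concurrent / params.cell_length_um,
        bleach_rate=params.bleach_rate,
    )
    return ImageStack(data, params.pixel_size_um,
                      params.frame_interval_s), truth


def synth_fm_trace(k_percent_per_min: float, fast_phase_s: float = 60.0,
                   noise_sd: float = 0.0, n_min: float = 15.0,
                   dt_s: float = 5.0, seed: int = 0) -> FMTrace:
    """FM4-64 staining trace: saturating fast phase reaching exactly 1 at
    ``fast_phase_s``, then linear growth at ``k_percent_per_min``/100 per
    minute, plus optional Gaussian noise."""
    if k_percent_per_min < 0:
        raise ValueError("rate must be non-negative")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    rng = np.random.default_rng(seed)
    t_s = np.arange(0.0, n_min * 60.0 + dt_s / 2, dt_s)
    tau = fast_phase_s / 5.0
    sat = (1.0 - np.exp(-t_s / tau)) / (1.0 - np.exp(-fast_phase_s / tau))
    lin = 1.0 + (k_percent_per_min / 100.0) * (t_s - fast_phase_s) / 60.0
    f = np.where(t_s < fast_phase_s, sat, lin)
    if noise_sd > 0:
        f = f + rng.normal(0, noise_sd, f.shape)
    return FMTrace(t_s / 60.0, f, fast_phase_end_min=fast_phase_s / 60.0)


def synth_aspiration_series(sigma_true_n_per_m: float, rp_um: float,
                            rc_um: float,
                            pressure_steps_pa: Sequence[float]
                            ) -> pd.DataFrame:
    """Tongue-length series for a target membrane tension.

    The tongue grows linearly with aspiration pressure and crosses
    l = Rp exactly at the critical pressure ΔP* = 2σ(1 − Rp/Rc)/Rp.
    """
    if rp_um >= rc_um:
        raise ValueError("requires Rp < Rc")
    if sigma_true_n_per_m <= 0:
        raise ValueError("tension must be positive")
    dp_star = (2.0 * sigma_true_n_per_m * (1.0 - rp_um / rc_um)
               / (rp_um * 1e-6))
    p = np.asarray(pressure_steps_pa, dtype=float)
    return pd.DataFrame({"pressure_pa": p,
                         "tongue_um": rp_um * p / dp_star})


def synth_eisosome_series(f0: float = 1.0, decay_rate_per_min: float = 0.1,
                          plateau: float = 0.0, n_min: float = 10.0,
                          noise_sd: float = 0.0, dt_min: float = 0.25,
                          seed: int = 0) -> pd.DataFrame:
    """Normalized eisosome area-fraction decay after a hypotonic shock:
    f(t) = plateau + (f0 − plateau)·exp(−rate·t), normalized to f(0)=1."""
    if decay_rate_per_min < 0:
        raise ValueError("decay rate must be non-negative")
    if not 0 <= plateau <= f0 <= 1:
        raise ValueError("requires 0 <= plateau <= f0 <= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, n_min + dt_min / 2, dt_min)
    f = (plateau + (f0 - plateau) * np.exp(-decay_rate_per_min * t)) / f0
    if noise_sd > 0:
        noise = rng.normal(0, noise_sd, f.shape)
        noise[0] = 0.0          # normalization anchor stays exactly 1
        f = f + noise
    return pd.DataFrame({"t_min": t, "area_fraction": f})


def synth_survival_times(n: int, death_prob_per_interval: float,
                         n_intervals: int, seed: int = 0) -> pd.DataFrame:
    """Geometric survival times with right-censoring past ``n_intervals``.

    Each subject dies at each interval with the given probability
    (emulating repeated osmotic shocks); survivors are censored at
    ``n_intervals``.  Returns columns ``time`` and ``status`` (1=death).
    """
    p = death_prob_per_interval
    if not 0 <= p <= 1:
        raise ValueError("probability must be in [0, 1]")
    if n == 0:
        return pd.DataFrame({"time": [], "status": []})
    rng = np.random.default_rng(seed)
    if p == 0:
        times = np.full(n, n_intervals)
        status = np.zeros(n, dtype=int)
    else:
        times = rng.geometric(p, n)
        status = (times <= n_intervals).astype(int)
        times = np.minimum(times, n_intervals)
    return pd.DataFrame({"time": times, "status": status})
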