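"""Temporal super-resolution alignment and ensemble averaging.

Single-event intensity traces are sampled at the frame interval with no
absolute time reference.  The aligner iteratively estimates a sub-frame
temporal offset for each trace by exhaustive grid search (step
``sub_dt_s``) minimizing the mean square difference to a reference, then
recomputes the reference as the pointwise mean of the realigned traces
— an estimator of the true underlying signal.  The ensemble time axis is
shifted so the (lightly smoothed) mean peaks at t = 0, the moment of
vesicle scission.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class CalibrationFactor:
    """Intensity → molecule-number conversion anchored on a control
    strain whose ensemble peak corresponds to a known copy number."""

    control_peak_intensity: float
    anchor_molecules: float = 830.0

    def __post_init__(self) -> None:
        if self.control_peak_intensity <= 0:
            raise ValueError("control peak intensity must be positive")
        if self.anchor_molecules <= 0:
            raise ValueError("anchor molecule number must be positive")

    @property
    def molecules_per_au(self) -> float:
        return self.anchor_molecules / self.control_peak_intensity


@dataclass
class AlignedEnsemble:
    """Sub-frame-aligned ensemble mean ± 95% CI versus time (peak at 0)."""

    t_s: np.ndarray
    mean: np.ndarray
    ci95: np.ndarray
    n_per_point: np.ndarray
    offsets_s: np.ndarray
    n_tracks: int
    mean_speed_um_s: Optional[np.ndarray] = None
    speed_sd: Optional[np.ndarray] = None
    units: str = "a.u."
    objective_history: list = field(default_factory=list)

    @property
    def peak_value(self) -> float:
        return float(self.mean[np.argmin(np.abs(self.t_s))])

    def to_frame(self) -> pd.DataFrame:
        d = {"t_s": self.t_s, "mean": self.mean, "ci95": self.ci95,
             "n": self.n_per_point}
        if self.mean_speed_um_s is not None:
            d["mean_speed_um_s"] = self.mean_speed_um_s
            d["speed_sd"] = self.speed_sd
        return pd.DataFrame(d)


def _smooth3(y: np.ndarray) -> np.ndarray:
    if y.size < 3:
        return y
    out = y.copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def _interp_masked(tq: np.ndarray, t: np.ndarray, y: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Linear interpolation restricted to the support of (t, y)."""
    inside = (tq >= t[0]) & (tq <= t[-1])
    vals = np.interp(tq, t, y)
    return vals, inside


def align_and_average(traces: Sequence[Tuple[np.ndarray, np.ndarray]],
                      sub_dt_s: float = 0.1, max_shift_s: float = 10.0,
                      tol: Optional[float] = None, max_iter: int = 50,
                      aux_traces: Optional[Sequence] = None
                      ) -> AlignedEnsemble:
    """Align traces with sub-frame offsets and average them.

    Parameters
    ----------
    traces :
        List of ``(times_s, values)`` pairs, each with >= 5 samples.
    sub_dt_s :
        Offset grid step; this sets the temporal resolution of the
        ensemble, finer than the acquisition frame interval.
    max_shift_s, tol, max_iter :
        Search range, convergence tolerance on the largest offset change
        (default ``sub_dt_s``), and iteration cap.
    aux_traces :
        Optional per-trace auxiliary series ``(times_s, values)`` (e.g.
        patch speed) averaged on the same grid using the same offsets.
    """
    if tol is None:
        tol = sub_dt_s
    traces = [(np.asarray(t, dtype=float), np.asarray(y, dtype=float))
              for t, y in traces]
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    for t, y in traces:
        if t.size < 5:
            raise ValueError("each trace needs at least 5 samples")

    # events carry no absolute clock: coarse-center each trace on its own
    # sample maximum, then refine with the sub-frame grid search
    coarse = np.array([t[int(np.argmax(y))] for t, y in traces])
    traces = [(t - c, y) for (t, y), c in zip(traces, coarse)]

    shifts = np.arange(-max_shift_s, max_shift_s + sub_dt_s / 2, sub_dt_s)
    ref_t, ref_y = traces[0]
    offsets = np.zeros(len(traces))
    dropped = np.zeros(len(traces), dtype=bool)
    history: list = []

    for _ in range(max_iter):
        new_offsets = offsets.copy()
        total = 0.0
        for i, (t, y) in enumerate(traces):
            if dropped[i]:
                continue
            best, best_mse = offsets[i], np.inf
            for s in shifts:
                lo = max(ref_t[0], t[0] + s)
                hi = min(ref_t[-1], t[-1] + s)
                if hi - lo < sub_dt_s:
                    continue
                tq = np.arange(lo, hi + sub_dt_s / 2, sub_dt_s)
                mse = np.mean((np.interp(tq - s, t, y)
                               - np.interp(tq, ref_t, ref_y)) ** 2)
                if mse < best_mse:
                    best_mse, best = mse, s
            if not np.isfinite(best_mse):
                warnings.warn(f"trace {i} has no overlap with the "
                              "reference after shifting; dropped")
                dropped[i] = True
                continue
            new_offsets[i] = best
            total += best_mse
        if dropped.all():
            raise ValueError("all traces dropped: no overlap")
        history.append(total)

        # new reference: pointwise mean of the realigned traces
        lo = min(t[0] + s for (t, _), s, d
                 in zip(traces, new_offsets, dropped) if not d)
        hi = max(t[-1] + s for (t, _), s, d
                 in zip(traces, new_offsets, dropped) if not d)
        grid = np.arange(lo, hi + sub_dt_s / 2, sub_dt_s)
        acc = np.zeros_like(grid)
        cnt = np.zeros_like(grid)
        for (t, y), s, d in zip(traces, new_offsets, dropped):
            if d:
                continue
            vals, inside = _interp_masked(grid - s, t, y)
            acc[inside] += vals[inside]
            cnt[inside] += 1
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        valid = cnt > 0
        ref_t, ref_y = grid[valid], mean[valid]

        if np.max(np.abs(new_offsets - offsets)) < tol:
            offsets = new_offsets
            break
        offsets = new_offsets

    # final pointwise statistics on the reference grid
    grid = ref_t
    stacked = np.full((len(traces), grid.size), np.nan)
    for i, ((t, y), s) in enumerate(zip(traces, offsets)):
        if dropped[i]:
            continue
        vals, inside = _interp_masked(grid - s, t, y)
        stacked[i, inside] = vals[inside]
    n = np.sum(~np.isnan(stacked), axis=0)
    keep = n > 0
    grid, stacked, n = grid[keep], stacked[:, keep], n[keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
        sd = np.nanstd(stacked, axis=0, ddof=1) if len(traces) > 1 \
            else np.zeros_like(mean)
    sd = np.nan_to_num(sd)
    ci = 1.96 * sd / np.sqrt(np.maximum(n, 1))

    # put the (smoothed) peak at t = 0
    t_peak = grid[int(np.argmax(_smooth3(mean)))]
    grid = grid - t_peak

    # total offset applied to the original (uncentered) trace times
    total_offsets = offsets - coarse

    speed_mean = speed_sd = None
    if aux_traces is not None:
        aux_stack = np.full((len(traces), grid.size), np.nan)
        for i, ((ta, ya), s) in enumerate(zip(aux_traces, total_offsets)):
            if dropped[i]:
                continue
            ta = np.asarray(ta, dtype=float)
            ya = np.asarray(ya, dtype=float)
            if ta.size < 2:
                continue
            vals, inside = _interp_masked(grid + t_peak - s, ta, ya)
            aux_stack[i, inside] = vals[inside]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            speed_mean = np.nanmean(aux_stack, axis=0)
            speed_sd = np.nanstd(aux_stack, axis=0, ddof=1)

    return AlignedEnsemble(t_s=grid, mean=mean, ci95=ci, n_per_point=n,
                           offsets_s=total_offsets,
                           n_tracks=int((~dropped).sum()),
                           mean_speed_um_s=speed_mean, speed_sd=speed_sd,
                           objective_history=history)


def calibrate_molecules(ensemble: AlignedEnsemble,
                        calib: CalibrationFactor) -> AlignedEnsemble:
    """Convert ensemble intensities to molecule numbers via the control
    anchor: molecules = intensity × anchor / control_peak."""
    f = calib.molecules_per_au
    return AlignedEnsemble(
        t_s=ensemble.t_s, mean=ensemble.mean * f, ci95=ensemble.ci95 * f,
        n_per_point=ensemble.n_per_point, offsets_s=ensemble.offsets_s,
        n_tracks=ensemble.n_tracks,
        mean_speed_um_s=ensemble.mean_speed_um_s,
        speed_sd=ensemble.speed_sd, units="molecules",
        objective_history=ensemble.objective_history)


def compute_speed(times_s: np.ndarray, positions_um: np.ndarray
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Frame-to-frame speed of a patch: |r(t+Δt) − r(t)|/Δt.

    Returns ``(times, speeds)`` where the speed at ``times[i]`` is the
    displacement to the next sample.  Single-point tracks yield empty
    series.
    """
    t = np.asarray(times_s, dtype=float)
    r = np.asarray(positions_um, dtype=float).reshape(len(t), -1)
    if t.size < 2:
        return np.zeros(0), np.zeros(0)
    dt = np.diff(t)
    disp = np.linalg.norm(np.diff(r, axis=0), axis=1)
    return t[:-1], disp / dt


def half_peak_times(ensemble: AlignedEnsemble
                    ) -> Tuple[Optional[float], Optional[float]]:
    """Assembly and disassembly durations from half-peak crossings.

    Assembly = time from the first upward half-peak crossing to the
    peak; disassembly = time from the peak to the last downward
    crossing; crossings are linearly interpolated.  A side on which the
    trace never drops below half-peak is reported as ``None``.
    """
    t, y = ensemble.t_s, ensemble.mean
    i_peak = int(np.argmax(_smooth3(y)))
    half = y[i_peak] / 2.0

    assembly = disassembly = None
    pre_t, pre_y = t[:i_peak + 1], y[:i_peak + 1]
    below = np.nonzero(pre_y < half)[0]
    if below.size:
        j = below[-1]
        t_cross = np.interp(half, [pre_y[j], pre_y[j + 1]],
                            [pre_t[j], pre_t[j + 1]])
        assembly = float(t[i_peak] - t_cross)
    post_t, post_y = t[i_peak:], y[i_peak:]
    below = np.nonzero(post_y < half)[0]
    if below.size:
        j = below[0]
        t_cross = np.interp(half, [post_y[j], post_y[j - 1]],
                            [post_t[j], post_t[j - 1]])
        disassembly = float(t_cross - t[i_peak])
    return assembly, disassembly
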