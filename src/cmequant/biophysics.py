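"""Closed-form biophysical calculations.

Membrane tension from micropipette aspiration, osmotic pressure from the
concentration jump of a hypotonic shock, capsule surface geometry of a
rod-shaped yeast cell, the membrane reservoir stored in eisosomes, and the
net surface-area budget of post-shock endocytosis/exocytosis modulation.

All functions take the units stated in their docstrings (pressures in Pa,
lengths in µm unless noted) and convert to SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: van 't Hoff conversion from osmolyte concentration difference (M) to
#: osmotic pressure (Pa) at growth temperature: ΔP = RT·ΔC ≈ 2.45e6·ΔC.
OSMOTIC_PA_PER_MOLAR = 2.45e6


@dataclass
class AspirationMeasurement:
    """One micropipette-aspiration reading.

    ``delta_p_pa`` is the aspiration pressure, ``rp_um``/``rc_um`` the
    pipette and cell radii, and ``tongue_um`` the length of the membrane
    tongue pulled into the pipette.
    """

    delta_p_pa: float
    rp_um: float
    rc_um: float
    tongue_um: float

    def __post_init__(self) -> None:
        if self.rp_um >= self.rc_um:
            raise ValueError("pipette radius must be smaller than cell radius")


def tension_from_aspiration(delta_p_pa: float, rp_um: float,
                            rc_um: float) -> float:
    """Membrane tension (N/m) from the Laplace-law aspiration relation.

    σ = ΔP·Rp / [2(1 − Rp/Rc)], where ΔP is the aspiration pressure at
    which the tongue length equals the pipette radius Rp.
    """
    if rp_um >= rc_um:
        raise ValueError("requires Rp < Rc (denominator must be positive)")
    if rp_um <= 0:
        raise ValueError("Rp must be positive")
    if delta_p_pa < 0:
        raise ValueError("aspiration pressure must be non-negative")
    rp_m = rp_um * 1e-6
    return delta_p_pa * rp_m / (2.0 * (1.0 - rp_um / rc_um))


def critical_pressure(pressures_pa: Sequence[float],
                      tongues_um: Sequence[float],
                      rp_um: float) -> Optional[float]:
    """Aspiration pressure at which the tongue length reaches Rp.

    Linearly interpolates the (monotone) tongue-length series at l = Rp.
    Returns ``None`` when the tongue never reaches Rp in the measured
    range ("not reached").
    """
    p = np.asarray(pressures_pa, dtype=float)
    l = np.asarray(tongues_um, dtype=float)
    if p.size != l.size or p.size == 0:
        raise ValueError("pressure and tongue series must have equal length")
    order = np.argsort(p)
    p, l = p[order], l[order]
    if np.any(np.diff(l) < -1e-12):
        raise ValueError("tongue length must be non-decreasing with pressure")
    if l[0] >= rp_um:
        return float(p[0])
    if l[-1] < rp_um:
        return None
    return float(np.interp(rp_um, l, p))


def osmotic_pressure(delta_c_molar: float) -> float:
    """Osmotic pressure change (Pa) for a concentration difference (M)."""
    return OSMOTIC_PA_PER_MOLAR * delta_c_molar


def capsule_area(length_um: float, radius_um: float) -> float:
    """Surface area (µm²) of a cylinder of total length L capped by two
    hemispheres of radius r: 2πr(L − 2r) + 4πr² = 2πrL."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if length_um < 2 * radius_um:
        raise ValueError("capsule requires L >= 2r")
    return 2.0 * math.pi * radius_um * length_um


def eisosome_reservoir(linear_density_um_per_um2: float,
                       diameter_um: float,
                       disassembled_fraction: float = 1.0) -> float:
    """Fraction of plasma-membrane area released by eisosome disassembly.

    Eisosomes are modelled as membrane hemi-cylinders: per unit furrow
    length, πd/2 of membrane is stored above a flat footprint of width d,
    so flattening releases (π/2 − 1)·d per unit length.  With ρ µm of
    eisosome per µm² of membrane, full disassembly releases
    (π/2 − 1)·d·ρ of the surface area (≈4.6% for ρ=1.6 µm/µm², d=50 nm,
    i.e. "about 5%").
    """
    if linear_density_um_per_um2 < 0 or diameter_um < 0:
        raise ValueError("inputs must be non-negative")
    if not 0 <= disassembled_fraction <= 1:
        raise ValueError("disassembled_fraction must be in [0, 1]")
    return (disassembled_fraction * linear_density_um_per_um2
            * (math.pi / 2.0 - 1.0) * diameter_um)


def net_area_budget(endo_rate_pct_per_min: float,
                    endo_reduction_fraction: float,
                    exo_rate_pct_per_min: float,
                    exo_increase_fraction: float,
                    duration_min: float) -> dict:
    """Net % of surface area gained by transiently shifting the
    endocytosis/exocytosis balance.

    Reduced endocytosis leaves membrane on the surface
    (endo_rate·reduction·duration) and increased exocytosis adds more
    (exo_rate·increase·duration).  Components are also reported rounded
    to integer percent, the convention used for summary tables.
    """
    for v in (endo_rate_pct_per_min, endo_reduction_fraction,
              exo_rate_pct_per_min, exo_increase_fraction, duration_min):
        if v < 0:
            raise ValueError("inputs must be non-negative")
    endo_gain = endo_rate_pct_per_min * endo_reduction_fraction * duration_min
    exo_gain = exo_rate_pct_per_min * exo_increase_fraction * duration_min
    return {
        "endo_gain_pct": endo_gain,
        "exo_gain_pct": exo_gain,
        "total_gain_pct": endo_gain + exo_gain,
        "endo_gain_pct_rounded": round(endo_gain),
        "exo_gain_pct_rounded": round(exo_gain),
        "total_gain_pct_rounded": round(endo_gain) + round(exo_gain),
    }


def fold_change(before: float, after: float) -> float:
    """after/before; report convention rounds to one decimal."""
    if before <= 0:
        raise ValueError("before must be positive")
    return after / before


def percent_change(before: float, after: float) -> float:
    """100·(after − before)/before; report convention rounds to integer."""
    if before <= 0:
        raise ValueError("before must be positive")
    return 100.0 * (after - before) / before
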