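"""Spherical-cap geometry of self-spreading hydrogel drops.

A drop of volume V dispensed on a flat surface either keeps a near-spherical
shape (no spreading) or relaxes into a spherical cap of contact radius
a = D_eq / 2 and height h, with

    V = (pi * h / 6) * (3 * a**2 + h**2).

Two scalars summarize the behavior:

* the **spreading ratio** S0 = D_eq / D_ideal, where D_ideal = (6 V / pi)**(1/3)
  is the diameter of the equal-volume sphere — S0 > 1 means the material
  flowed outward;
* the **minimum layer height** h, the unique positive root of the cap-volume
  cubic, which is the thinnest uniform layer the material can self-form at
  that time point.

Records taken every 30 min from the start of crosslinking are classified
into the two processability windows: *self-spreading* strictly before the
gel point and *shape-retaining* from the gel point on (the gel point is when
solid behavior starts, so the boundary is closed on the gel side).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

from scipy.optimize import brentq

__all__ = [
    "DropRecord",
    "SpreadResult",
    "TimecoursePoint",
    "ideal_drop_diameter",
    "spreading_ratio",
    "cap_height",
    "analyze_drop",
    "spreading_timecourse",
]

#: 1 microliter = 1 cubic millimeter, so V in uL is numerically V in mm^3


@dataclass(frozen=True)
class DropRecord:
    """One dispensed drop: volume (uL), equilibrium contact diameter (mm),
    minutes since the onset of crosslinking."""

    volume: float  # uL == mm^3
    D_eq: float  # mm
    time_since_crosslink: float = 0.0  # minutes

    def __post_init__(self):
        if not self.volume > 0:
            raise ValueError("volume must be positive")
        if self.D_eq < 0:
            raise ValueError("D_eq must be non-negative")


@dataclass(frozen=True)
class SpreadResult:
    """Derived spreading geometry for one drop."""

    D_ideal: float  # mm
    S0: float  # dimensionless
    h_min: Optional[float]  # mm; None when the cap model does not apply
    non_wetting: bool = False


@dataclass(frozen=True)
class TimecoursePoint:
    """One time point of a spreading time course."""

    time: float  # minutes
    S0: float
    h_min: Optional[float]
    window: str  # "self_spreading" | "shape_retaining"
    monotonic: bool  # False when S0 rose relative to the previous record


def ideal_drop_diameter(volume: float) -> float:
    """Diameter (mm) of a sphere with the drop's volume (uL)."""
    if not volume > 0:
        raise ValueError("volume must be positive")
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


def spreading_ratio(rec: DropRecord) -> float:
    """S0 = D_eq / D_ideal.  Values above one indicate outward flow."""
    return rec.D_eq / ideal_drop_diameter(rec.volume)


def cap_height(volume: float, D_eq: float, xtol: float = 1e-12) -> float:
    """Height h (mm) of the spherical cap with base diameter ``D_eq`` and
    volume ``volume``.

    Solves (pi h / 6)(3 a^2 + h^2) = V for the unique positive root by
    bracketed root finding on (0, a + D_ideal]; the cubic is strictly
    increasing in h, so the root is unique.  Only valid in the spread
    regime D_eq >= D_ideal.
    """
    if not volume > 0:
        raise ValueError("volume must be positive")
    d_ideal = ideal_drop_diameter(volume)
    if D_eq < d_ideal:
        raise ValueError(
            f"D_eq={D_eq} mm < D_ideal={d_ideal:.4f} mm: drop has not spread, "
            "the cap model does not apply"
        )
    a = D_eq / 2.0

    def f(h: float) -> float:
        return math.pi * h * (3.0 * a * a + h * h) / 6.0 - volume

    hi = a + d_ideal
    return float(brentq(f, 0.0, hi, xtol=xtol))


def cap_volume(h: float, D_eq: float) -> float:
    """Volume (uL) of a spherical cap of height h and base diameter D_eq."""
    a = D_eq / 2.0
    return math.pi * h * (3.0 * a * a + h * h) / 6.0


def analyze_drop(rec: DropRecord) -> SpreadResult:
    """Full spreading geometry for one record.

    ``D_eq = 0`` flags a non-wetting drop (S0 = 0, no cap height); a drop
    with D_eq below D_ideal has not spread, so h_min is undefined there too.
    """
    d_ideal = ideal_drop_diameter(rec.volume)
    if rec.D_eq == 0:
        return SpreadResult(D_ideal=d_ideal, S0=0.0, h_min=None, non_wetting=True)
    s0 = rec.D_eq / d_ideal
    h = cap_height(rec.volume, rec.D_eq) if rec.D_eq >= d_ideal else None
    return SpreadResult(D_ideal=d_ideal, S0=s0, h_min=h)


def spreading_timecourse(
    records: Sequence[DropRecord], gel_point: float
) -> List[TimecoursePoint]:
    """Per-time spreading geometry with processability-window labels.

    Records must be sorted by time.  Each record at t < gel_point is labeled
    ``self_spreading``; t >= gel_point is ``shape_retaining``.  Because
    crosslinking steadily raises viscosity, S0 should not increase between
    consecutive records: violations are flagged (``monotonic=False``) and
    warned about, not rejected.
    """
    times = [r.time_since_crosslink for r in records]
    if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError("records must be sorted by time_since_crosslink")
    out: List[TimecoursePoint] = []
    prev_s0: Optional[float] = None
    for rec in records:
        res = analyze_drop(rec)
        window = (
            "self_spreading"
            if rec.time_since_crosslink < gel_point
            else "shape_retaining"
        )
        monotonic = prev_s0 is None or res.S0 <= prev_s0
        if not monotonic:
            warnings.warn(
                f"S0 increased between consecutive records at "
                f"t={rec.time_since_crosslink} min; spreading should decay "
                "as crosslinking advances",
                stacklevel=2,
            )
        out.append(
            TimecoursePoint(
                time=rec.time_since_crosslink,
                S0=res.S0,
                h_min=res.h_min,
                window=window,
                monotonic=monotonic,
            )
        )
        prev_s0 = res.S0
    return out
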