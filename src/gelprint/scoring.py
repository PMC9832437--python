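"""Shape-fidelity scoring of extrusion-printed fibers and grids.

Printability is quantified against the CAD design by five scalars.  With
``L_real`` the mean measured fiber diameter, ``SD_L`` its sample standard
deviation, ``D_needle`` the needle bore, ``L0x``/``L0y`` the CAD side
lengths, ``Lbx``/``Lby`` the mean printed side lengths per axis and
``SDbx``/``SDby`` their standard deviations:

* spreading factor      ``S  = 100 * L_real / D_needle``  [percent] — the
  relaxation (die swell / slumping) of the fiber after extrusion;
* uniformity            ``U  = (L_real + SD_L) / L_ideal`` with
  ``L_ideal = D_needle * S / 100`` — a perfectly even fiber gives U = 1 and
  any diameter dispersion pushes U above it;
* perimeter coefficient ``Pe = (Lbx + SDbx + Lby + SDby) / (L0x + L0y)``;
* pore coefficient      ``Pr = (Lbx - SDbx + Lby - SDby) / (L0x + L0y)`` —
  Pe and Pr bracket the printed geometry from outside and inside: both are
  exactly 1 for a perfectly adherent, dispersion-free print, and jitter
  splits them to either side of unity;
* printability          ``P  = (U + Pe + Pr) / 3`` — the single-number
  combination of the average fidelity scores, unity for an ideal print.

The standard deviations use the n-1 (sample) convention of common rheometer
and image-analysis software; a single-point measurement has undefined
dispersion and scores U = 1 with a warning.

The module also provides the first-order minimum-extrusion-pressure model:
the pressure that brings the wall shear stress of a cylindrical needle
(radius R, length L) to the material's yield stress,

    dP = 2 * L * tau_y / R,

the laminar-capillary force balance, independent of the constitutive law.
A power-law variant estimating the pressure required to drive a given
volumetric flow rate is exposed as an alternative model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional

import numpy as np

from .rheology import PowerLawFit

__all__ = [
    "GAUGE_INNER_DIAMETER_MM",
    "NeedleGeometry",
    "FiberMeasurement",
    "GridMeasurement",
    "ScoreSet",
    "PressureEstimate",
    "spreading_factor",
    "uniformity_coefficient",
    "perimeter_coefficient",
    "pore_coefficient",
    "printability_coefficient",
    "estimate_extrusion_pressure",
    "score_print",
]

#: nominal inner diameters of common dispensing-needle gauges, mm
GAUGE_INNER_DIAMETER_MM: Dict[str, float] = {
    "18G": 0.84,
    "20G": 0.60,
    "21G": 0.51,
    "22G": 0.41,
    "23G": 0.34,
    "25G": 0.26,
    "27G": 0.21,
}

#: |P - 1| band within which a print still counts as suitable for
#: extrusion-based bioprinting (slight displacement from the optimum)
EBB_SUITABILITY_BAND = 0.10


@dataclass(frozen=True)
class NeedleGeometry:
    """Cylindrical dispensing needle: bore diameter and length, mm."""

    inner_diameter: float
    length: float

    def __post_init__(self):
        if not (self.inner_diameter > 0 and self.length > 0):
            raise ValueError("needle dimensions must be positive")

    @classmethod
    def from_gauge(cls, gauge: str, length: float) -> "NeedleGeometry":
        try:
            d = GAUGE_INNER_DIAMETER_MM[gauge.upper()]
        except KeyError:
            raise ValueError(f"unknown needle gauge {gauge!r}") from None
        return cls(inner_diameter=d, length=length)


@dataclass(frozen=True)
class FiberMeasurement:
    """Fiber diameters sampled at random points along printed fibers.

    The standard protocol samples 10 points on each of 5 fibers.
    """

    diameters: np.ndarray  # mm
    n_fibers: int = 5
    points_per_fiber: int = 10

    def __post_init__(self):
        d = np.asarray(self.diameters, dtype=float).ravel()
        if d.size == 0:
            raise ValueError("diameters must be non-empty")
        if np.any(d <= 0):
            raise ValueError("diameters must be positive")
        object.__setattr__(self, "diameters", d)

    @property
    def mean(self) -> float:
        return float(self.diameters.mean())

    @property
    def sd(self) -> float:
        if self.diameters.size < 2:
            return 0.0
        return float(self.diameters.std(ddof=1))


@dataclass(frozen=True)
class GridMeasurement:
    """Printed-grid side lengths per axis together with their CAD targets."""

    cad_side_x: float  # mm (L0x)
    cad_side_y: float  # mm (L0y)
    printed_sides_x: np.ndarray  # mm
    printed_sides_y: np.ndarray  # mm

    def __post_init__(self):
        for name in ("cad_side_x", "cad_side_y"):
            v = getattr(self, name)
            if math.isfinite(v) and v <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("printed_sides_x", "printed_sides_y"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            if arr.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if np.any(arr <= 0):
                raise ValueError(f"{name} entries must be positive")
            object.__setattr__(self, name, arr)

    def _stats(self, axis: str):
        arr = self.printed_sides_x if axis == "x" else self.printed_sides_y
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    @property
    def Lbx(self) -> float:
        return self._stats("x")[0]

    @property
    def Lby(self) -> float:
        return self._stats("y")[0]

    @property
    def SDbx(self) -> float:
        return self._stats("x")[1]

    @property
    def SDby(self) -> float:
        return self._stats("y")[1]


@dataclass(frozen=True)
class ScoreSet:
    """The five fidelity scores with the measurements that produced them."""

    S: float  # percent
    U: float
    Pe: float
    Pr: float
    P: float
    provenance: Dict[str, object] = dc_field(default_factory=dict)

    @property
    def suitable_for_ebb(self) -> bool:
        """True when P deviates from the optimum by at most 10%."""
        return abs(self.P - 1.0) <= EBB_SUITABILITY_BAND


@dataclass(frozen=True)
class PressureEstimate:
    """Minimum-extrusion-pressure estimate, labeled with its model variant."""

    pressure_kpa: float
    model: str  # "wall_stress" | "power_law_flow"


def _require_cad(gm: GridMeasurement) -> None:
    if not (math.isfinite(gm.cad_side_x) and math.isfinite(gm.cad_side_y)):
        raise ValueError("grid measurement lacks CAD side lengths")


def spreading_factor(fm: FiberMeasurement, ng: NeedleGeometry) -> float:
    """S = 100 * L_real / D_needle, in percent."""
    return 100.0 * fm.mean / ng.inner_diameter


def uniformity_coefficient(fm: FiberMeasurement, ng: NeedleGeometry) -> float:
    """U = (L_real + SD_L) / L_ideal with L_ideal = D_needle * S / 100.

    Equals 1 exactly for a dispersion-free fiber.  A single measurement
    point leaves the dispersion undefined and scores U = 1 with a warning.
    """
    if fm.diameters.size < 2:
        warnings.warn(
            "single measurement point: fiber dispersion undefined, U = 1",
            stacklevel=2,
        )
        return 1.0
    s = spreading_factor(fm, ng)
    l_ideal = ng.inner_diameter * s / 100.0
    return (fm.mean + fm.sd) / l_ideal


def perimeter_coefficient(gm: GridMeasurement) -> float:
    """Pe = (Lbx + SDbx + Lby + SDby) / (L0x + L0y)."""
    _require_cad(gm)
    return (gm.Lbx + gm.SDbx + gm.Lby + gm.SDby) / (gm.cad_side_x + gm.cad_side_y)


def pore_coefficient(gm: GridMeasurement) -> float:
    """Pr = (Lbx - SDbx + Lby - SDby) / (L0x + L0y)."""
    _require_cad(gm)
    return (gm.Lbx - gm.SDbx + gm.Lby - gm.SDby) / (gm.cad_side_x + gm.cad_side_y)


def printability_coefficient(U: float, Pe: float, Pr: float) -> float:
    """P = (U + Pe + Pr) / 3; unity when every component is ideal."""
    vals = (U, Pe, Pr)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("component scores must be finite")
    return sum(vals) / 3.0


def estimate_extrusion_pressure(
    yield_stress: float,
    ng: NeedleGeometry,
    flow: Optional[PowerLawFit] = None,
    model: str = "wall_stress",
    flow_rate_ul_s: Optional[float] = None,
) -> PressureEstimate:
    """Minimum extrusion pressure (kPa) for a cylindrical needle.

    ``wall_stress`` (default): pressure at which the wall shear stress
    reaches ``yield_stress`` — dP = 2 L tau_y / R, the laminar force
    balance, valid for any constitutive law.

    ``power_law_flow``: pressure required to drive ``flow_rate_ul_s``
    through the needle for a power-law fluid (Rabinowitsch-Mooney),
    dP = (2 K L / R) * ((3n + 1)/n * Q / (pi R^3))**n; needs ``flow`` and
    ``flow_rate_ul_s``.
    """
    if not yield_stress > 0:
        raise ValueError("yield_stress must be positive")
    R = ng.inner_diameter / 2.0 * 1e-3  # m
    L = ng.length * 1e-3  # m
    if model == "wall_stress":
        dp = 2.0 * L * yield_stress / R  # Pa
    elif model == "power_law_flow":
        if flow is None or flow_rate_ul_s is None:
            raise ValueError("power_law_flow needs a PowerLawFit and a flow rate")
        q = flow_rate_ul_s * 1e-9  # m^3/s
        n = flow.n
        dp = (2.0 * flow.K * L / R) * ((3.0 * n + 1.0) / n * q / (math.pi * R**3)) ** n
    else:
        raise ValueError(f"unknown pressure model {model!r}")
    return PressureEstimate(pressure_kpa=dp / 1000.0, model=model)


def score_print(
    fm: FiberMeasurement, gm: GridMeasurement, ng: NeedleGeometry
) -> ScoreSet:
    """Compute the full fidelity score set for one print."""
    s = spreading_factor(fm, ng)
    u = uniformity_coefficient(fm, ng)
    pe = perimeter_coefficient(gm)
    pr = pore_coefficient(gm)
    p = printability_coefficient(u, pe, pr)
    provenance = {
        "n_fiber_points": int(fm.diameters.size),
        "fiber_mean_mm": fm.mean,
        "fiber_sd_mm": fm.sd,
        "needle_inner_diameter_mm": ng.inner_diameter,
        "needle_length_mm": ng.length,
        "Lbx_mm": gm.Lbx,
        "Lby_mm": gm.Lby,
        "SDbx_mm": gm.SDbx,
        "SDby_mm": gm.SDby,
        "cad_side_x_mm": gm.cad_side_x,
        "cad_side_y_mm": gm.cad_side_y,
    }
    return ScoreSet(S=s, U=u, Pe=pe, Pr=pr, P=p, provenance=provenance)
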