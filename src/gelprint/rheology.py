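"""Scalar characterization of oscillatory-rheometry sweeps and flow curves.

The analyses here turn raw rheometer exports into the handful of scalars that
drive bioink processing decisions:

* **gel point** — the time at which the storage modulus G' first overtakes the
  loss modulus G'' in a time sweep, i.e. the onset of solid-like behavior;
* **yield point** — the oscillatory stress amplitude at which G'' overtakes G'
  in an amplitude sweep, i.e. the onset of flow during extrusion;
* **recovery** — the fraction of the pre-yield G' plateau recovered after a
  three-interval (rest / yield / rest) protocol;
* **LVE summary** — band-averaged G', G'' and tan(delta) from a frequency sweep
  within the linear viscoelastic region;
* **power-law fit** — consistency index K and flow index n of the
  shear-thinning law eta = K * gamma_dot**(n - 1).

Moduli routinely span decades, so crossing localization interpolates the
*logarithm* of the moduli: linearly in time for time sweeps and in log-stress
for amplitude sweeps.  A crossing only counts when the new sign of (G' - G'')
persists for at least two consecutive samples, which rejects single-point
noise flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "TEST_TYPES",
    "RheoSweep",
    "FlowCurve",
    "GelPointResult",
    "YieldPointResult",
    "PowerLawFit",
    "RecoveryResult",
    "LVESummary",
    "NoSolidRegimeError",
    "detect_gel_point",
    "detect_yield_point",
    "fit_power_law",
    "compute_recovery",
    "summarize_lve",
    "read_rheo_table",
    "write_rheo_table",
]

TEST_TYPES = ("time_sweep", "freq_sweep", "amplitude_sweep", "recovery")

#: abscissa units expected per test type in the CSV dialect
_ABSCISSA_UNITS = {
    "time_sweep": "min",
    "freq_sweep": "Hz",
    "amplitude_sweep": "Pa",
    "recovery": "s",
    "flow_curve": "1/s",
}

_TABLE_COLUMNS = [
    "test_type",
    "abscissa",
    "abscissa_units",
    "Gp_Pa",
    "Gpp_Pa",
    "eta_Pa_s",
    "temp_C",
]


class NoSolidRegimeError(ValueError):
    """Raised when an amplitude sweep starts with G'' >= G' already.

    Such a sample has no solid regime to yield from, which is a distinct
    situation from "solid throughout the probed range" (no crossing found).
    """


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class RheoSweep:
    """One oscillatory rheometer test record.

    Parameters
    ----------
    test_type : str
        One of ``time_sweep``, ``freq_sweep``, ``amplitude_sweep``,
        ``recovery``.
    abscissa : array
        Minutes for time sweeps, Hz for frequency sweeps, Pa of oscillatory
        stress amplitude for amplitude sweeps, seconds for recovery traces.
        Strictly increasing.
    Gp, Gpp : array
        Storage and loss moduli in Pa, non-negative, same length as
        ``abscissa``.
    temperature : float
        Plate temperature in deg C.  Carried as metadata only: in the
        25-37 deg C range the crosslinking kinetics of internally gelled
        alginates are temperature-insensitive, so no correction is applied.
    """

    test_type: str
    abscissa: np.ndarray
    Gp: np.ndarray
    Gpp: np.ndarray
    temperature: float = 37.0

    def __post_init__(self):
        if self.test_type not in TEST_TYPES:
            raise ValueError(f"unknown test_type {self.test_type!r}")
        object.__setattr__(self, "abscissa", _as_1d(self.abscissa, "abscissa"))
        object.__setattr__(self, "Gp", _as_1d(self.Gp, "Gp"))
        object.__setattr__(self, "Gpp", _as_1d(self.Gpp, "Gpp"))
        n = self.abscissa.size
        if self.Gp.size != n or self.Gpp.size != n:
            raise ValueError("abscissa, Gp and Gpp must have equal lengths")
        if n and np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if np.any(self.Gp < 0) or np.any(self.Gpp < 0):
            raise ValueError("moduli must be non-negative")

    @property
    def tan_delta(self) -> np.ndarray:
        """Loss tangent tan(delta) = G''/G', pointwise."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.Gpp / self.Gp

    def __len__(self) -> int:
        return self.abscissa.size


@dataclass(frozen=True)
class FlowCurve:
    """Steady-shear viscosity record: eta(gamma_dot)."""

    shear_rate: np.ndarray
    viscosity: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shear_rate", _as_1d(self.shear_rate, "shear_rate"))
        object.__setattr__(self, "viscosity", _as_1d(self.viscosity, "viscosity"))
        if self.shear_rate.size != self.viscosity.size:
            raise ValueError("shear_rate and viscosity must have equal lengths")
        if self.shear_rate.size and np.any(np.diff(self.shear_rate) <= 0):
            raise ValueError("shear_rate must be strictly increasing")
        if np.any(self.shear_rate <= 0) or np.any(self.viscosity <= 0):
            raise ValueError("shear_rate and viscosity must be positive")

    def __len__(self) -> int:
        return self.shear_rate.size


@dataclass(frozen=True)
class GelPointResult:
    """Location of the G'-G'' crossover in a time sweep, if any."""

    crossover_time: Optional[float]  # minutes
    method: str = "crossover"
    bracketing_indices: Optional[Tuple[int, int]] = None

    @property
    def gelled(self) -> bool:
        return self.crossover_time is not None


@dataclass(frozen=True)
class YieldPointResult:
    """Oscillatory stress amplitude at which G'' overtakes G', if any."""

    sigma_y: Optional[float]  # Pa
    bracketing_indices: Optional[Tuple[int, int]] = None

    @property
    def yields(self) -> bool:
        return self.sigma_y is not None


@dataclass(frozen=True)
class PowerLawFit:
    """Ostwald-de Waele fit eta = K * gamma_dot**(n-1)."""

    K: float  # Pa s^n
    n: float  # dimensionless flow index
    r_squared: float


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of a three-interval recovery analysis."""

    recovery: float  # plateau_final / plateau_initial
    plateau_initial: float  # Pa, median G' over the last half of interval 1
    plateau_final: float  # Pa, median G' over the last half of interval 3


@dataclass(frozen=True)
class LVESummary:
    """Band-averaged linear-viscoelastic summary of a frequency sweep."""

    mean_Gp: float
    mean_Gpp: float
    mean_tan_delta: float
    band: Tuple[float, float] = (0.1, 22.5)
    n_points: int = 0


# ---------------------------------------------------------------------------
# crossing detection
# ---------------------------------------------------------------------------

def _find_sustained_crossing(diff: np.ndarray, direction: int, persistence: int = 2):
    """Index pair bracketing the first sustained sign change of *diff*.

    ``direction=+1`` looks for negative-to-positive (gelation), ``-1`` for
    positive-to-negative (yielding).  The new sign must hold for at least
    ``persistence`` consecutive samples (or to the end of the series).
    Returns ``(i, j)`` with the crossing between samples i and j, or
    ``(i, i)`` for an exact tie at sample i, or ``None``.
    """
    d = direction * np.asarray(diff, dtype=float)
    n = d.size
    i = 0
    # the series must start on the "before" side; skip an initial after-side run
    while i < n and d[i] >= 0:
        i += 1
    while i < n:
        if d[i] < 0:
            i += 1
            continue
        # candidate crossing: d[i-1] < 0, d[i] >= 0
        window = d[i : i + persistence]
        if np.all(window >= 0) and np.any(window > 0):
            return (i, i) if d[i] == 0 else (i - 1, i)
        i += 1
    return None


def _interp_crossing(x0, x1, f0, f1) -> float:
    """Zero of the secant through (x0, f0), (x1, f1)."""
    if f1 == f0:  # pragma: no cover - bracketing guarantees a sign change
        return 0.5 * (x0 + x1)
    return x0 - f0 * (x1 - x0) / (f1 - f0)


def _log_modulus_diff(sweep: RheoSweep, i: int) -> float:
    gp, gpp = sweep.Gp[i], sweep.Gpp[i]
    if gp > 0 and gpp > 0:
        return float(np.log(gp) - np.log(gpp))
    return float(gp - gpp)  # degenerate zero modulus: fall back to linear


def detect_gel_point(sweep: RheoSweep, persistence: int = 2) -> GelPointResult:
    """Locate the gel point of a time sweep.

    The gel point is the first *sustained* crossing where G' overtakes G''.
    It is localized by linear interpolation of log(G') - log(G'') against
    time between the two bracketing samples; an exact tie at a sample
    reports that sample's time.  A sweep in which G' never overtakes G''
    returns an absent result rather than raising.
    """
    if sweep.test_type != "time_sweep":
        raise ValueError("detect_gel_point requires a time_sweep record")
    if len(sweep) < 4:
        raise ValueError("need at least 4 samples to detect a gel point")
    diff = sweep.Gp - sweep.Gpp
    bracket = _find_sustained_crossing(diff, direction=+1, persistence=persistence)
    if bracket is None:
        return GelPointResult(crossover_time=None)
    i, j = bracket
    if i == j:
        return GelPointResult(float(sweep.abscissa[i]), bracketing_indices=(i, j))
    f0 = _log_modulus_diff(sweep, i)
    f1 = _log_modulus_diff(sweep, j)
    t = _interp_crossing(sweep.abscissa[i], sweep.abscissa[j], f0, f1)
    return GelPointResult(float(t), bracketing_indices=(i, j))


def detect_yield_point(sweep: RheoSweep, persistence: int = 2) -> YieldPointResult:
    """Locate the yield point of an oscillatory stress amplitude sweep.

    The yield point is the stress amplitude at which G'' starts to prevail
    over G'.  Interpolation is log-log (log-modulus difference against
    log-stress).  If G' < G'' already at the lowest amplitude there is no
    solid regime at all and :class:`NoSolidRegimeError` is raised; a sweep
    that remains solid throughout returns an absent result instead.
    """
    if sweep.test_type != "amplitude_sweep":
        raise ValueError("detect_yield_point requires an amplitude_sweep record")
    if len(sweep) < 2:
        raise ValueError("need at least 2 samples to detect a yield point")
    if sweep.Gp[0] < sweep.Gpp[0]:
        raise NoSolidRegimeError(
            "G' < G'' already at the lowest amplitude: no solid regime"
        )
    diff = sweep.Gp - sweep.Gpp
    bracket = _find_sustained_crossing(diff, direction=-1, persistence=persistence)
    if bracket is None:
        return YieldPointResult(sigma_y=None)
    i, j = bracket
    if i == j:
        return YieldPointResult(float(sweep.abscissa[i]), bracketing_indices=(i, j))
    f0 = _log_modulus_diff(sweep, i)
    f1 = _log_modulus_diff(sweep, j)
    logs = _interp_crossing(
        np.log(sweep.abscissa[i]), np.log(sweep.abscissa[j]), f0, f1
    )
    return YieldPointResult(float(np.exp(logs)), bracketing_indices=(i, j))


# ---------------------------------------------------------------------------
# power-law viscosity fit
# ---------------------------------------------------------------------------

def fit_power_law(curve: FlowCurve) -> PowerLawFit:
    """Least-squares fit of log(eta) on log(gamma_dot).

    Slope is n - 1, intercept is log(K).  Exact on noiseless power-law data.
    """
    if len(curve) < 3:
        raise ValueError("need at least 3 points for a power-law fit")
    x = np.log(curve.shear_rate)
    y = np.log(curve.viscosity)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(K=float(np.exp(intercept)), n=float(slope + 1.0), r_squared=r2)


# ---------------------------------------------------------------------------
# recovery & LVE
# ---------------------------------------------------------------------------

_DEFAULT_INTERVALS = ((0.0, 100.0), (100.0, 300.0), (300.0, 400.0))


def compute_recovery(
    trace: RheoSweep,
    interval_bounds: Sequence[Tuple[float, float]] = _DEFAULT_INTERVALS,
) -> RecoveryResult:
    """Recovery fraction from a three-interval (rest/yield/rest) trace.

    The protocol applies three strain amplitudes (low, high, low) for 100,
    200 and 100 s.  Recovery is the median G' over the last half of the
    third interval divided by the median over the last half of the first.
    Every interval must contain samples; the yielded interval is required
    even though it does not enter the ratio, because its absence means the
    protocol was not followed.
    """
    if trace.test_type != "recovery":
        raise ValueError("compute_recovery requires a recovery record")
    if len(interval_bounds) != 3:
        raise ValueError("exactly three intervals are required")
    t = trace.abscissa
    medians = []
    for k, (lo, hi) in enumerate(interval_bounds):
        if hi <= lo:
            raise ValueError(f"interval {k + 1} bounds are not increasing")
        mask = (t >= lo) & (t < hi)
        if not mask.any():
            raise ValueError(f"no samples cover interval {k + 1} [{lo}, {hi}) s")
        half = (t >= (lo + hi) / 2.0) & mask
        medians.append(float(np.median(trace.Gp[half if half.any() else mask])))
    plateau1, _, plateau3 = medians
    if plateau1 <= 0:
        raise ValueError("initial plateau is non-positive; recovery undefined")
    return RecoveryResult(
        recovery=plateau3 / plateau1,
        plateau_initial=plateau1,
        plateau_final=plateau3,
    )


def summarize_lve(
    sweep: RheoSweep, band: Tuple[float, float] = (0.1, 22.5)
) -> LVESummary:
    """Arithmetic means of G', G'' and tan(delta) over a frequency band.

    tan(delta) is computed pointwise as G''/G' and then averaged.
    """
    if sweep.test_type != "freq_sweep":
        raise ValueError("summarize_lve requires a freq_sweep record")
    lo, hi = band
    if hi <= lo:
        raise ValueError("band bounds must be increasing")
    f = sweep.abscissa
    if lo < f[0] or hi > f[-1]:
        raise ValueError(
            f"band [{lo}, {hi}] Hz outside the sweep range [{f[0]}, {f[-1]}] Hz"
        )
    mask = (f >= lo) & (f <= hi)
    gp = sweep.Gp[mask]
    gpp = sweep.Gpp[mask]
    return LVESummary(
        mean_Gp=float(gp.mean()),
        mean_Gpp=float(gpp.mean()),
        mean_tan_delta=float((gpp / gp).mean()),
        band=(lo, hi),
        n_points=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_rheo_table(record: Union[RheoSweep, FlowCurve], path) -> None:
    """Write a sweep or flow curve in the shared rheometer CSV dialect.

    Header: ``test_type, abscissa, abscissa_units, Gp_Pa, Gpp_Pa, eta_Pa_s,
    temp_C``.  Flow curves leave the modulus columns empty; sweeps leave the
    viscosity column empty.
    """
    if isinstance(record, FlowCurve):
        df = pd.DataFrame(
            {
                "test_type": "flow_curve",
                "abscissa": record.shear_rate,
                "abscissa_units": _ABSCISSA_UNITS["flow_curve"],
                "Gp_Pa": np.nan,
                "Gpp_Pa": np.nan,
                "eta_Pa_s": record.viscosity,
                "temp_C": np.nan,
            }
        )
    else:
        df = pd.DataFrame(
            {
                "test_type": record.test_type,
                "abscissa": record.abscissa,
                "abscissa_units": _ABSCISSA_UNITS[record.test_type],
                "Gp_Pa": record.Gp,
                "Gpp_Pa": record.Gpp,
                "eta_Pa_s": np.nan,
                "temp_C": record.temperature,
            }
        )
    df.to_csv(path, index=False)


#: accepted abscissa units and the factor converting them to the canonical
#: unit of each test type
_UNIT_FACTORS = {
    "time_sweep": {"min": 1.0, "s": 1.0 / 60.0, "h": 60.0},
    "freq_sweep": {"Hz": 1.0, "rad/s": 1.0 / (2.0 * np.pi)},
    "amplitude_sweep": {"Pa": 1.0, "kPa": 1000.0},
    "recovery": {"s": 1.0, "min": 60.0},
    "flow_curve": {"1/s": 1.0, "s^-1": 1.0},
}


def read_rheo_table(path) -> Union[RheoSweep, FlowCurve]:
    """Read a rheometer CSV written in the shared dialect.

    Units are normalized to the canonical unit of the declared test type
    (minutes / Hz / Pa / seconds / 1/s).  Rows out of abscissa order are
    sorted with a warning; unknown columns, unknown units, or a modulus
    column missing for a sweep raise ``ValueError``.
    """
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(_TABLE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown columns in rheometer table: {sorted(unknown)}")
    for col in ("test_type", "abscissa", "abscissa_units"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    test_types = df["test_type"].unique()
    if len(test_types) != 1:
        raise ValueError("a rheometer table must contain exactly one test_type")
    test_type = str(test_types[0])
    if test_type not in _UNIT_FACTORS:
        raise ValueError(f"unknown test_type {test_type!r}")

    units = df["abscissa_units"].unique()
    if len(units) != 1:
        raise ValueError("mixed abscissa units in one table")
    unit = str(units[0])
    try:
        factor = _UNIT_FACTORS[test_type][unit]
    except KeyError:
        raise ValueError(f"unit {unit!r} is not valid for a {test_type}") from None

    x = df["abscissa"].to_numpy(dtype=float) * factor
    order = np.argsort(x, kind="stable")
    if np.any(np.diff(x) <= 0):
        warnings.warn("rows were not sorted by abscissa; sorting", stacklevel=2)
        df = df.iloc[order].reset_index(drop=True)
        x = x[order]

    if test_type == "flow_curve":
        if "eta_Pa_s" not in df.columns or df["eta_Pa_s"].isna().any():
            raise ValueError("flow_curve table requires a complete eta_Pa_s column")
        return FlowCurve(shear_rate=x, viscosity=df["eta_Pa_s"].to_numpy(dtype=float))

    for col in ("Gp_Pa", "Gpp_Pa"):
        if col not in df.columns or df[col].isna().any():
            raise ValueError(f"{test_type} table requires a complete {col} column")
    temp = 37.0
    if "temp_C" in df.columns and df["temp_C"].notna().any():
        temp = float(df["temp_C"].dropna().iloc[0])
    return RheoSweep(
        test_type=test_type,
        abscissa=x,
        Gp=df["Gp_Pa"].to_numpy(dtype=float),
        Gpp=df["Gpp_Pa"].to_numpy(dtype=float),
        temperature=temp,
    )
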