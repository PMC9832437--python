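"""Seeded synthetic generators for every input the characterization pipeline consumes.

Each generator is deterministic given its ``seed``, returns its ground truth
alongside the data (either because the truth *is* the parameter set, or as
extra fields carrying realized per-object values), and produces analytically
exact curves when the noise level is zero.

The rheological curve shapes are phenomenological stand-ins, parameterized
directly by the quantity the downstream detector is meant to recover:

* gelation time sweeps use saturating-exponential rises for G' and G'' with
  the G'' timescale solved so the G'-G'' crossing lands exactly at the
  requested crossover time;
* amplitude sweeps impose tan(delta) = (sigma / sigma_y)**k, which yields an
  exact, unique crossing at the yield stress with a loss-modulus bump near it;
* flow curves are exact power laws eta = K * gamma_dot**(n-1);
* noise is multiplicative log-normal, instrument-like and positivity-
  preserving.

Images are rendered binary at 8-bit depth (0 / 255) with a constant
micrometer-per-pixel scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import tifffile

from .rheology import FlowCurve, RheoSweep

__all__ = [
    "GelationParams",
    "PowerLawParams",
    "YieldSweepParams",
    "PrintJobTruth",
    "ImageField",
    "SimulatedPrint",
    "simulate_gelation_timesweep",
    "simulate_flow_curve",
    "simulate_yield_sweep",
    "simulate_recovery_trace",
    "simulate_frequency_sweep",
    "simulate_print_images",
    "simulate_drop_frames",
    "simulate_particle_field",
    "simulate_nuclei_planes",
    "write_image",
    "read_image",
]

PLANE_LABELS = ("top", "middle", "bottom", "none")


@dataclass(frozen=True)
class ImageField:
    """A 2-D grayscale micrograph with its physical scale.

    ``pixels`` is an 8-bit array; ``scale`` is micrometers per pixel and is
    constant across the image; ``plane_label`` marks the optical plane for
    embedded-cell stacks.
    """

    pixels: np.ndarray
    scale: float  # um per pixel
    plane_label: str = "none"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.floating) and px.max(initial=0) <= 1.0:
                px = (px * 255).round().astype(np.uint8)
            else:
                px = np.clip(px, 0, 255).astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if not self.scale > 0:
            raise ValueError("scale must be positive (um per pixel)")
        if self.plane_label not in PLANE_LABELS:
            raise ValueError(f"plane_label must be one of {PLANE_LABELS}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


def write_image(field: ImageField, path) -> Path:
    """Write an 8-bit grayscale TIFF plus a JSON sidecar with the scale."""
    path = Path(path)
    tifffile.imwrite(path, field.pixels)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"um_per_px": field.scale, "plane_label": field.plane_label})
    )
    return path


def read_image(path) -> ImageField:
    """Read a TIFF/PNG written by :func:`write_image` (or with a manual sidecar)."""
    path = Path(path)
    pixels = tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff") else None
    if pixels is None:
        from imageio.v3 import imread  # PNG fallback

        pixels = imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing scale sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return ImageField(
        pixels=pixels,
        scale=float(meta["um_per_px"]),
        plane_label=meta.get("plane_label", "none"),
    )


# ---------------------------------------------------------------------------
# rheology generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GelationParams:
    """Ground truth for a gelation time sweep.

    ``crossover_time`` (minutes) is where G' overtakes G''; the saturating
    plateaus and the G' rise timescale shape the curves around it.  The
    construction requires G'(t_c) < Gpp_plateau, i.e. the crossing happens
    while the moduli are still rising — the physically meaningful regime.
    """

    crossover_time: float  # minutes
    Gp_plateau: float = 1000.0  # Pa
    Gpp_plateau: float = 300.0  # Pa
    rise_timescale: Optional[float] = None  # minutes; default 5 * crossover_time
    noise_sd_rel: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.crossover_time > 0:
            raise ValueError("crossover_time must be positive")
        if not (self.Gp_plateau > 0 and self.Gpp_plateau > 0):
            raise ValueError("modulus plateaus must be positive")
        if self.rise_timescale is None:
            object.__setattr__(self, "rise_timescale", 5.0 * self.crossover_time)
        if not self.rise_timescale > 0:
            raise ValueError("rise_timescale must be positive")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be non-negative")


def simulate_gelation_timesweep(
    params: GelationParams, sampling: Sequence[float]
) -> RheoSweep:
    """Generate a time sweep whose noiseless G'-G'' crossing lies exactly at
    ``params.crossover_time``.

    G'(t) = Gp_plateau * (1 - exp(-t / tau)); G'' uses the same form with its
    timescale solved so G''(t_c) = G'(t_c).  When Gp_plateau > Gpp_plateau
    the loss modulus rises faster, giving the liquid-to-solid crossover;
    the modulus ratio is monotone in time, so the crossing is unique.
    Multiplicative log-normal noise leaves the expected (median) crossing
    unchanged.
    """
    t = np.asarray(sampling, dtype=float)
    if t.size < 10:
        raise ValueError("sampling grid needs at least 10 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sampling grid must be strictly increasing")
    if np.any(t < 0):
        raise ValueError("time samples must be non-negative")

    tc, tau = params.crossover_time, params.rise_timescale
    # solve the G'' timescale so that the curves meet exactly at t = tc
    r = (params.Gp_plateau / params.Gpp_plateau) * (-np.expm1(-tc / tau))
    if not 0.0 < r < 1.0:
        raise ValueError(
            "crossover not attainable: G'(crossover_time) must stay below "
            "Gpp_plateau; increase rise_timescale or Gpp_plateau"
        )
    tau_pp = -tc / np.log1p(-r)

    Gp = params.Gp_plateau * (-np.expm1(-t / tau))
    Gpp = params.Gpp_plateau * (-np.expm1(-t / tau_pp))
    if params.noise_sd_rel > 0:
        rng = np.random.default_rng(params.seed)
        Gp = Gp * np.exp(params.noise_sd_rel * rng.standard_normal(t.size))
        Gpp = Gpp * np.exp(params.noise_sd_rel * rng.standard_normal(t.size))
    return RheoSweep(test_type="time_sweep", abscissa=t, Gp=Gp, Gpp=Gpp)


@dataclass(frozen=True)
class PowerLawParams:
    """Ground truth for a shear-thinning flow curve eta = K * gamma_dot**(n-1)."""

    K: float  # consistency index, Pa s^n
    n: float  # flow index, 0 < n <= 1
    rate_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(0, 2, 25)
    )  # 1/s, the 1-100 1/s protocol range
    noise_sd_rel: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.K > 0:
            raise ValueError("K must be positive")
        if not 0 < self.n <= 1:
            raise ValueError("flow index n must satisfy 0 < n <= 1")
        grid = np.asarray(self.rate_grid, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) <= 0) or np.any(grid <= 0):
            raise ValueError("rate_grid must be positive and strictly increasing")
        object.__setattr__(self, "rate_grid", grid)
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be non-negative")


def simulate_flow_curve(params: PowerLawParams) -> FlowCurve:
    """Power-law viscosity samples with optional multiplicative log-normal noise."""
    eta = params.K * params.rate_grid ** (params.n - 1.0)
    if params.noise_sd_rel > 0:
        rng = np.random.default_rng(params.seed)
        eta = eta * np.exp(params.noise_sd_rel * rng.standard_normal(eta.size))
    return FlowCurve(shear_rate=params.rate_grid.copy(), viscosity=eta)


@dataclass(frozen=True)
class YieldSweepParams:
    """Ground truth for an oscillatory stress amplitude sweep.

    ``sigma_y`` is the stress where G' = G''.  The default grid extends past
    the 0.1-100 Pa protocol window because engineered-hydrogel yield stresses
    can exceed 100 Pa.
    """

    sigma_y: float  # Pa
    Gp0: float = 2000.0  # Pa, low-amplitude storage plateau
    Gpp0: float = 400.0  # Pa, low-amplitude loss plateau
    stress_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-1, np.log10(400.0), 80)
    )
    noise_sd_rel: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.sigma_y > 0:
            raise ValueError("sigma_y must be positive")
        if not (self.Gp0 > 0 and self.Gpp0 > 0):
            raise ValueError("moduli must be positive")
        if not self.Gp0 > self.Gpp0:
            raise ValueError("Gp0 must exceed Gpp0 (solid at rest)")
        grid = np.asarray(self.stress_grid, dtype=float)
        if grid.size < 4 or np.any(np.diff(grid) <= 0) or np.any(grid <= 0):
            raise ValueError("stress_grid must be positive and strictly increasing")
        if not grid[0] < self.sigma_y:
            raise ValueError("sigma_y must lie above the lowest grid stress")
        object.__setattr__(self, "stress_grid", grid)
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be non-negative")


def simulate_yield_sweep(params: YieldSweepParams) -> RheoSweep:
    """Amplitude sweep with G' > G'' strictly below sigma_y and G'' > G' above.

    The loss tangent is imposed as tan(delta) = (sigma / sigma_y)**k with the
    exponent anchored so that tan(delta) at the lowest grid stress equals
    Gpp0/Gp0.  G' decays logistically in log-stress around sigma_y; G''
    consequently shows a bump near the yield point, as amplitude sweeps of
    yield-stress gels do.
    """
    sigma = params.stress_grid
    x = sigma / params.sigma_y
    k = np.log(params.Gp0 / params.Gpp0) / np.log(params.sigma_y / sigma[0])
    Gp = params.Gp0 / (1.0 + x**2)
    Gpp = Gp * x**k
    if params.noise_sd_rel > 0:
        # common-mode noise preserves the strict G'/G'' ordering either side
        # of sigma_y, which is the generator's contractual invariant
        rng = np.random.default_rng(params.seed)
        common = np.exp(params.noise_sd_rel * rng.standard_normal(sigma.size))
        Gp, Gpp = Gp * common, Gpp * common
    return RheoSweep(test_type="amplitude_sweep", abscissa=sigma, Gp=Gp, Gpp=Gpp)


def simulate_recovery_trace(
    plateau1: float,
    yielded_level: float,
    recovery_fraction: float,
    seed: int = 0,
    noise_sd_rel: float = 0.0,
    dt: float = 2.0,
    interval_durations: Tuple[float, float, float] = (100.0, 200.0, 100.0),
    transition_timescale: float = 5.0,
) -> RheoSweep:
    """Three-interval recovery trace (rest 100 s / yield 200 s / rest 100 s).

    G' holds ``plateau1`` in the first interval, drops to ``yielded_level``
    in the second, and settles at ``recovery_fraction * plateau1`` in the
    third, with short exponential transitions.  G'' is set to 25% of G' in
    the solid intervals and to twice the yielded G' level while yielded, so
    the trace is viscous-dominated exactly when the material is flowing.
    """
    if not plateau1 > 0:
        raise ValueError("plateau1 must be positive")
    if yielded_level < 0:
        raise ValueError("yielded_level must be non-negative")
    if yielded_level > plateau1:
        raise ValueError("yielding must lower G': yielded_level > plateau1")
    if not 0.0 <= recovery_fraction <= 1.0:
        raise ValueError("recovery_fraction must lie in [0, 1]")
    d1, d2, d3 = interval_durations
    t = np.arange(dt / 2.0, d1 + d2 + d3, dt)  # sample at interval midpoints
    targets_gp = np.where(
        t < d1, plateau1, np.where(t < d1 + d2, yielded_level, recovery_fraction * plateau1)
    )
    # exponential approach to the current target, restarting at each switch
    gp = np.empty_like(t)
    for i, (ti, tgt) in enumerate(zip(t, targets_gp)):
        if ti < d1:
            t0, prev = 0.0, plateau1  # assume equilibrated at load
        elif ti < d1 + d2:
            t0, prev = d1, plateau1
        else:
            t0, prev = d1 + d2, yielded_level
        gp[i] = tgt + (prev - tgt) * np.exp(-(ti - t0) / transition_timescale)
    solid = (t < d1) | (t >= d1 + d2)
    gpp = np.where(solid, 0.25 * gp, np.maximum(2.0 * gp, 1e-9))
    if noise_sd_rel > 0:
        rng = np.random.default_rng(seed)
        gp = gp * np.exp(noise_sd_rel * rng.standard_normal(t.size))
        gpp = gpp * np.exp(noise_sd_rel * rng.standard_normal(t.size))
    return RheoSweep(test_type="recovery", abscissa=t, Gp=gp, Gpp=gpp)


def simulate_frequency_sweep(
    Gp_level: float = 1500.0,
    Gpp_level: float = 300.0,
    freq_grid: Optional[np.ndarray] = None,
    slope: float = 0.05,
    noise_sd_rel: float = 0.0,
    seed: int = 0,
) -> RheoSweep:
    """Weakly frequency-dependent LVE sweep for a crosslinked gel.

    G' and G'' follow shallow power laws of frequency (exponent ``slope``),
    the signature of a developed elastic network; levels are the values at
    1 Hz.
    """
    if freq_grid is None:
        freq_grid = np.logspace(-1, np.log10(22.5), 30)
    f = np.asarray(freq_grid, dtype=float)
    if not (Gp_level > 0 and Gpp_level > 0):
        raise ValueError("modulus levels must be positive")
    gp = Gp_level * f**slope
    gpp = Gpp_level * f**slope
    if noise_sd_rel > 0:
        rng = np.random.default_rng(seed)
        gp = gp * np.exp(noise_sd_rel * rng.standard_normal(f.size))
        gpp = gpp * np.exp(noise_sd_rel * rng.standard_normal(f.size))
    return RheoSweep(test_type="freq_sweep", abscissa=f, Gp=gp, Gpp=gpp)


# ---------------------------------------------------------------------------
# print-job image generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrintJobTruth:
    """Ground-truth geometry of a synthetic print job.

    Defaults mirror a standard extrusion setup: a 22G cylindrical needle
    (0.41 mm bore, 12.5 mm long) printing a 20 x 20 mm grid-infill square.
    """

    needle_inner_diameter: float = 0.41  # mm
    needle_length: float = 12.5  # mm
    cad_side_x: float = 20.0  # mm
    cad_side_y: float = 20.0  # mm
    true_fiber_diameter: float = 0.5  # mm
    fiber_waviness_amp: float = 0.0  # mm
    side_jitter_sd: float = 0.0  # mm
    seed: int = 0

    def __post_init__(self):
        for name in (
            "needle_inner_diameter",
            "needle_length",
            "cad_side_x",
            "cad_side_y",
            "true_fiber_diameter",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.fiber_waviness_amp < 0 or self.side_jitter_sd < 0:
            raise ValueError("waviness and jitter must be non-negative")
        if self.fiber_waviness_amp >= self.true_fiber_diameter:
            raise ValueError("fiber_waviness_amp must be below true_fiber_diameter")


@dataclass(frozen=True)
class SimulatedPrint:
    """Rendered fiber and grid micrographs plus realized ground truth."""

    fiber: ImageField
    grid: ImageField
    fiber_diameter_mm: float
    pore_sides_x_mm: np.ndarray  # realized, one entry per pore
    pore_sides_y_mm: np.ndarray
    nominal_pore_side_x_mm: float
    nominal_pore_side_y_mm: float


def simulate_print_images(
    truth: PrintJobTruth,
    scale: float = 10.0,
    n_fibers: int = 5,
    fiber_length_mm: float = 8.0,
    waviness_wavelength_mm: float = 5.0,
    n_pores: int = 4,
    grid_scale: Optional[float] = None,
) -> SimulatedPrint:
    """Render binary micrographs of extruded fibers and a printed grid.

    ``scale`` is micrometers per pixel for the fiber image; ``grid_scale``
    (default 2.5x coarser) for the grid image.  Fibers are sinusoidally wavy
    constant-width strands; the grid is a square lattice of straight strands
    whose interior positions are jittered by ``side_jitter_sd``, and the
    realized pore side lengths are returned as truth (one per pore, so their
    dispersion is directly comparable with image measurements).
    """
    w_px = truth.true_fiber_diameter * 1000.0 / scale
    if w_px < 3:
        raise ValueError("fiber thinner than 3 px at this scale; reduce scale")
    rng = np.random.default_rng(truth.seed)

    # --- fiber image ----------------------------------------------------
    L_px = int(round(fiber_length_mm * 1000.0 / scale))
    amp_px = truth.fiber_waviness_amp * 1000.0 / scale
    lam_px = waviness_wavelength_mm * 1000.0 / scale
    pitch = 2.0 * (w_px + 2.0 * amp_px) + 10.0
    H = int(np.ceil(n_fibers * pitch + pitch))
    margin = int(np.ceil(w_px)) + 4
    img = np.zeros((H, L_px + 2 * margin), dtype=np.uint8)
    xx = np.arange(img.shape[1], dtype=float)
    yy = np.arange(H, dtype=float)[:, None]
    for i in range(n_fibers):
        y0 = pitch * (i + 1)
        phase = rng.uniform(0, 2 * np.pi)
        center = y0 + amp_px * np.sin(2 * np.pi * xx / lam_px + phase)
        slope = amp_px * (2 * np.pi / lam_px) * np.cos(2 * np.pi * xx / lam_px + phase)
        # vertical half-thickness giving a constant *perpendicular* width;
        # strict comparison so the rasterized span matches the continuous one
        half = 0.5 * w_px * np.sqrt(1.0 + slope**2)
        inside = np.abs(yy - center[None, :]) < half[None, :]
        inside[:, : margin] = False
        inside[:, margin + L_px :] = False
        img[inside] = 255
    fiber_field = ImageField(pixels=img, scale=scale)

    # --- grid image -----------------------------------------------------
    gscale = grid_scale if grid_scale is not None else scale * 2.5
    w_g_px = truth.true_fiber_diameter * 1000.0 / gscale
    if w_g_px < 3:
        raise ValueError("grid strand thinner than 3 px; use a finer grid_scale")
    side_x_px = truth.cad_side_x * 1000.0 / gscale
    side_y_px = truth.cad_side_y * 1000.0 / gscale
    jit_px = truth.side_jitter_sd * 1000.0 / gscale
    gmargin = 10.0
    # strand centerline positions; borders fixed so every pore stays enclosed
    xs = gmargin + np.linspace(0.0, side_x_px, n_pores + 1)
    ys = gmargin + np.linspace(0.0, side_y_px, n_pores + 1)
    if jit_px > 0:
        xs[1:-1] += rng.normal(0.0, jit_px, n_pores - 1)
        ys[1:-1] += rng.normal(0.0, jit_px, n_pores - 1)
        xs, ys = np.sort(xs), np.sort(ys)
    Wg = int(np.ceil(xs[-1] + w_g_px / 2 + gmargin))
    Hg = int(np.ceil(ys[-1] + w_g_px / 2 + gmargin))
    gimg = np.zeros((Hg, Wg), dtype=np.uint8)
    gx = np.arange(Wg, dtype=float)
    gy = np.arange(Hg, dtype=float)
    for xc in xs:
        cols = np.abs(gx - xc) < w_g_px / 2
        rows = (gy > ys[0] - w_g_px / 2) & (gy < ys[-1] + w_g_px / 2)
        gimg[np.ix_(rows, cols)] = 255
    for yc in ys:
        rows = np.abs(gy - yc) < w_g_px / 2
        cols = (gx > xs[0] - w_g_px / 2) & (gx < xs[-1] + w_g_px / 2)
        gimg[np.ix_(rows, cols)] = 255
    grid_field = ImageField(pixels=gimg, scale=gscale)

    gaps_x = (np.diff(xs) - w_g_px) * gscale / 1000.0  # mm, per column
    gaps_y = (np.diff(ys) - w_g_px) * gscale / 1000.0
    pore_x = np.repeat(gaps_x, n_pores)  # one value per pore (column-major)
    pore_y = np.tile(gaps_y, n_pores)
    nominal_x = (side_x_px / n_pores - w_g_px) * gscale / 1000.0
    nominal_y = (side_y_px / n_pores - w_g_px) * gscale / 1000.0
    return SimulatedPrint(
        fiber=fiber_field,
        grid=grid_field,
        fiber_diameter_mm=truth.true_fiber_diameter,
        pore_sides_x_mm=pore_x,
        pore_sides_y_mm=pore_y,
        nominal_pore_side_x_mm=nominal_x,
        nominal_pore_side_y_mm=nominal_y,
    )


# ---------------------------------------------------------------------------
# drop / particle / nuclei generators
# ---------------------------------------------------------------------------

def _render_disk(diameter_px: float, size: Tuple[int, int], center=None) -> np.ndarray:
    H, W = size
    cy, cx = center if center is not None else ((H - 1) / 2.0, (W - 1) / 2.0)
    yy, xx = np.mgrid[0:H, 0:W]
    return ((yy - cy) ** 2 + (xx - cx) ** 2) <= (diameter_px / 2.0) ** 2


def simulate_drop_frames(
    volume: float,
    D_eq: float,
    n_frames: int = 8,
    seed: int = 0,
    scale: float = 50.0,
) -> List[ImageField]:
    """Frames of a drop footprint growing monotonically to its equilibrium diameter.

    ``volume`` in microliters, ``D_eq`` in mm.  The first frame shows the
    projected diameter of the undeformed (spherical) drop; the last frame is
    rendered at exactly ``D_eq``.  The footprint is a filled binary disk.
    """
    if not volume > 0:
        raise ValueError("volume must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    d_ideal = (6.0 * volume / np.pi) ** (1.0 / 3.0)  # mm, equal-volume sphere
    if D_eq < d_ideal:
        raise ValueError(
            f"D_eq={D_eq} mm below the no-spreading diameter {d_ideal:.3f} mm"
        )
    if n_frames == 1:
        diams = np.array([D_eq])
    else:
        u = np.linspace(0.0, 1.0, n_frames)
        diams = D_eq - (D_eq - d_ideal) * (1.0 - u) ** 2  # monotone, exact at the end
    size_px = int(np.ceil(D_eq * 1000.0 / scale)) + 20
    frames = []
    for d in diams:
        mask = _render_disk(d * 1000.0 / scale, (size_px, size_px))
        frames.append(ImageField(pixels=mask.astype(np.uint8) * 255, scale=scale))
    return frames


def simulate_particle_field(
    diameters: Sequence[float],
    scale: float = 5.0,
    seed: int = 0,
    image_size: Optional[Tuple[int, int]] = None,
    max_tries: int = 10_000,
) -> ImageField:
    """Non-overlapping disk particles with the given equivalent diameters (um).

    The ground truth is the input diameter list itself.  Raises if the
    particles cannot be placed without overlap at the implied density.
    """
    diameters = np.asarray(list(diameters), dtype=float)
    if diameters.size and np.any(diameters <= 0):
        raise ValueError("particle diameters must be positive")
    radii_px = diameters / 2.0 / scale
    if image_size is None:
        area_px = float(np.sum(np.pi * (radii_px + 2) ** 2))
        side = int(np.ceil(np.sqrt(max(area_px, 1.0) * 12))) + int(
            2 * (radii_px.max() if radii_px.size else 0) + 20
        )
        image_size = (side, side)
    H, W = image_size
    img = np.zeros((H, W), dtype=np.uint8)
    rng = np.random.default_rng(seed)
    placed: List[Tuple[float, float, float]] = []
    for r in sorted(radii_px, reverse=True):  # large first eases packing
        for _ in range(max_tries):
            cy = rng.uniform(r + 1, H - r - 1)
            cx = rng.uniform(r + 1, W - r - 1)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 2) ** 2
                   for py, px, pr in placed):
                placed.append((cy, cx, r))
                break
        else:
            raise ValueError("could not place particles without overlap")
    yy, xx = np.mgrid[0:H, 0:W]
    for cy, cx, r in placed:
        img[((yy - cy) ** 2 + (xx - cx) ** 2) <= r**2] = 255
    return ImageField(pixels=img, scale=scale)


def simulate_nuclei_planes(
    area_fraction_per_plane: Sequence[float],
    spot_radius: float = 4.0,
    seed: int = 0,
    size: Tuple[int, int] = (512, 512),
) -> List[ImageField]:
    """Three stained-nuclei planes (top/middle/bottom) with known area fraction.

    Non-overlapping disks of ``spot_radius`` px are placed until the
    foreground fraction reaches the requested value; with the default spot
    size one disk contributes ~0.02% of the frame, so the realized fraction
    lands within 0.5 percentage points of the target.
    """
    fractions = list(area_fraction_per_plane)
    if len(fractions) != 3:
        raise ValueError("exactly three plane fractions are required")
    if any(not 0.0 <= f < 0.3 for f in fractions):
        raise ValueError("plane fractions must lie in [0, 0.3)")
    H, W = size
    spot_area = np.pi * spot_radius**2
    if spot_area / (H * W) > 0.005:
        raise ValueError("spot_radius too large to hit the fraction within 0.5 pp")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:H, 0:W]
    planes = []
    for label, frac in zip(("top", "middle", "bottom"), fractions):
        img = np.zeros((H, W), dtype=bool)
        target_px = frac * H * W
        centers: List[Tuple[float, float]] = []
        tries = 0
        while img.sum() + spot_area / 2 < target_px and tries < 100_000:
            tries += 1
            cy = rng.uniform(spot_radius, H - spot_radius)
            cx = rng.uniform(spot_radius, W - spot_radius)
            if any((cy - py) ** 2 + (cx - px) ** 2 < (2 * spot_radius + 1) ** 2
                   for py, px in centers):
                continue
            centers.append((cy, cx))
            img |= ((yy - cy) ** 2 + (xx - cx) ** 2) <= spot_radius**2
        planes.append(
            ImageField(pixels=img.astype(np.uint8) * 255, scale=1.0, plane_label=label)
        )
    return planes
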