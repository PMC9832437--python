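"""End-to-end characterization pipeline over synthetic or file inputs.

A :class:`RunConfig` describes a reproducible run: per-material rheological
truths, needle and CAD geometry, drop protocol and seeds.  The pipeline
simulates every instrument record, runs each analyzer and assembles one
JSON-serializable report per run:

* gel point (min), yield point (Pa), recovery fraction and LVE summary per
  material;
* power-law viscosity fit and the minimum-extrusion-pressure estimate;
* drop-spreading time course (S0, minimum layer height, window labels);
* fiber/grid shape-fidelity scores (S, U, Pe, Pr, P);
* particle granulometry and embedded-cell plane coverage before/after the
  gel point.

Runs are deterministic: all randomness derives from ``config.seed``, the
canonical JSON serialization is sorted, and the config hash is recorded in
the report, so two runs of the same config produce byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging import (
    cell_area_fraction,
    compare_plane_coverage,
    measure_drop_diameter,
    measure_fiber_profile,
    measure_granulometry,
    measure_grid,
)
from .rheology import (
    compute_recovery,
    detect_gel_point,
    detect_yield_point,
    fit_power_law,
    summarize_lve,
)
from .scoring import NeedleGeometry, estimate_extrusion_pressure, score_print
from .spreading import DropRecord, spreading_timecourse
from .synthetic import (
    GelationParams,
    PowerLawParams,
    PrintJobTruth,
    YieldSweepParams,
    simulate_drop_frames,
    simulate_flow_curve,
    simulate_frequency_sweep,
    simulate_gelation_timesweep,
    simulate_nuclei_planes,
    simulate_particle_field,
    simulate_print_images,
    simulate_recovery_trace,
    simulate_yield_sweep,
)

__all__ = ["MaterialSpec", "RunConfig", "PipelineError", "run_pipeline", "render_tables"]

logger = logging.getLogger("gelprint.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage and material it occurred in."""


@dataclass(frozen=True)
class MaterialSpec:
    """Ground-truth parameterization of one material for a simulated run."""

    name: str
    gel_point_min: float = 120.0
    yield_stress_pa: float = 205.0
    Gp_plateau: float = 1000.0
    Gpp_plateau: float = 300.0
    consistency_K: float = 10.0  # Pa s^n
    flow_index_n: float = 0.3
    recovery_fraction: float = 0.9
    initial_spreading_ratio: float = 2.0
    fiber_waviness_amp_mm: float = 0.03
    side_jitter_sd_mm: float = 0.15


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    materials: tuple = (
        MaterialSpec("alginate_ecm", gel_point_min=120.0, yield_stress_pa=205.0),
        MaterialSpec("alginate_gelatin", gel_point_min=60.0, yield_stress_pa=155.0),
        MaterialSpec("alginate", gel_point_min=60.0, yield_stress_pa=121.0),
    )
    needle_gauge: Optional[str] = "22G"
    needle_inner_diameter_mm: Optional[float] = None  # overrides the gauge
    needle_length_mm: float = 12.5
    cad_side_x_mm: float = 20.0
    cad_side_y_mm: float = 20.0
    drop_volume_ul: float = 100.0
    drop_interval_min: float = 30.0
    nuclei_area_fraction: float = 0.05
    particle_diameters_um: tuple = (100.0, 147.9, 200.0)
    output_dir: Optional[str] = None

    def needle(self) -> NeedleGeometry:
        if self.needle_inner_diameter_mm is not None:
            return NeedleGeometry(self.needle_inner_diameter_mm, self.needle_length_mm)
        if self.needle_gauge is None:
            raise ValueError(
                "config must provide needle_gauge or needle_inner_diameter_mm"
            )
        return NeedleGeometry.from_gauge(self.needle_gauge, self.needle_length_mm)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["materials"] = [dataclasses.asdict(m) for m in self.materials]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        mats = d.pop("materials", None)
        if mats is not None:
            d["materials"] = tuple(MaterialSpec(**m) for m in mats)
        if "particle_diameters_um" in d:
            d["particle_diameters_um"] = tuple(d["particle_diameters_um"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(base: int, material_index: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int((base * 1_000_003 + material_index * 1_009 + stage) % (2**31 - 1))


def _characterize_material(
    m: MaterialSpec, cfg: RunConfig, index: int
) -> Dict[str, object]:
    stage = "setup"
    try:
        needle = cfg.needle()
        out: Dict[str, object] = {"material": m.name}

        # --- rheology ---------------------------------------------------
        stage = "gel_point"
        t_grid = np.arange(1.0, max(2.5 * m.gel_point_min, 30.0), 1.0)
        sweep = simulate_gelation_timesweep(
            GelationParams(
                crossover_time=m.gel_point_min,
                Gp_plateau=m.Gp_plateau,
                Gpp_plateau=m.Gpp_plateau,
                seed=_stage_seed(cfg.seed, index, 1),
            ),
            sampling=t_grid,
        )
        gel = detect_gel_point(sweep)
        out["gel_point_min"] = gel.crossover_time

        stage = "yield_point"
        ysweep = simulate_yield_sweep(
            YieldSweepParams(
                sigma_y=m.yield_stress_pa,
                Gp0=2.0 * m.Gp_plateau,
                Gpp0=0.4 * m.Gp_plateau,
                seed=_stage_seed(cfg.seed, index, 2),
            )
        )
        ypt = detect_yield_point(ysweep)
        out["yield_stress_pa"] = ypt.sigma_y

        stage = "recovery"
        trace = simulate_recovery_trace(
            plateau1=m.Gp_plateau,
            yielded_level=0.05 * m.Gp_plateau,
            recovery_fraction=m.recovery_fraction,
            seed=_stage_seed(cfg.seed, index, 3),
        )
        rec = compute_recovery(trace)
        out["recovery_fraction"] = rec.recovery

        stage = "lve"
        fsweep = simulate_frequency_sweep(
            Gp_level=m.Gp_plateau,
            Gpp_level=m.Gpp_plateau,
            seed=_stage_seed(cfg.seed, index, 4),
        )
        lve = summarize_lve(fsweep)
        out["lve"] = {
            "mean_Gp_pa": lve.mean_Gp,
            "mean_Gpp_pa": lve.mean_Gpp,
            "mean_tan_delta": lve.mean_tan_delta,
        }

        stage = "flow_curve"
        curve = simulate_flow_curve(
            PowerLawParams(
                K=m.consistency_K,
                n=m.flow_index_n,
                seed=_stage_seed(cfg.seed, index, 5),
            )
        )
        plf = fit_power_law(curve)
        out["power_law"] = {"K_pa_sn": plf.K, "n": plf.n, "r_squared": plf.r_squared}

        stage = "extrusion_pressure"
        if ypt.sigma_y is not None:
            press = estimate_extrusion_pressure(ypt.sigma_y, needle)
            out["min_extrusion_pressure_kpa"] = press.pressure_kpa
            out["pressure_model"] = press.model
        else:
            out["min_extrusion_pressure_kpa"] = None

        # --- drop spreading ----------------------------------------------
        stage = "spreading"
        records: List[DropRecord] = []
        t = 0.0
        d_ideal = (6.0 * cfg.drop_volume_ul / np.pi) ** (1.0 / 3.0)
        k = 0
        while t < m.gel_point_min:
            # S0 relaxes linearly toward 1 as the gel point approaches
            s0 = 1.0 + (m.initial_spreading_ratio - 1.0) * (1.0 - t / m.gel_point_min)
            frames = simulate_drop_frames(
                volume=cfg.drop_volume_ul,
                D_eq=s0 * d_ideal,
                n_frames=1,
                seed=_stage_seed(cfg.seed, index, 10 + k),
            )
            d_meas = measure_drop_diameter(frames[-1])
            records.append(
                DropRecord(
                    volume=cfg.drop_volume_ul, D_eq=d_meas, time_since_crosslink=t
                )
            )
            t += cfg.drop_interval_min
            k += 1
        course = spreading_timecourse(records, gel_point=m.gel_point_min)
        out["spreading"] = [
            {
                "time_min": p.time,
                "S0": p.S0,
                "h_min_mm": p.h_min,
                "window": p.window,
            }
            for p in course
        ]

        # --- printing ----------------------------------------------------
        stage = "printing"
        truth = PrintJobTruth(
            needle_inner_diameter=needle.inner_diameter,
            needle_length=needle.length,
            cad_side_x=cfg.cad_side_x_mm,
            cad_side_y=cfg.cad_side_y_mm,
            true_fiber_diameter=1.2 * needle.inner_diameter,
            fiber_waviness_amp=m.fiber_waviness_amp_mm,
            side_jitter_sd=m.side_jitter_sd_mm,
            seed=_stage_seed(cfg.seed, index, 6),
        )
        sim = simulate_print_images(truth)
        fm = measure_fiber_profile(sim.fiber, seed=_stage_seed(cfg.seed, index, 7))
        gm = measure_grid(
            sim.grid,
            cad_side_x=sim.nominal_pore_side_x_mm,
            cad_side_y=sim.nominal_pore_side_y_mm,
        )
        scores = score_print(fm, gm, needle)
        out["scores"] = {
            "S_percent": scores.S,
            "U": scores.U,
            "Pe": scores.Pe,
            "Pr": scores.Pr,
            "P": scores.P,
            "suitable_for_ebb": scores.suitable_for_ebb,
        }

        # --- embedded cells ----------------------------------------------
        stage = "cell_distribution"
        frac = cfg.nuclei_area_fraction
        before = simulate_nuclei_planes(
            (frac, frac, frac), seed=_stage_seed(cfg.seed, index, 8)
        )
        after = simulate_nuclei_planes(
            (frac, frac, frac), seed=_stage_seed(cfg.seed, index, 9)
        )
        cov_before = [cell_area_fraction(p) for p in before]
        cov_after = [cell_area_fraction(p) for p in after]
        comparison = compare_plane_coverage(cov_before, cov_after)
        out["cell_distribution"] = {
            "before": {c.plane_label: c.cell_area_fraction for c in cov_before},
            "after": {c.plane_label: c.cell_area_fraction for c in cov_after},
            "homogeneous": comparison.homogeneous,
        }
        return out
    except Exception as exc:
        raise PipelineError(f"[{m.name}/{stage}] {exc}") from exc


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute every stage for every configured material.

    Returns the report dict; when ``config.output_dir`` is set, also writes
    ``report.json``, the summary CSV tables and ``run.log`` there.
    """
    config.needle()  # validate geometry before any compute
    t0 = time.perf_counter()
    report: Dict[str, object] = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "gelprint_version": __version__,
        "materials": [],
    }

    stage = "granulometry"
    try:
        particles = simulate_particle_field(
            config.particle_diameters_um, seed=_stage_seed(config.seed, 99, 0)
        )
        gran = measure_granulometry(particles)
        report["granulometry"] = {
            "mean_um": gran.mean_um,
            "sd_um": gran.sd_um,
            "n_particles": gran.n_particles,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[shared/{stage}] {exc}") from exc

    for i, m in enumerate(config.materials):
        logger.info("characterizing material %s", m.name)
        report["materials"].append(_characterize_material(m, config, i))

    elapsed = time.perf_counter() - t0
    logger.info("pipeline finished in %.1f s", elapsed)

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report_json(report))
        gel_tbl, print_tbl = render_tables(report)
        gel_tbl.to_csv(outdir / "gel_points.csv", index=False)
        print_tbl.to_csv(outdir / "printability.csv", index=False)
        with open(outdir / "run.log", "a") as fh:
            fh.write(
                f"gelprint {__version__} seed={config.seed} "
                f"config_hash={config.config_hash()} "
                f"numpy={np.__version__} elapsed_s={elapsed:.2f}\n"
            )
    return report


def report_json(report: Dict[str, object]) -> str:
    """Canonical (sorted, deterministic) JSON serialization of a report."""
    return json.dumps(report, sort_keys=True, indent=2)


def render_tables(report: Dict[str, object]):
    """Summary tables: (material, gel point) and (yield, pressure, scores).

    An empty or material-less report yields empty tables, not an error.
    """
    materials = report.get("materials", []) if report else []
    gel_rows = []
    print_rows = []
    for m in materials:
        gel_rows.append(
            {"material": m.get("material"), "gel_point_min": m.get("gel_point_min")}
        )
        scores = m.get("scores", {})
        print_rows.append(
            {
                "material": m.get("material"),
                "yield_stress_pa": m.get("yield_stress_pa"),
                "min_extrusion_pressure_kpa": m.get("min_extrusion_pressure_kpa"),
                "printability_P": scores.get("P"),
            }
        )
    cols_gel = ["material", "gel_point_min"]
    cols_print = [
        "material",
        "yield_stress_pa",
        "min_extrusion_pressure_kpa",
        "printability_P",
    ]
    return (
        pd.DataFrame(gel_rows, columns=cols_gel),
        pd.DataFrame(print_rows, columns=cols_print),
    )
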