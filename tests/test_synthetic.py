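"""Generator contracts: seeded determinism, exact noiseless curves, and the
ground-truth invariants each downstream analyzer relies on."""

import numpy as np
import pytest

from gelprint.synthetic import (
    GelationParams,
    ImageField,
    PowerLawParams,
    PrintJobTruth,
    YieldSweepParams,
    read_image,
    simulate_drop_frames,
    simulate_flow_curve,
    simulate_gelation_timesweep,
    simulate_nuclei_planes,
    simulate_particle_field,
    simulate_print_images,
    simulate_recovery_trace,
    simulate_yield_sweep,
    write_image,
)


class TestGelationGenerator:
    def test_noiseless_crossing_lands_exactly_at_crossover(self):
        tc = 90.0
        t = np.linspace(1.0, 300.0, 400)
        sweep = simulate_gelation_timesweep(GelationParams(crossover_time=tc), t)
        # continuous curves cross at tc: the sign of Gp - Gpp flips there
        d = sweep.Gp - sweep.Gpp
        assert np.all(d[t < tc - 1e-9] < 0)
        assert np.all(d[t > tc + 1e-9] > 0)

    def test_single_crossing_in_window(self):
        t = np.arange(1.0, 300.0, 1.0)
        sweep = simulate_gelation_timesweep(GelationParams(crossover_time=150.0), t)
        signs = np.sign(sweep.Gp - sweep.Gpp)
        flips = np.sum(np.abs(np.diff(np.sign(signs[signs != 0]))) > 0)
        assert flips == 1

    def test_no_gel_case_has_no_crossing(self):
        # crossover far beyond the observation window: liquid-like throughout
        t = np.arange(1.0, 100.0, 1.0)
        sweep = simulate_gelation_timesweep(GelationParams(crossover_time=500.0), t)
        assert np.all(sweep.Gp < sweep.Gpp)

    def test_seeded_noise_deterministic(self):
        t = np.arange(1.0, 100.0, 1.0)
        p = GelationParams(crossover_time=50.0, noise_sd_rel=0.05, seed=7)
        a = simulate_gelation_timesweep(p, t)
        b = simulate_gelation_timesweep(p, t)
        np.testing.assert_array_equal(a.Gp, b.Gp)

    def test_nonpositive_plateau_rejected(self):
        with pytest.raises(ValueError):
            GelationParams(crossover_time=60.0, Gp_plateau=-1.0)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError, match="10 points"):
            simulate_gelation_timesweep(
                GelationParams(crossover_time=60.0), np.arange(1.0, 6.0)
            )

    def test_infeasible_crossover_rejected(self):
        # crossing would have to happen above the loss plateau
        with pytest.raises(ValueError, match="not attainable"):
            simulate_gelation_timesweep(
                GelationParams(
                    crossover_time=60.0, Gp_plateau=1000.0, Gpp_plateau=10.0,
                    rise_timescale=30.0,
                ),
                np.arange(1.0, 100.0, 1.0),
            )


class TestFlowCurveGenerator:
    def test_newtonian_limit_constant(self):
        curve = simulate_flow_curve(PowerLawParams(K=10.0, n=1.0))
        np.testing.assert_allclose(curve.viscosity, 10.0)

    def test_unit_rate_identity(self):
        params = PowerLawParams(K=10.0, n=0.3, rate_grid=np.array([1.0, 10.0, 100.0]))
        curve = simulate_flow_curve(params)
        assert curve.viscosity[0] == pytest.approx(10.0)

    def test_closed_form_at_high_rate(self):
        params = PowerLawParams(K=10.0, n=0.3, rate_grid=np.array([1.0, 10.0, 100.0]))
        curve = simulate_flow_curve(params)
        assert curve.viscosity[-1] == pytest.approx(10.0 * 100.0 ** (-0.7), rel=1e-12)

    def test_shear_thinning_monotone(self):
        curve = simulate_flow_curve(PowerLawParams(K=5.0, n=0.4))
        assert np.all(np.diff(curve.viscosity) < 0)

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError):
            PowerLawParams(K=10.0, n=0.0)
        with pytest.raises(ValueError):
            PowerLawParams(K=-1.0, n=0.5)


class TestYieldGenerator:
    def test_strict_ordering_about_sigma_y(self):
        p = YieldSweepParams(sigma_y=50.0)
        sweep = simulate_yield_sweep(p)
        below = sweep.abscissa < 50.0
        above = sweep.abscissa > 50.0
        assert np.all(sweep.Gp[below] > sweep.Gpp[below])
        assert np.all(sweep.Gpp[above] > sweep.Gp[above])

    def test_grid_wider_than_protocol_allowed(self):
        # yield values can exceed the 0.1-100 Pa protocol window
        p = YieldSweepParams(sigma_y=205.0)
        assert p.stress_grid[-1] > 100.0

    def test_sigma_below_grid_rejected(self):
        with pytest.raises(ValueError):
            YieldSweepParams(sigma_y=0.05)


class TestRecoveryGenerator:
    def test_full_recovery_third_plateau_equals_first(self):
        tr = simulate_recovery_trace(800.0, 40.0, 1.0)
        last1 = tr.Gp[(tr.abscissa > 50) & (tr.abscissa < 100)]
        last3 = tr.Gp[tr.abscissa > 350]
        assert np.median(last3) == pytest.approx(np.median(last1), rel=1e-6)

    def test_third_plateau_scales_with_fraction(self):
        tr = simulate_recovery_trace(1000.0, 50.0, 0.5)
        assert np.median(tr.Gp[tr.abscissa > 350]) == pytest.approx(500.0, rel=1e-3)

    def test_yield_level_above_plateau_rejected(self):
        with pytest.raises(ValueError, match="yield"):
            simulate_recovery_trace(100.0, 200.0, 0.5)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            simulate_recovery_trace(100.0, -1.0, 0.5)


class TestPrintImageGenerator:
    def test_ideal_print_is_straight_and_exact(self):
        truth = PrintJobTruth(fiber_waviness_amp=0.0, side_jitter_sd=0.0)
        sim = simulate_print_images(truth)
        # straight fibers: every row of a fiber's span is identical
        col_counts = (sim.fiber.pixels > 0).sum(axis=0)
        interior = col_counts[col_counts > 0]
        assert np.all(interior == interior[0])
        # grid gaps all equal the nominal pore side
        np.testing.assert_allclose(
            sim.pore_sides_x_mm, sim.nominal_pore_side_x_mm, atol=1e-12
        )

    def test_rendered_width_follows_scale_arithmetic(self):
        truth = PrintJobTruth(true_fiber_diameter=0.5, fiber_waviness_amp=0.0)
        sim = simulate_print_images(truth, scale=10.0)
        col_counts = (sim.fiber.pixels > 0).sum(axis=0)
        per_fiber = col_counts[col_counts > 0] / 5  # five stacked fibers
        assert per_fiber[0] == pytest.approx(50.0, abs=1.0)

    def test_seeded_determinism(self):
        truth = PrintJobTruth(fiber_waviness_amp=0.04, side_jitter_sd=0.2, seed=11)
        a = simulate_print_images(truth)
        b = simulate_print_images(truth)
        np.testing.assert_array_equal(a.fiber.pixels, b.fiber.pixels)
        np.testing.assert_array_equal(a.grid.pixels, b.grid.pixels)

    def test_too_thin_fiber_rejected(self):
        with pytest.raises(ValueError, match="3 px"):
            simulate_print_images(PrintJobTruth(true_fiber_diameter=0.05), scale=25.0)

    def test_waviness_must_stay_below_diameter(self):
        with pytest.raises(ValueError):
            PrintJobTruth(true_fiber_diameter=0.4, fiber_waviness_amp=0.5)


class TestDropFrames:
    def test_footprint_grows_monotonically_to_d_eq(self):
        frames = simulate_drop_frames(100.0, 10.0, n_frames=6)
        areas = [(f.pixels > 0).sum() for f in frames]
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))
        d_px = 2.0 * np.sqrt(areas[-1] / np.pi)
        assert d_px * frames[-1].scale / 1000.0 == pytest.approx(
            10.0, abs=frames[-1].scale / 1000.0
        )

    def test_no_spreading_case_constant(self):
        d_ideal = (600.0 / np.pi) ** (1.0 / 3.0)
        frames = simulate_drop_frames(100.0, d_ideal, n_frames=4)
        areas = {(f.pixels > 0).sum() for f in frames}
        assert len(areas) == 1

    def test_single_frame_is_equilibrium(self):
        frames = simulate_drop_frames(100.0, 9.0, n_frames=1)
        assert len(frames) == 1
        d_px = 2.0 * np.sqrt((frames[0].pixels > 0).sum() / np.pi)
        assert d_px * frames[0].scale / 1000.0 == pytest.approx(9.0, abs=0.05)

    def test_sub_spherical_diameter_rejected(self):
        with pytest.raises(ValueError, match="no-spreading"):
            simulate_drop_frames(100.0, 3.0, n_frames=3)


class TestParticlesAndNuclei:
    def test_empty_particle_list_gives_blank_field(self):
        field = simulate_particle_field([], seed=0)
        assert (field.pixels > 0).sum() == 0

    def test_nuclei_fraction_within_half_point(self):
        planes = simulate_nuclei_planes((0.02, 0.05, 0.10), seed=3)
        for plane, frac in zip(planes, (0.02, 0.05, 0.10)):
            realized = (plane.pixels > 0).mean()
            assert realized == pytest.approx(frac, abs=0.005)

    def test_zero_fraction_blank_plane(self):
        planes = simulate_nuclei_planes((0.0, 0.05, 0.05), seed=1)
        assert (planes[0].pixels > 0).sum() == 0

    def test_seeded_determinism(self):
        a = simulate_nuclei_planes((0.02, 0.05, 0.10), seed=9)
        b = simulate_nuclei_planes((0.02, 0.05, 0.10), seed=9)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.pixels, pb.pixels)

    def test_saturating_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_nuclei_planes((0.5, 0.05, 0.05), seed=0)


class TestImageIO:
    def test_tiff_sidecar_round_trip(self, tmp_path):
        field = simulate_particle_field([100.0, 150.0], scale=5.0, seed=2)
        path = write_image(field, tmp_path / "particles.tif")
        back = read_image(path)
        np.testing.assert_array_equal(back.pixels, field.pixels)
        assert back.scale == field.scale

    def test_missing_sidecar_rejected(self, tmp_path):
        import tifffile

        p = tmp_path / "orphan.tif"
        tifffile.imwrite(p, np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(FileNotFoundError):
            read_image(p)

    def test_plane_label_validation(self):
        with pytest.raises(ValueError):
            ImageField(np.zeros((4, 4), dtype=np.uint8), 1.0, plane_label="side")
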