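"""Unit and property tests for sweep analysis: gel point, yield point,
power-law fit, recovery and LVE summaries, plus the CSV dialect."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelprint.rheology import (
    FlowCurve,
    NoSolidRegimeError,
    RheoSweep,
    compute_recovery,
    detect_gel_point,
    detect_yield_point,
    fit_power_law,
    read_rheo_table,
    summarize_lve,
    write_rheo_table,
)
from gelprint.synthetic import (
    GelationParams,
    PowerLawParams,
    YieldSweepParams,
    simulate_flow_curve,
    simulate_gelation_timesweep,
    simulate_recovery_trace,
    simulate_yield_sweep,
)


def _linear_time_sweep():
    """Gp(t) = 2t, Gpp(t) = t + 60: G' overtakes G'' at exactly t = 60 min."""
    t = np.arange(1.0, 200.0, 1.0)
    return RheoSweep("time_sweep", t, 2.0 * t, t + 60.0)


class TestGelPoint:
    def test_linear_crossing_is_exact(self):
        res = detect_gel_point(_linear_time_sweep())
        assert res.gelled
        assert res.crossover_time == pytest.approx(60.0)

    @pytest.mark.parametrize("tc", [120.0, 60.0])
    def test_constructed_crossover_recovered_within_sampling_interval(self, tc):
        sweep = simulate_gelation_timesweep(
            GelationParams(crossover_time=tc), np.arange(1.0, 300.0, 1.0)
        )
        res = detect_gel_point(sweep)
        assert res.crossover_time == pytest.approx(tc, abs=1.0)

    def test_never_gelling_sweep_returns_absent_without_error(self):
        t = np.arange(1.0, 100.0, 1.0)
        sweep = RheoSweep("time_sweep", t, np.full(t.size, 10.0), np.full(t.size, 20.0))
        res = detect_gel_point(sweep)
        assert not res.gelled
        assert res.crossover_time is None

    def test_reversed_roles_never_yield_the_same_interpretation(self):
        sweep = _linear_time_sweep()
        swapped = RheoSweep("time_sweep", sweep.abscissa, sweep.Gpp, sweep.Gp)
        assert not detect_gel_point(swapped).gelled

    def test_result_invariant_ordering_around_crossing(self):
        sweep = simulate_gelation_timesweep(
            GelationParams(crossover_time=90.0), np.arange(1.0, 300.0, 1.0)
        )
        res = detect_gel_point(sweep)
        i, j = res.bracketing_indices
        assert sweep.Gp[i] <= sweep.Gpp[i]
        assert sweep.Gp[j + 1] > sweep.Gpp[j + 1]

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True, max_examples=30)
    def test_scale_invariance_of_crossing(self, scale):
        base = detect_gel_point(_linear_time_sweep()).crossover_time
        s = _linear_time_sweep()
        scaled = RheoSweep("time_sweep", s.abscissa, scale * s.Gp, scale * s.Gpp)
        assert detect_gel_point(scaled).crossover_time == pytest.approx(base)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            detect_gel_point(
                RheoSweep("time_sweep", [1.0, 2.0, 3.0], [1, 2, 3], [3, 2, 1])
            )

    def test_wrong_test_type_rejected(self):
        sweep = RheoSweep("freq_sweep", [1.0, 2.0, 3.0, 4.0], [1] * 4, [2] * 4)
        with pytest.raises(ValueError):
            detect_gel_point(sweep)

    def test_noise_flip_rejected_by_persistence(self):
        # single-sample positive flip in an otherwise liquid series
        t = np.arange(1.0, 30.0, 1.0)
        gp = np.full(t.size, 10.0)
        gpp = np.full(t.size, 20.0)
        gp[12] = 25.0  # isolated flip
        res = detect_gel_point(RheoSweep("time_sweep", t, gp, gpp))
        assert not res.gelled


class TestYieldPoint:
    def test_linear_symmetric_crossing_exact(self):
        sigma = np.arange(1.0, 410.0, 1.0)
        sweep = RheoSweep("amplitude_sweep", sigma, 410.0 - sigma, sigma)
        assert detect_yield_point(sweep).sigma_y == pytest.approx(205.0)

    @pytest.mark.parametrize("sy", [205.0, 155.0, 121.0])
    def test_constructed_yield_recovered_within_grid_resolution(self, sy):
        params = YieldSweepParams(sigma_y=sy)
        res = detect_yield_point(simulate_yield_sweep(params))
        grid = params.stress_grid
        i = np.searchsorted(grid, sy)
        resolution = grid[min(i, grid.size - 1)] - grid[max(i - 1, 0)]
        assert res.sigma_y == pytest.approx(sy, abs=resolution)

    def test_liquid_at_lowest_amplitude_is_a_distinct_error(self):
        sigma = np.logspace(-1, 2, 20)
        sweep = RheoSweep("amplitude_sweep", sigma, np.full(20, 1.0), np.full(20, 2.0))
        with pytest.raises(NoSolidRegimeError):
            detect_yield_point(sweep)

    def test_solid_throughout_returns_absent(self):
        sigma = np.logspace(-1, 2, 20)
        sweep = RheoSweep("amplitude_sweep", sigma, np.full(20, 5.0), np.full(20, 1.0))
        res = detect_yield_point(sweep)
        assert res.sigma_y is None

    def test_moduli_ordering_invariant(self):
        params = YieldSweepParams(sigma_y=205.0)
        sweep = simulate_yield_sweep(params)
        below = sweep.abscissa < params.sigma_y
        assert np.all(sweep.Gp[below] > sweep.Gpp[below])
        above = sweep.abscissa > params.sigma_y
        assert np.all(sweep.Gpp[above] > sweep.Gp[above])


class TestPowerLawFit:
    def test_exact_on_noiseless_power_law(self):
        fit = fit_power_law(simulate_flow_curve(PowerLawParams(K=10.0, n=0.3)))
        assert fit.K == pytest.approx(10.0, rel=1e-6)
        assert fit.n == pytest.approx(0.3, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_newtonian_constant_viscosity(self):
        curve = FlowCurve(np.logspace(0, 2, 10), np.full(10, 5.0))
        fit = fit_power_law(curve)
        assert fit.n == pytest.approx(1.0, abs=1e-12)
        assert fit.K == pytest.approx(5.0, rel=1e-12)

    def test_estimator_bias_vanishes_with_noise(self):
        errs = []
        for rep in range(50):
            params = PowerLawParams(
                K=10.0, n=0.3, rate_grid=np.logspace(0, 2, 50),
                noise_sd_rel=0.02, seed=rep,
            )
            errs.append(fit_power_law(simulate_flow_curve(params)).n - 0.3)
        assert abs(np.median(errs)) < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(FlowCurve([1.0, 2.0], [3.0, 2.0]))

    def test_nonpositive_viscosity_rejected_by_container(self):
        with pytest.raises(ValueError):
            FlowCurve([1.0, 2.0, 3.0], [1.0, -1.0, 0.5])


class TestRecovery:
    def test_full_recovery(self):
        trace = simulate_recovery_trace(1000.0, 50.0, 1.0)
        assert compute_recovery(trace).recovery == pytest.approx(1.0, abs=1e-6)

    def test_half_recovery_by_construction(self):
        trace = simulate_recovery_trace(1000.0, 50.0, 0.5)
        res = compute_recovery(trace)
        assert res.recovery == pytest.approx(0.5, abs=0.01)
        assert res.plateau_initial == pytest.approx(1000.0, rel=0.01)
        assert res.plateau_final == pytest.approx(500.0, rel=0.01)

    def test_missing_middle_interval_is_protocol_violation(self):
        trace = simulate_recovery_trace(1000.0, 50.0, 0.5)
        t = trace.abscissa
        keep = (t < 100.0) | (t >= 300.0)
        clipped = RheoSweep("recovery", t[keep], trace.Gp[keep], trace.Gpp[keep])
        with pytest.raises(ValueError, match="interval 2"):
            compute_recovery(clipped)

    def test_yielded_interval_is_viscous_dominated(self):
        trace = simulate_recovery_trace(1000.0, 50.0, 0.8)
        mid = (trace.abscissa > 150.0) & (trace.abscissa < 290.0)
        assert np.all(trace.Gpp[mid] > trace.Gp[mid])


class TestLVE:
    def test_constant_moduli(self):
        f = np.linspace(0.1, 22.5, 40)
        sweep = RheoSweep("freq_sweep", f, np.full(40, 1000.0), np.full(40, 200.0))
        res = summarize_lve(sweep)
        assert res.mean_Gp == pytest.approx(1000.0)
        assert res.mean_Gpp == pytest.approx(200.0)
        assert res.mean_tan_delta == pytest.approx(0.2)

    def test_band_outside_range_rejected(self):
        f = np.linspace(1.0, 10.0, 20)
        sweep = RheoSweep("freq_sweep", f, np.ones(20), np.ones(20))
        with pytest.raises(ValueError):
            summarize_lve(sweep, band=(0.1, 22.5))

    def test_two_point_band_matches_hand_computed_mean(self):
        f = np.array([1.0, 2.0, 4.0, 8.0])
        gp = np.array([100.0, 200.0, 400.0, 800.0])
        gpp = np.array([10.0, 40.0, 40.0, 80.0])
        res = summarize_lve(RheoSweep("freq_sweep", f, gp, gpp), band=(1.5, 5.0))
        assert res.n_points == 2
        assert res.mean_Gp == pytest.approx((200.0 + 400.0) / 2)
        assert res.mean_tan_delta == pytest.approx((40 / 200 + 40 / 400) / 2)


class TestRheoTableIO:
    def test_sweep_round_trip(self, tmp_path):
        sweep = simulate_gelation_timesweep(
            GelationParams(crossover_time=60.0, noise_sd_rel=0.02, seed=5),
            np.arange(1.0, 120.0, 1.0),
        )
        path = tmp_path / "sweep.csv"
        write_rheo_table(sweep, path)
        back = read_rheo_table(path)
        np.testing.assert_allclose(back.abscissa, sweep.abscissa)
        np.testing.assert_allclose(back.Gp, sweep.Gp)
        np.testing.assert_allclose(back.Gpp, sweep.Gpp)
        assert back.test_type == "time_sweep"

    def test_flow_curve_round_trip(self, tmp_path):
        curve = simulate_flow_curve(PowerLawParams(K=2.0, n=0.5))
        path = tmp_path / "flow.csv"
        write_rheo_table(curve, path)
        back = read_rheo_table(path)
        np.testing.assert_allclose(back.viscosity, curve.viscosity)

    def test_shuffled_rows_sorted_with_warning(self, tmp_path):
        import pandas as pd

        sweep = _linear_time_sweep()
        path = tmp_path / "sweep.csv"
        write_rheo_table(sweep, path)
        df = pd.read_csv(path).sample(frac=1.0, random_state=0)
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="sort"):
            back = read_rheo_table(path)
        np.testing.assert_allclose(back.abscissa, sweep.abscissa)

    def test_missing_gpp_column_rejected(self, tmp_path):
        import pandas as pd

        sweep = _linear_time_sweep()
        path = tmp_path / "sweep.csv"
        write_rheo_table(sweep, path)
        df = pd.read_csv(path).drop(columns=["Gpp_Pa"])
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="Gpp"):
            read_rheo_table(path)

    def test_unknown_column_rejected(self, tmp_path):
        import pandas as pd

        path = tmp_path / "bad.csv"
        write_rheo_table(_linear_time_sweep(), path)
        df = pd.read_csv(path)
        df["mystery"] = 1
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="unknown columns"):
            read_rheo_table(path)

    def test_seconds_normalized_to_minutes(self, tmp_path):
        import pandas as pd

        path = tmp_path / "sweep.csv"
        write_rheo_table(_linear_time_sweep(), path)
        df = pd.read_csv(path)
        df["abscissa"] = df["abscissa"] * 60.0
        df["abscissa_units"] = "s"
        df.to_csv(path, index=False)
        back = read_rheo_table(path)
        np.testing.assert_allclose(back.abscissa, _linear_time_sweep().abscissa)
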