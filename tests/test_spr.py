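"""SPR model, global kinetic fit, equilibrium, calibration, competition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mechsnp import spr
from mechsnp import synthetic_data as synth

SCHED = spr.SensorgramSchedule()


class TestLangmuirResponse:
    def test_worked_association_value(self):
        # kobs = 0.02/s, Req = 50 RU -> R(60 s) = 50*(1 - exp(-1.2))
        curve = spr.langmuir_response(1e5, 1e-2, 100.0, 100.0, SCHED)
        i = np.searchsorted(curve.time, 60.0)
        assert curve.response[i] == pytest.approx(34.94, abs=0.005)

    def test_irreversible_limit_saturates_at_rmax(self):
        sched = spr.SensorgramSchedule(t_assoc=20000.0, t_dissoc=100.0, dt=10.0)
        curve = spr.langmuir_response(1e5, 1e-9, 100.0, 8.0, sched)
        i = np.searchsorted(curve.time, 20000.0) - 1
        assert curve.response[i] == pytest.approx(100.0, abs=0.01)

    def test_dissociation_is_single_exponential(self):
        curve = spr.langmuir_response(1e5, 1e-2, 100.0, 100.0, SCHED)
        mask = curve.time > SCHED.t_assoc
        td = curve.time[mask] - SCHED.t_assoc
        r0 = curve.response[np.searchsorted(curve.time, SCHED.t_assoc)]
        assert np.allclose(curve.response[mask], r0 * np.exp(-1e-2 * td))

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            spr.langmuir_response(-1e5, 1e-2, 100.0, 8.0, SCHED)


class TestKineticFit:
    def test_noiseless_recovery_is_exact_to_optimizer_tolerance(self):
        curves = synth.gen_sensorgrams(3e5, 2e-2, 150.0,
                                       [4, 8, 16, 32, 64, 128, 256, 512],
                                       SCHED, 0.0, seed=0)
        fit = spr.fit_kinetics_global(curves)
        assert fit.kon == pytest.approx(3e5, rel=1e-3)
        assert fit.koff == pytest.approx(2e-2, rel=1e-3)
        assert fit.rmax == pytest.approx(150.0, rel=1e-3)

    def test_kd_identity_holds_exactly(self):
        curves = synth.gen_sensorgrams(1e5, 1e-2, 100.0, [8, 32, 128], SCHED, 0.0, 0)
        fit = spr.fit_kinetics_global(curves)
        assert fit.kd == fit.koff / fit.kon

    def test_randomized_noiseless_recovery(self):
        rng = np.random.default_rng(42)
        for _ in range(8):
            kon = 10 ** rng.uniform(4.3, 6.0)
            koff = 10 ** rng.uniform(-2.5, -1.0)
            rmax = rng.uniform(50, 300)
            curves = synth.gen_sensorgrams(
                kon, koff, rmax, [4, 16, 64, 256, 512], SCHED, 0.0, 0)
            fit = spr.fit_kinetics_global(curves)
            assert fit.kon == pytest.approx(kon, rel=1e-3)
            assert fit.koff == pytest.approx(koff, rel=1e-3)

    def test_noisy_recovery_within_five_percent(self):
        hits = []
        for seed in range(10):
            curves = synth.gen_sensorgrams(
                1e5, 1e-2, 100.0, [4, 8, 16, 32, 64, 128, 256, 512],
                SCHED, 2.0, seed=seed)
            fit = spr.fit_kinetics_global(curves)
            hits.append(abs(fit.kon - 1e5) / 1e5 < 0.05
                        and abs(fit.koff - 1e-2) / 1e-2 < 0.05)
        assert all(hits)

    def test_too_few_concentrations_rejected(self):
        curves = synth.gen_sensorgrams(1e5, 1e-2, 100.0, [8, 32], SCHED, 0.0, 0)
        with pytest.raises(ValueError, match="at least 3"):
            spr.fit_kinetics_global(curves)


class TestEquilibriumFit:
    def test_exact_isotherm_recovery_and_scatchard_identity(self):
        kd, rmax = 30.0, 120.0
        table = {c: rmax * c / (kd + c) for c in (4, 8, 16, 32, 64, 128, 256, 512)}
        fit = spr.fit_equilibrium(table)
        assert fit.kd_nM == pytest.approx(kd, rel=1e-9)
        assert fit.rmax == pytest.approx(rmax, rel=1e-9)
        assert fit.scatchard_slope == pytest.approx(-1.0 / kd, rel=1e-9)
        assert fit.scatchard_intercept == pytest.approx(rmax / kd, rel=1e-9)

    def test_agrees_with_kinetic_analysis_on_same_system(self):
        kon, koff, rmax = 2e5, 4e-3, 100.0
        kd_nM = koff / kon * 1e9
        sched = spr.SensorgramSchedule(t_assoc=5000.0, t_dissoc=100.0, dt=5.0)
        table = {}
        for c in (4, 8, 16, 32, 64, 128, 256, 512):
            curve = spr.langmuir_response(kon, koff, rmax, c, sched)
            table[c] = spr.steady_state_response(curve, window=10.0)
        fit = spr.fit_equilibrium(table)
        assert fit.kd_nM == pytest.approx(kd_nM, rel=0.01)

    def test_concentrations_below_kd_flagged(self):
        kd, rmax = 5000.0, 100.0
        table = {c: rmax * c / (kd + c) for c in (1, 2, 4, 8)}
        fit = spr.fit_equilibrium(table)
        assert fit.ill_conditioned


class TestInitialRateCalibration:
    def test_initial_rate_approaches_analytic_derivative(self):
        # dR/dt at t=0 is kon*C*Rmax = 1.0 RU/s for these parameters
        sched = spr.SensorgramSchedule(t_assoc=30.0, t_dissoc=30.0, dt=0.01)
        curve = spr.langmuir_response(1e5, 1e-2, 100.0, 100.0, sched)
        assert spr.initial_rate(curve, window=0.1) == pytest.approx(1.0, rel=2e-3)

    def test_finite_window_underestimate_bounded_by_taylor_term(self):
        sched = spr.SensorgramSchedule(t_assoc=60.0, t_dissoc=30.0, dt=0.05)
        kon, koff, rmax, conc = 1e5, 1e-2, 100.0, 100.0
        kobs = kon * conc * 1e-9 + koff
        curve = spr.langmuir_response(kon, koff, rmax, conc, sched)
        window = 5.0
        rate = spr.initial_rate(curve, window=window)
        analytic = kon * conc * 1e-9 * rmax
        assert rate < analytic
        assert (analytic - rate) / analytic < kobs * window / 2

    def test_zero_curve_gives_zero_rate(self):
        t = np.arange(0.0, 60.0, 0.5)
        curve = spr.Sensorgram(t, np.zeros_like(t), 10.0, 30.0)
        assert spr.initial_rate(curve) == 0.0

    def test_window_beyond_association_rejected(self):
        sched = spr.SensorgramSchedule(t_assoc=10.0, t_dissoc=10.0, dt=0.5)
        curve = spr.langmuir_response(1e5, 1e-2, 100.0, 10.0, sched)
        with pytest.raises(ValueError, match="association"):
            spr.initial_rate(curve, window=20.0)

    def test_calibration_on_proportional_data(self):
        rates = [(c, 0.01 * c) for c in (1.5, 2.5, 5.0, 7.5, 10.0, 12.5)]
        cal = spr.calibration_fit(rates)
        assert cal.slope == pytest.approx(0.01, rel=1e-9)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        conc, in_range = cal.conc_for_rate(0.05)
        assert conc == pytest.approx(5.0) and in_range
        _, in_range = cal.conc_for_rate(0.5)
        assert not in_range

    def test_free_concentration_round_trip_through_calibration(self):
        sched = spr.SensorgramSchedule(t_assoc=30.0, t_dissoc=30.0, dt=0.1)
        kon, koff, rmax = 1e5, 1e-2, 100.0
        rates = [(c, spr.initial_rate(
            spr.langmuir_response(kon, koff, rmax, c, sched), window=2.0))
            for c in (1.5, 2.5, 5.0, 7.5, 10.0, 12.5)]
        cal = spr.calibration_fit(rates)
        for truth in (2.0, 6.0, 11.0):
            rate = spr.initial_rate(
                spr.langmuir_response(kon, koff, rmax, truth, sched), window=2.0)
            conc, in_range = cal.conc_for_rate(rate)
            assert in_range
            assert conc == pytest.approx(truth, rel=5e-3)

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            spr.calibration_fit([(5.0, 0.1), (5.0, 0.2), (5.0, 0.3)])


class TestSolutionAffinity:
    def test_no_competitor_leaves_analyte_free(self):
        assert spr.solution_free_analyte(10.0, 0.0, 10.0) == pytest.approx(10.0)

    def test_stoichiometric_titration_limit(self):
        assert spr.solution_free_analyte(10.0, 10.0, 1e-9) == pytest.approx(0.0, abs=1e-3)

    def test_quadratic_worked_example(self):
        af = spr.solution_free_analyte(10.0, 10.0, 10.0)
        assert af == pytest.approx(6.18, abs=0.005)
        # detailed balance: Af*Sf = Kd*(A0-Af)
        sf = 10.0 - (10.0 - af)
        assert af * sf == pytest.approx(10.0 * (10.0 - af), rel=1e-9)

    @given(a0=st.floats(0.1, 1000.0), s0=st.floats(0.0, 1000.0),
           kd=st.floats(0.01, 1000.0))
    def test_mass_balance_and_detailed_balance(self, a0, s0, kd):
        af = spr.solution_free_analyte(a0, s0, kd)
        complex_ = a0 - af
        sf = s0 - complex_
        assert 0.0 <= af <= a0 * (1 + 1e-12)
        assert sf >= -1e-9 * max(s0, 1.0)
        assert af * sf == pytest.approx(kd * complex_, rel=1e-9, abs=1e-9)

    def test_exact_series_recovers_kd(self):
        s0 = np.geomspace(0.1, 10_000.0, 12)
        free = spr.solution_free_analyte(10.0, s0, 15.0)
        fit = spr.fit_solution_affinity(spr.CompetitionSeries(10.0, s0, free))
        assert fit.kd_nM == pytest.approx(15.0, rel=1e-6)
        assert not fit.ill_conditioned

    def test_noisy_series_recovery_within_ten_percent(self):
        s0 = np.geomspace(0.1, 10_000.0, 12)
        truth = 15.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            free = spr.solution_free_analyte(10.0, s0, truth)
            noisy = np.clip(free * (1 + rng.normal(0, 0.02, free.size)), 0, 10.0)
            fit = spr.fit_solution_affinity(spr.CompetitionSeries(10.0, s0, noisy))
            assert fit.kd_nM == pytest.approx(truth, rel=0.10)

    def test_competition_agrees_with_direct_fit_on_matched_system(self):
        # the solution-phase Kd of a matched synthetic system must agree with
        # the Kd from the direct kinetic analysis
        kon, koff, rmax = 8.7e5, 12.9e-2, 100.0
        curves = synth.gen_sensorgrams(kon, koff, rmax,
                                       [4, 8, 16, 32, 64, 128, 256, 512],
                                       SCHED, 0.0, 0)
        kin = spr.fit_kinetics_global(curves)
        s0 = np.geomspace(0.1, 10_000.0, 12)
        free = spr.solution_free_analyte(100.0, s0, kin.kd_nM)
        sol = spr.fit_solution_affinity(spr.CompetitionSeries(100.0, s0, free))
        assert sol.kd_nM == pytest.approx(kin.kd_nM, rel=0.01)


class TestSensorgramIO:
    def test_csv_round_trip(self, tmp_path):
        curves = synth.gen_sensorgrams(1e5, 1e-2, 100.0, [8, 32, 128],
                                       SCHED, 1.0, seed=3)
        curves.write_csv(tmp_path / "spr")
        back = spr.SensorgramSet.read_csv(tmp_path / "spr" / "sensorgram_manifest.csv")
        assert back.concentrations_nM == curves.concentrations_nM
        for a, b in zip(back, curves):
            assert np.allclose(a.response, b.response)
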