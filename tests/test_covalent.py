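"""Covalent kinetics: mechanism simulation, linearization and the
k_inact/K_I inference chain."""

import numpy as np
import pytest

from covalkit import (
    FitError,
    MechanismParams,
    TimeSeries,
    analyze_covalent_fp,
    fit_efficiency_linear,
    fit_kinact_KI,
    fit_modification_timecourse,
    ki_at_t0,
    linearize_timecourse,
    simulate_mechanism,
)
from covalkit.equilibria import competitive_equilibrium
from covalkit.synthesize import default_spec, generate

K_INACT, K_I, K_i, K_L = 2.1e-4, 3.6e-6, 1.1e-6, 77.56e-9


def _mech(E=50e-9, P=10e-9, I=5e-6, kon_I=1e4, k_inact=K_INACT):
    return MechanismParams(
        kon_P=1e6, koff_P=1e6 * K_L, kon_I=kon_I, koff_I=kon_I * K_i,
        k_inact=k_inact, E_total=E, P_total=P, I_total=I,
    )


class TestSimulateMechanism:
    def test_mass_conservation(self):
        traj = simulate_mechanism(_mech(), np.linspace(1.0, 20000.0, 50))
        E_tot = traj["E"] + traj["EP"] + traj["EI"] + traj["EIx"]
        P_tot = traj["P"] + traj["EP"]
        I_tot = traj["I"] + traj["EI"] + traj["EIx"]
        assert np.max(np.abs(E_tot / 50e-9 - 1)) < 1e-8
        assert np.max(np.abs(P_tot / 10e-9 - 1)) < 1e-8
        assert np.max(np.abs(I_tot / 5e-6 - 1)) < 1e-8

    def test_no_inhibitor_settles_at_two_species_equilibrium(self):
        traj = simulate_mechanism(_mech(I=0.0), np.linspace(100.0, 5000.0, 20))
        eq = competitive_equilibrium(50e-9, 10e-9, 0.0, K_L, K_i)
        assert np.allclose(traj["EP"], eq["EL"], rtol=1e-6)

    def test_reversible_limit_matches_closed_form(self):
        # k_inact = 0: long-time EP equals the independent equilibrium solve
        traj = simulate_mechanism(_mech(k_inact=0.0),
                                  np.linspace(0.0, 50000.0, 30))
        eq = competitive_equilibrium(50e-9, 10e-9, 5e-6, K_L, K_i)
        assert traj["EP"][-1] == pytest.approx(eq["EL"], rel=1e-6)

    def test_irreversible_sink_empties_bound_probe(self):
        traj = simulate_mechanism(_mech(I=100e-6), np.linspace(0.0, 2e5, 40))
        assert traj["F_b"][-1] < 1e-4

    def test_pre_equilibrated_start(self):
        traj = simulate_mechanism(_mech(k_inact=0.0), np.linspace(0.0, 10.0, 5),
                                  pre_equilibrate=True)
        eq = competitive_equilibrium(50e-9, 10e-9, 5e-6, K_L, K_i)
        assert traj["EP"][0] == pytest.approx(eq["EL"], rel=1e-9)


class TestLinearizeTimecourse:
    def test_plain_slope_intercept_arithmetic(self):
        # exact straight line: k_obs = -slope/F_b0 = 1e-5/0.5
        t = np.linspace(0.0, 5000.0, 10)
        ts = TimeSeries(times=t, values=0.5 - 1.0e-5 * t)
        lin = linearize_timecourse(ts, curvature_correction=False)
        assert lin.F_b0 == pytest.approx(0.5, rel=1e-9)
        assert lin.k_obs == pytest.approx(2.0e-5, rel=1e-9)

    def test_flat_series_has_zero_rate(self):
        ts = TimeSeries(times=np.arange(6.0), values=np.full(6, 0.4))
        assert linearize_timecourse(ts).k_obs == 0.0

    def test_exponential_early_window_recovery(self):
        # f = 0.6 exp(-1e-4 t) sampled to t = 0.2/k
        k = 1e-4
        t = np.linspace(0.0, 0.2 / k, 11)
        ts = TimeSeries(times=t, values=0.6 * np.exp(-k * t))
        lin = linearize_timecourse(ts)
        assert lin.k_obs == pytest.approx(k, rel=0.05)
        assert lin.F_b0 == pytest.approx(0.6, rel=0.01)

    def test_curvature_correction_is_exact_on_first_order_decay(self):
        k = 2e-4
        t = np.linspace(0.0, 3600.0, 31)
        ts = TimeSeries(times=t, values=0.4 * np.exp(-k * t))
        lin = linearize_timecourse(ts)
        assert lin.k_obs == pytest.approx(k, rel=1e-6)
        raw = lin.flags["k_obs_raw"]
        assert raw < k  # the uncorrected ratio underestimates

    def test_rising_signal_warns_and_zeroes(self):
        t = np.linspace(0.0, 1000.0, 8)
        ts = TimeSeries(times=t, values=0.3 + 1e-4 * t)
        with pytest.warns(UserWarning, match="positive slope"):
            lin = linearize_timecourse(ts)
        assert lin.k_obs == 0.0
        assert lin.flags["wrong_sign_slope"]


class TestFitKinactKI:
    def test_half_saturation_at_KI(self):
        I = np.array([0.5, 1, 2, 3.6, 7, 15, 30, 60]) * 1e-6
        k = K_INACT * I / (K_I + I)
        fit = fit_kinact_KI(list(zip(I, k)))
        half = fit.k_inact * K_I / (fit.K_I + K_I)
        assert half == pytest.approx(fit.k_inact / 2.0, rel=1e-6)

    def test_noiseless_round_trip(self):
        I = 50e-6 / 2 ** np.arange(10)
        k = K_INACT * I / (K_I + I)
        fit = fit_kinact_KI(list(zip(I, k)))
        assert fit.k_inact == pytest.approx(K_INACT, rel=1e-6)
        assert fit.K_I == pytest.approx(K_I, rel=1e-6)
        assert fit.efficiency == pytest.approx(fit.k_inact / fit.K_I, rel=1e-9)

    def test_kobs_monotone_under_fitted_model(self):
        I = 50e-6 / 2 ** np.arange(8)
        k = K_INACT * I / (K_I + I)
        fit = fit_kinact_KI(list(zip(I, k)))
        grid = np.logspace(-8, -4, 50)
        kk = fit.k_inact * grid / (fit.K_I + grid)
        assert np.all(np.diff(kk) > 0)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_kinact_KI([(1e-6, 1e-5)] * 3)


class TestEfficiencyLinear:
    def test_exact_line_through_origin(self):
        I = np.linspace(0.05e-6, 0.7e-6, 8)
        fit = fit_efficiency_linear(list(zip(I, 58.0 * I)))
        assert fit.efficiency == pytest.approx(58.0, rel=1e-9)

    def test_truncated_saturation_data_matches_true_efficiency(self):
        # in the genuinely linear regime (I <= K_I/10) the zero-intercept
        # slope of saturation-model data reproduces k_inact/K_I; deeper
        # truncation biases the concentration-weighted slope low
        I = np.linspace(0.02e-6, 0.1 * K_I, 10)
        k = K_INACT * I / (K_I + I)  # generated from the saturation model
        fit = fit_efficiency_linear(list(zip(I, k)))
        assert fit.efficiency == pytest.approx(K_INACT / K_I, rel=0.10)

    def test_agrees_with_saturation_fit_on_shared_truth(self):
        I_low = np.linspace(0.02e-6, 0.1 * K_I, 8)
        I_all = 50e-6 / 2 ** np.arange(10)
        klow = K_INACT * I_low / (K_I + I_low)
        kall = K_INACT * I_all / (K_I + I_all)
        lin = fit_efficiency_linear(list(zip(I_low, klow)))
        sat = fit_kinact_KI(list(zip(I_all, kall)))
        assert lin.efficiency == pytest.approx(sat.efficiency, rel=0.10)

    def test_regime_violation_warns(self):
        I = np.array([0.5, 1, 2, 4]) * 1e-6
        with pytest.warns(UserWarning, match="linear-regime"):
            fit_efficiency_linear(list(zip(I, 58.0 * I)), K_I=K_I)

    def test_empty_input_rejected(self):
        with pytest.raises(FitError):
            fit_efficiency_linear([])


class TestKiAtT0:
    def test_reversible_equilibrium_recovery(self):
        E, L = 50e-9, 10e-9
        conc = np.concatenate([[0.0], 50e-6 / 2 ** np.arange(11)])
        fb0 = [(I, competitive_equilibrium(E, L, I, K_L, K_i)["EL"] / L)
               for I in conc]
        got, fit = ki_at_t0(fb0, L, K_L, E)
        assert got == pytest.approx(K_i, rel=0.15)
        assert got <= fit.IC50

    def test_no_effect_is_an_error(self):
        conc = np.concatenate([[0.0], 50e-6 / 2 ** np.arange(7)])
        fb0 = [(I, 0.39) for I in conc]
        with pytest.raises(FitError):
            ki_at_t0(fb0, 10e-9, K_L, 50e-9)


class TestFullPipeline:
    def test_mechanistic_simulation_recovery(self):
        # rapid-equilibrium regime, protein well below K_L so the probe
        # readout stays proportional to surviving protein
        kon_I = 1e4
        KI_true = (kon_I * K_i + K_INACT) / kon_I
        times = np.linspace(0.0, 3600.0, 31)
        pairs = []
        for I in 50e-6 / 2 ** np.arange(10):
            p = _mech(E=2e-9, P=5e-9, I=I, kon_I=kon_I)
            traj = simulate_mechanism(p, times, pre_equilibrate=True)
            ts = TimeSeries(times=times, values=traj["F_b"],
                            inhibitor_concentration=I)
            pairs.append((I, linearize_timecourse(ts).k_obs))
        fit = fit_kinact_KI(pairs)
        assert fit.k_inact == pytest.approx(K_INACT, rel=0.15)
        assert fit.K_I == pytest.approx(KI_true, rel=0.15)
        assert fit.efficiency == pytest.approx(K_INACT / KI_true, rel=0.15)

    def test_synthetic_assay_recovery_with_noise(self, calib, write_dataset):
        import covalkit.io as io

        path, truth = write_dataset(default_spec("covalent_fp", seed=21))
        series = io.average_replicates(io.read_timecourse_csv(path))
        res = analyze_covalent_fp(series, calib, truth["probe"], truth["K_L"],
                                  truth["protein"])
        assert res.k_inact == pytest.approx(truth["k_inact"], rel=0.15)
        assert res.K_I == pytest.approx(truth["K_I"], rel=0.15)
        assert res.Ki_t0 == pytest.approx(truth["K_i"], rel=0.15)


class TestModificationTimecourse:
    def test_inverse_identity_t95(self):
        k = np.log(20.0) / 7200.0
        t = np.linspace(0.0, 7200.0, 13)
        ts = TimeSeries(times=t, values=1.0 - np.exp(-k * t))
        fit = fit_modification_timecourse(ts)
        assert fit["t95"] == pytest.approx(7200.0, rel=1e-6)

    def test_noisy_recovery(self, write_dataset):
        path, truth = write_dataset(default_spec("modification_ms", seed=31))
        import pandas as pd

        df = pd.read_csv(path)
        ts = TimeSeries(times=df["time_s"].to_numpy(),
                        values=df["response"].to_numpy())
        fit = fit_modification_timecourse(ts)
        assert fit["k"] == pytest.approx(truth["k"], rel=0.10)

    def test_out_of_range_fraction_rejected(self):
        ts = TimeSeries(times=np.arange(4.0), values=[0.0, 0.5, 1.1, 1.0])
        with pytest.raises(ValueError):
            fit_modification_timecourse(ts)
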