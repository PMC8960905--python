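"""Inversion of the flux/turnover equations, rescaling, regimes, bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rankdyn import (
    ModelParams,
    RankTable,
    bootstrap_curve_test,
    estimate_system_size,
    fit_parameters,
    fit_table,
    measure_flux_turnover,
    mean_flux_theory,
    mean_turnover_theory,
    regime_classify,
    regime_scan,
    regime_weights,
    rescale_parameters,
    simulate,
    subsampling_analysis,
)
from rankdyn.fitting import NotRescalableError


class TestEstimateSystemSize:
    def test_closed_table(self, static_table):
        N, p = estimate_system_size(static_table)
        assert (N, p) == (3, 1.0)

    def test_hand_count(self, tiny_table):
        N, p = estimate_system_size(tiny_table)
        assert N == 4
        assert p == pytest.approx(0.75)

    def test_grows_with_window(self):
        params = ModelParams(N=100, N0=60, tau=0.1, nu=0.1, T=200, seed=8)
        table = simulate(params)
        n_short, _ = estimate_system_size(
            RankTable(occupants=table.occupants[:20])
        )
        n_long, _ = estimate_system_size(table)
        assert n_long > n_short


class TestFitParameters:
    def test_forward_inverse_round_trip(self):
        F = mean_flux_theory(0.1, 0.2, 0.8)
        od = mean_turnover_theory(0.1, 0.2, 0.8)
        fit = fit_parameters(F, od, 0.8)
        assert fit.converged
        assert fit.tau_hat == pytest.approx(0.1, abs=1e-6)
        assert fit.nu_hat == pytest.approx(0.2, abs=1e-6)
        assert fit.residual < 1e-8

    @settings(max_examples=60, deadline=None)
    @given(
        tau=st.floats(0.01, 1.0),
        nu=st.floats(0.01, 1.0),
        p=st.floats(0.1, 0.99),
    )
    def test_round_trip_property(self, tau, nu, p):
        F = mean_flux_theory(tau, nu, p)
        od = mean_turnover_theory(tau, nu, p)
        fit = fit_parameters(F, od, p)
        assert fit.converged
        assert fit.tau_hat == pytest.approx(tau, abs=1e-6, rel=1e-6)
        assert fit.nu_hat == pytest.approx(nu, abs=1e-6, rel=1e-6)

    def test_closed_system(self):
        fit = fit_parameters(0.0, 0.0, 0.5)
        assert (fit.tau_hat, fit.nu_hat) == (0.0, 0.0)
        assert fit.converged
        assert any("unidentifiable" in w for w in fit.warnings)

    def test_zero_flux_positive_turnover_infeasible(self):
        fit = fit_parameters(0.0, 0.1, 0.5)
        assert not fit.converged
        assert any("infeasible" in w for w in fit.warnings)

    def test_p_one_closed_window(self):
        fit = fit_parameters(0.3, -math.log(0.7), 1.0)
        assert fit.tau_hat == 0.0
        assert fit.nu_hat == pytest.approx(-math.log(0.7))
        assert fit.converged
        assert any("unidentifiable" in w for w in fit.warnings)

    def test_infeasible_pair_falls_back(self):
        # turnover far above what any (tau, nu) can produce at this flux
        fit = fit_parameters(0.05, 0.9, 0.5)
        assert not fit.converged
        assert fit.method == "least_squares"
        assert fit.tau_hat >= 0 and fit.nu_hat >= 0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fit_parameters(1.0, 0.1, 0.5)
        with pytest.raises(ValueError):
            fit_parameters(0.1, -0.1, 0.5)
        with pytest.raises(ValueError):
            fit_parameters(0.1, 0.1, 1.5)

    def test_recovery_from_simulation_moderate_nu(self):
        # at small nu the closed forms' per-step linearization bias is small:
        # nu is recovered well, tau keeps a positive documented bias
        taus, nus = [], []
        for seed in range(8):
            table = simulate(
                ModelParams(N=500, N0=400, tau=0.1, nu=0.05, T=300, seed=seed)
            )
            s = measure_flux_turnover(table)
            fit = fit_parameters(s.mean_flux, s.mean_turnover_rate, 0.8)
            taus.append(fit.tau_hat)
            nus.append(fit.nu_hat)
        assert np.mean(nus) == pytest.approx(0.05, rel=0.05)
        assert np.mean(taus) == pytest.approx(0.1, rel=0.35)


class TestRescaling:
    def test_on_curve_point(self):
        # o_dot from the turnover equation at (0.05, 0.1, 0.25) is 2/15 and
        # this point satisfies the universal curve exactly
        od = mean_turnover_theory(0.05, 0.1, 0.25)
        assert od == pytest.approx(2.0 / 15.0, rel=1e-12)
        resc = rescale_parameters(0.05, 0.1, 0.25, od)
        assert resc.tau_r == pytest.approx(2.0, rel=1e-12)
        assert resc.nu_r == pytest.approx(0.5, rel=1e-12)
        assert resc.product == pytest.approx(1.0, rel=1e-12)
        assert resc.curve_distance == pytest.approx(0.0, abs=1e-12)

    def test_nu_r_zero(self):
        resc = rescale_parameters(0.1, 0.05, 0.5, 0.1)
        assert resc.nu_r == 0.0

    def test_not_rescalable(self):
        with pytest.raises(NotRescalableError, match="p"):
            rescale_parameters(0.1, 0.1, 1.0, 0.1)
        with pytest.raises(NotRescalableError, match="o_dot"):
            rescale_parameters(0.1, 0.1, 0.5, 0.0)


class TestRegimes:
    def test_diffusion_example(self):
        label, w = regime_classify(0.1, 0.2)
        assert label == "diffusion"
        assert w.w_diff == pytest.approx(0.741, abs=1e-3)

    def test_levy_and_replacement_limits(self):
        assert regime_classify(5.0, 0.01)[0] == "levy"
        assert regime_classify(0.01, 5.0)[0] == "replacement"

    def test_agrees_with_argmax(self):
        rng = np.random.default_rng(1)
        for tau, nu in rng.uniform(0, 3, size=(300, 2)):
            label, w = regime_classify(tau, nu)
            vals = {"levy": w.w_levy, "diffusion": w.w_diff,
                    "replacement": w.w_repl}
            assert vals[label] == max(vals.values())

    def test_scan_rows_consistent(self):
        scan = regime_scan(0.3, 0.05, n_points=40)
        assert len(scan) == 40
        sums = scan[["w_levy", "w_diff", "w_repl"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert np.allclose(scan.tau_r * scan.nu_r, 1.0, atol=1e-6)
        # monotone in tau along the scan; crossover exists when ends differ
        assert scan.tau.is_monotonic_increasing
        assert scan.w_levy.is_monotonic_increasing
        first = regime_classify(scan.tau.iloc[0], scan.nu.iloc[0])[0]
        last = regime_classify(scan.tau.iloc[-1], scan.nu.iloc[-1])[0]
        labels = [
            regime_classify(row.tau, row.nu)[0] for row in scan.itertuples()
        ]
        if first != last:
            assert len(set(labels)) >= 2

    def test_scan_domain(self):
        with pytest.raises(ValueError):
            regime_scan(1.0, 0.1)
        with pytest.raises(ValueError):
            regime_scan(0.5, 0.0)


class TestSubsamplingAnalysis:
    def test_k1_matches_plain_fit(self, sim_table_open):
        rep = subsampling_analysis(sim_table_open, [1])
        fit = fit_table(sim_table_open)
        row = rep.iloc[0]
        assert row.tau_hat == pytest.approx(fit.tau_hat)
        assert row.nu_hat == pytest.approx(fit.nu_hat)
        assert row.replacement_rate == pytest.approx(fit.nu_hat)

    def test_replacement_rate_roughly_constant(self):
        table = simulate(
            ModelParams(N=200, N0=100, tau=0.1, nu=0.01, T=600, seed=5)
        )
        rep = subsampling_analysis(table, [1, 2, 4])
        rates = rep.replacement_rate.to_numpy()
        assert (rates.max() - rates.min()) / rates.mean() <= 0.2

    def test_moves_down_the_curve(self):
        # subsampling increases per-observation turnover: tau_r shrinks
        table = simulate(
            ModelParams(N=200, N0=100, tau=0.1, nu=0.01, T=600, seed=7)
        )
        rep = subsampling_analysis(table, [1, 4])
        assert rep.tau_r.iloc[1] < rep.tau_r.iloc[0]

    def test_t_eff(self):
        table = simulate(ModelParams(N=50, N0=30, tau=0.2, nu=0.1, T=10, seed=0))
        rep = subsampling_analysis(table, [3])
        assert rep.T_eff.iloc[0] == 4  # ceil(10/3)


class TestBootstrapCurveTest:
    def test_n_boot_zero_error(self, sim_table_open, sim_params_open):
        fit = fit_table(sim_table_open)
        with pytest.raises(ValueError):
            bootstrap_curve_test(fit, sim_params_open, n_boot=0, seed=1)

    def test_model_data_calibration(self):
        # model-generated data should rarely be flagged
        flags = []
        for seed in range(5):
            table = simulate(
                ModelParams(N=150, N0=100, tau=0.15, nu=0.05, T=100, seed=seed)
            )
            fit = fit_table(table)
            params = ModelParams(
                N=fit.N, N0=fit.N0, tau=fit.tau_hat, nu=fit.nu_hat,
                T=table.n_times, seed=seed,
            )
            res = bootstrap_curve_test(fit, params, n_boot=30, seed=seed + 77)
            flags.append(res.exceed_flag)
        assert np.mean(flags) <= 0.2

    def test_nonstationary_input_is_farther(self):
        # switching tau mid-series should push the fit off the curve more
        # than a matched stationary control (compare medians over seeds)
        dist_switch, dist_control = [], []
        for seed in range(6):
            a = simulate(ModelParams(N=120, N0=80, tau=0.02, nu=0.02, T=60,
                                     seed=seed))
            b = simulate(ModelParams(N=120, N0=80, tau=0.8, nu=0.02, T=61,
                                     seed=seed + 500))
            # prefix second-half ids: the two runs name elements independently
            switched = RankTable(
                occupants=a.occupants
                + [["b" + el for el in row] for row in b.occupants[1:]]
            )
            control = simulate(ModelParams(N=120, N0=80, tau=0.41, nu=0.02,
                                           T=120, seed=seed + 1000))
            for table, acc in ((switched, dist_switch), (control, dist_control)):
                fit = fit_table(table)
                d = rescale_parameters(
                    fit.tau_hat, fit.nu_hat, fit.p, fit.o_dot_obs
                ).curve_distance
                acc.append(d)
        assert np.median(dist_switch) > np.median(dist_control)
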