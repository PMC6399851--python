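"""Erlang lag distribution, linear chain reduction and renewal oracle."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp
from scipy.stats import erlang as scipy_erlang

from bystander_tgi import (
    AgeStructureParameters,
    ChainState,
    GridError,
    PayloadParameters,
    TumorParameters,
    chain_rhs,
    emax_inhibition,
    erlang_pdf,
    erlang_survival,
    growth_modifier,
    hazard_rate,
    initial_chain_state,
    renewal_integral_reference,
    simulate_age_structured,
    simulate_tgi,
)


class TestErlangPrimitives:
    def test_single_stage_is_exponential(self):
        age = AgeStructureParameters(theta=0.25, n_shape=1)
        a = np.linspace(0, 2, 50)
        np.testing.assert_allclose(erlang_pdf(a, age), np.exp(-a / 0.25) / 0.25)
        np.testing.assert_allclose(erlang_survival(a, age), np.exp(-a / 0.25))

    @pytest.mark.parametrize("n", [1, 2, 5, 20])
    def test_density_normalises_and_has_mean_n_theta(self, n):
        age = AgeStructureParameters(theta=0.1, n_shape=n)
        total, _ = quad(lambda a: erlang_pdf(a, age), 0, np.inf, limit=200)
        mean, _ = quad(lambda a: a * erlang_pdf(a, age), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)
        assert mean == pytest.approx(age.mean_lag, rel=1e-8)

    @pytest.mark.parametrize("n", [1, 3, 10])
    def test_matches_scipy_reference_distribution(self, n):
        age = AgeStructureParameters(theta=0.3, n_shape=n)
        a = np.linspace(0.0, 5.0, 101)
        np.testing.assert_allclose(
            erlang_pdf(a, age), scipy_erlang.pdf(a, n, scale=0.3), rtol=1e-12
        )
        np.testing.assert_allclose(
            erlang_survival(a, age), scipy_erlang.sf(a, n, scale=0.3), rtol=1e-10
        )

    def test_survival_solves_hazard_ode(self):
        # dPhi/da = -gamma(a) Phi(a), checked by central differences
        age = AgeStructureParameters(theta=0.1, n_shape=5)
        h = 1e-5
        for a in (0.1, 0.5, 1.0, 2.0):
            dphi = (erlang_survival(a + h, age) - erlang_survival(a - h, age)) / (2 * h)
            residual = dphi + hazard_rate(a, age) * erlang_survival(a, age)
            assert residual == pytest.approx(0.0, abs=1e-6)

    def test_hazard_limits(self):
        memoryless = AgeStructureParameters(theta=0.2, n_shape=1)
        assert hazard_rate(0.0, memoryless) == pytest.approx(5.0)
        assert hazard_rate(3.0, memoryless) == pytest.approx(5.0)
        multi = AgeStructureParameters(theta=0.2, n_shape=2)
        assert hazard_rate(0.0, multi) == 0.0
        # asymptote 1/theta far beyond the mean lag
        far = 100 * multi.mean_lag
        assert hazard_rate(far, multi) == pytest.approx(5.0, rel=1e-2)

    def test_hazard_increasing_for_multistage(self):
        age = AgeStructureParameters(theta=0.1, n_shape=4)
        a = np.linspace(0.0, 3.0, 200)
        np.testing.assert_array_less(np.diff(hazard_rate(a, age)) * -1, 0)

    def test_negative_age_rejected(self, age_params):
        for fn in (erlang_pdf, erlang_survival, hazard_rate):
            with pytest.raises(ValueError):
                fn(-0.1, age_params)

    @pytest.mark.parametrize("kwargs", [{"theta": 0.0}, {"n_shape": 0}, {"n_shape": 1.5}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AgeStructureParameters(**kwargs)


class TestChain:
    def test_quasi_steady_single_stage_recovers_memoryless_rate(self):
        # with F1 = theta*drive the outflux equals the drive exactly
        age = AgeStructureParameters(theta=0.1, n_shape=1)
        drive = 321.0
        state = ChainState((age.theta * drive,), tumor=1000.0)
        df, d_tumor = chain_rhs(state, age, lam=0.5, drive=drive)
        assert df[0] == pytest.approx(0.0, abs=1e-10)
        assert d_tumor == pytest.approx(drive - 0.5 * 1000.0)

    def test_zero_drive_and_empty_chain_decays_at_lam(self, age_params):
        state = ChainState((0.0,) * age_params.n_shape, tumor=800.0)
        df, d_tumor = chain_rhs(state, age_params, lam=0.5, drive=0.0)
        np.testing.assert_allclose(df, 0.0)
        assert d_tumor == pytest.approx(-0.5 * 800.0)

    def test_printed_initial_condition_loads_stage_one_only(
        self, dr_params, tumor_params, age_params
    ):
        st = initial_chain_state(700.0, dr_params, tumor_params, age_params, "impulse")
        assert st.f_phi[0] == pytest.approx(tumor_params.c * dr_params.e0 * 700.0)
        assert all(v == 0.0 for v in st.f_phi[1:])

    def test_steady_initial_condition_balances_drug_free_drive(
        self, dr_params, tumor_params, age_params
    ):
        st = initial_chain_state(700.0, dr_params, tumor_params, age_params, "steady")
        drive = (
            tumor_params.c
            * dr_params.e0
            * growth_modifier(700.0, tumor_params)
            * 700.0
        )
        df, d_tumor = chain_rhs(st, age_params, tumor_params.lam, drive)
        np.testing.assert_allclose(df, 0.0, atol=1e-9)
        assert d_tumor == pytest.approx(drive - tumor_params.lam * 700.0)


class TestSimulation:
    def test_undosed_tumor_never_declines(self, dr_params, tumor_params, age_params):
        grid = np.linspace(0, 30, 301)
        traj = simulate_age_structured(
            PayloadParameters(c0=0.0), dr_params, tumor_params, age_params, grid
        )
        assert np.all(np.diff(traj["T_total"]) > -1e-9)

    def test_initial_delay_despite_full_dose(
        self, payload_params, dr_params, tumor_params, age_params
    ):
        # the hallmark of the age-structured model: the tumor keeps
        # growing above T0 for an initial interval although 200 nM of
        # payload is present from t = 0
        grid = np.linspace(0, 60, 601)
        traj = simulate_age_structured(
            payload_params, dr_params, tumor_params, age_params, grid
        )
        total = traj["T_total"]
        assert np.all(total[1:21] > tumor_params.t0)  # first two days
        assert total[-1] < tumor_params.t0  # inhibition eventually dominates

    def test_peak_time_increases_with_stage_count(
        self, payload_params, dr_params, tumor_params
    ):
        grid = np.linspace(0, 20, 2001)
        peaks = []
        for n in (1, 5, 10, 20):
            traj = simulate_age_structured(
                payload_params,
                dr_params,
                tumor_params,
                AgeStructureParameters(n_shape=n),
                grid,
            )
            peaks.append(grid[np.argmax(traj["T_total"])])
        assert peaks == sorted(peaks)
        assert peaks[0] < peaks[-1]

    def test_memoryless_limit_as_theta_vanishes(
        self, payload_params, dr_params, tumor_params
    ):
        grid = np.linspace(0, 30, 301)
        reference = simulate_tgi(payload_params, dr_params, tumor_params, grid)
        gaps = []
        for theta in (0.1, 0.01, 0.001):
            traj = simulate_age_structured(
                payload_params,
                dr_params,
                tumor_params,
                AgeStructureParameters(theta=theta, n_shape=1),
                grid,
                method="LSODA",
            )
            gaps.append(
                np.max(
                    np.abs(traj["T_total"] - reference["T_total"])
                    / reference["T_total"]
                )
            )
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[-1] < 1e-3

    def test_single_stage_chain_matches_explicit_lag_system(
        self, payload_params, dr_params, tumor_params
    ):
        """Independent oracle: hand-written payload + single-lag ODEs."""
        age = AgeStructureParameters(theta=0.1, n_shape=1)
        grid = np.linspace(0, 20, 201)
        traj = simulate_age_structured(
            payload_params, dr_params, tumor_params, age, grid,
            rtol=1e-10, atol=1e-10,
        )

        pp, tu, dr = payload_params, tumor_params, dr_params

        def rhs(t, y):
            cp, cn, ce, f1a, t1, f1b, t2 = y
            dcp = pp.beta * pp.k_in * ce - pp.k_out * cp
            dcn = (1 - pp.beta) * pp.k_in * ce - pp.k_out * cn
            dce = -pp.k_in * ce + pp.k_out * (cp + cn)
            out = [dcp, dcn, dce]
            for conc, f1, ts in ((cp, f1a, t1), (cn, f1b, t2)):
                e = emax_inhibition(max(conc, 0.0), dr)
                f = 1.0 - ts / tu.tmax
                drive = tu.c * e * f * ts
                out.append(drive - f1 / age.theta)
                out.append(f1 / age.theta - tu.lam * ts)
            return out

        g0 = age.theta * tu.c * dr.e0
        y0 = [
            pp.c0, 0.0, 0.0,
            g0 * (1 - 700.0 / tu.tmax) * 700.0, 700.0,
            g0 * (1 - 300.0 / tu.tmax) * 300.0, 300.0,
        ]
        sol = solve_ivp(rhs, (0, 20), y0, t_eval=grid, rtol=1e-10, atol=1e-10)
        total = sol.y[4] + sol.y[6]
        np.testing.assert_allclose(traj["T_total"], total, rtol=1e-7)


class TestRenewalOracle:
    @pytest.mark.parametrize("n", [1, 2, 5])
    def test_chain_equals_renewal_integral(
        self, payload_params, dr_params, tumor_params, n
    ):
        age = AgeStructureParameters(n_shape=n)
        h = age.theta / 40
        grid = np.arange(0.0, 30.0 + h / 2, h)
        chain = simulate_age_structured(
            payload_params, dr_params, tumor_params, age, grid,
            rtol=1e-10, atol=1e-10,
        )
        renewal = renewal_integral_reference(
            payload_params, dr_params, tumor_params, age, grid
        )
        rel = np.max(
            np.abs(chain["T_total"] - renewal["T_total"]) / chain["T_total"]
        )
        assert rel < 1e-3

    def test_impulse_history_matches_printed_initial_condition_chain(
        self, payload_params, dr_params, tumor_params
    ):
        age = AgeStructureParameters(n_shape=2)
        h = age.theta / 40
        grid = np.arange(0.0, 10.0 + h / 2, h)
        chain = simulate_age_structured(
            payload_params, dr_params, tumor_params, age, grid,
            initial_chain="impulse", rtol=1e-10, atol=1e-10,
        )
        renewal = renewal_integral_reference(
            payload_params, dr_params, tumor_params, age, grid,
            initial_history="impulse",
        )
        rel = np.max(
            np.abs(chain["T_total"] - renewal["T_total"]) / chain["T_total"]
        )
        assert rel < 1e-3

    def test_zero_drive_decays_exponentially(self, dr_params, age_params):
        # a vanishing growth coefficient leaves only -lam*T
        tumor = TumorParameters(c=1e-12)
        h = age_params.theta / 10
        grid = np.arange(0.0, 5.0 + h / 2, h)
        traj = renewal_integral_reference(
            PayloadParameters(c0=0.0), dr_params, tumor, age_params, grid
        )
        expect = 1000.0 * np.exp(-tumor.lam * grid)
        # second-order march: global error ~ (lam*h)^2 over the horizon
        np.testing.assert_allclose(traj["T1"] + traj["T2"], expect, rtol=1e-4)

    def test_coarse_grid_rejected(
        self, payload_params, dr_params, tumor_params, age_params
    ):
        grid = np.linspace(0.0, 10.0, 101)  # step 0.1 = theta, too coarse
        with pytest.raises(GridError):
            renewal_integral_reference(
                payload_params, dr_params, tumor_params, age_params, grid
            )

    def test_nonuniform_grid_rejected(
        self, payload_params, dr_params, tumor_params, age_params
    ):
        grid = np.array([0.0, 0.001, 0.01, 0.02])
        with pytest.raises(GridError):
            renewal_integral_reference(
                payload_params, dr_params, tumor_params, age_params, grid
            )
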