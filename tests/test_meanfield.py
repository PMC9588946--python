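from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from critnet import meanfield as mf
from critnet.params import DriveParams, NeuronParams, STPParams


@pytest.fixture(scope="module")
def params():
    return mf.MeanFieldParams()


@pytest.fixture(scope="module")
def avalanche_params():
    return mf.MeanFieldParams(
        drive=DriveParams(rho_ext_E=230.0, rho_ext_I=150.0))


class TestAveragePotential:
    def test_zero_rates_leak(self, params):
        assert mf.average_potential(0.0, 0.0, params) == params.neuron.v_leak

    def test_excitation_dominant_limit(self, params):
        v = mf.average_potential(1e9, 0.0, params)
        # clamped at threshold: the reset bounds the time-averaged level
        assert v == params.neuron.v_th

    def test_inhibition_dominant_limit(self, params):
        v = mf.average_potential(0.0, 1e9, params, "I")
        assert v == pytest.approx(params.neuron.V_R_inh, abs=1e-3)

    def test_matches_ode_steady_state(self, params):
        """Equals the voltage equation's fixed point at time-averaged g."""
        n = params.neuron
        rho_E, rho_I = 5.0, 12.0
        aE = (params.k["EE"] * params.w["EE"] * n.g0_exc * rho_E * 1e-3
              * n.tau_syn_exc)
        aI = (params.k["EI"] * params.w["EI"] * n.g0_inh * rho_I * 1e-3
              * n.tau_syn_inh)

        def rhs(t, v):
            return ((n.v_leak - v) + aE * (n.V_R_exc - v)
                    + aI * (n.V_R_inh - v)) / n.tau_m

        sol = solve_ivp(rhs, (0, 2000.0), [n.v_rest], rtol=1e-10)
        assert mf.average_potential(rho_E, rho_I, params) == pytest.approx(
            sol.y[0, -1], abs=1e-5)


class TestCouplingCoefficients:
    def test_signs(self, params):
        c = mf.coupling_coefficients(params, 5.0, 10.0)
        assert c["EE"] > 0 and c["IE"] > 0
        assert c["EI"] < 0 and c["II"] < 0

    def test_zero_weight_zero_coefficient(self, params):
        p = replace(params, w={**params.w, "EI": 0.0})
        assert mf.coupling_coefficients(p, 5.0, 10.0)["EI"] == 0.0

    def test_linear_in_degree(self, params):
        # at zero rates the potentials are pinned at v_leak, so the
        # coefficient is exactly linear in the degree
        c1 = mf.coupling_coefficients(params, 0.0, 0.0)
        p2 = replace(params, k={**params.k, "EE": 2 * params.k["EE"]})
        c2 = mf.coupling_coefficients(p2, 0.0, 0.0)
        assert c2["EE"] == pytest.approx(2 * c1["EE"])

    def test_reference_table_near_slope_matching(self, params):
        """The balanced weight table sits close to the slope condition
        c_EE c_II = c_EI c_IE at mid-interval potentials."""
        r = mf.bt_residuals(params, 10.0, 30.0)
        c = mf.coupling_coefficients(params, 10.0, 30.0)
        assert abs(r.slope) < 0.1 * abs(c["EE"] * c["II"])


class TestFixedPoints:
    def test_subthreshold_drive_single_quiescent(self):
        p = mf.MeanFieldParams(
            drive=DriveParams(rho_ext_E=100.0, rho_ext_I=100.0))
        fps = mf.find_fixed_points(p, grid_n=100)
        assert len(fps) == 1
        assert fps[0].regime == "Q"
        assert "stable" in fps[0].classification

    def test_residual_and_classification(self, avalanche_params):
        for fp in mf.find_fixed_points(avalanche_params, grid_n=100):
            r = mf.rate_ode_rhs((fp.rho_E, fp.rho_I), avalanche_params)
            assert np.linalg.norm(r) < 1e-6
            if fp.det < 0:
                assert fp.classification == "saddle"
            elif fp.trace < 0:
                assert fp.classification.startswith("stable")

    def test_matches_brute_force_grid(self, avalanche_params):
        """Dense residual-grid root scan finds the same solutions."""
        fps = mf.find_fixed_points(avalanche_params, grid_n=100)
        grid = np.linspace(0, 600, 400)
        best = []
        res = np.empty((400, 400))
        for i, a in enumerate(grid):
            for j, b in enumerate(grid):
                r = mf.rate_ode_rhs((a, b), avalanche_params)
                res[i, j] = np.linalg.norm(r)
        # every reported fixed point has a near-zero residual cell nearby
        for fp in fps:
            i = np.argmin(np.abs(grid - fp.rho_E))
            j = np.argmin(np.abs(grid - fp.rho_I))
            assert res[i, j] < 0.6  # coarse cell
        # conversely every deep local minimum is near a reported root
        for i in range(1, 399):
            for j in range(1, 399):
                if res[i, j] < 0.005:
                    assert any(abs(grid[i] - fp.rho_E) < 5
                               and abs(grid[j] - fp.rho_I) < 5
                               for fp in fps)

    def test_stable_point_attracts_trajectories(self, avalanche_params):
        fps = [f for f in mf.find_fixed_points(avalanche_params, grid_n=100)
               if f.classification.startswith("stable")]
        fp = fps[0]
        y0 = [fp.rho_E + 0.5, fp.rho_I + 0.5]
        sol = solve_ivp(lambda t, y: mf.rate_ode_rhs(y, avalanche_params),
                        (0, 2000.0), y0, rtol=1e-9)
        assert np.allclose(sol.y[:, -1], [fp.rho_E, fp.rho_I], atol=1e-3)


class TestNullclines:
    def test_points_satisfy_equations(self, avalanche_params):
        grid = np.linspace(0.0, 400.0, 25)
        cE, cI, ratios = mf.nullclines(avalanche_params, grid)
        for pt in cE[:50]:
            r = mf.rate_ode_rhs(pt, avalanche_params)
            assert abs(r[0]) < 1e-6
        for pt in cI[:50]:
            r = mf.rate_ode_rhs(pt, avalanche_params)
            assert abs(r[1]) < 1e-6

    def test_intersections_are_fixed_points(self, avalanche_params):
        fps = mf.find_fixed_points(avalanche_params, grid_n=100)
        grid = np.linspace(0.0, 500.0, 200)
        cE, cI, _ = mf.nullclines(avalanche_params, grid)
        # each fixed point lies on both curves (within grid resolution)
        for fp in fps:
            dE = np.min(np.hypot(cE[:, 0] - fp.rho_E, cE[:, 1] - fp.rho_I))
            dI = np.min(np.hypot(cI[:, 0] - fp.rho_E, cI[:, 1] - fp.rho_I))
            assert dE < 5.0 and dI < 5.0


class TestBTResiduals:
    def test_exact_slope_match_zero(self, params):
        # force c_EE c_II = c_EI c_IE = 0 by zeroing one factor per side
        p = replace(params, w={"EE": 0.0, "EI": 1.5, "IE": 0.0, "II": 2.0})
        r = mf.bt_residuals(p, 0.0, 0.0)
        assert r.slope == pytest.approx(0.0)

    def test_hand_arithmetic(self, params):
        c = mf.coupling_coefficients(params, 5.0, 15.0)
        r = mf.bt_residuals(params, 5.0, 15.0)
        d = params.d
        assert r.slope == pytest.approx(
            c["EE"] * c["II"] - c["EI"] * c["IE"])
        assert r.intercept == pytest.approx(
            params.drive.rho_ext_E
            - ((c["EE"] / c["IE"]) * (params.drive.rho_ext_I - d) + d))
        assert r.deltaW == pytest.approx(0.54 * 2.0 - 1.5 * 0.75)

    def test_effective_weight_enters_deltaW(self, params):
        r = mf.bt_residuals(replace(params, u_eff=0.5), 0.0, 0.0)
        assert r.deltaW == pytest.approx(0.5 * 0.54 * 2.0 - 1.5 * 0.75)


class TestSlowFast:
    def test_q_zero_relaxes_to_baseline(self, params):
        stp = STPParams(q=0.0, tau_STP=50.0)
        d = mf.slow_fast_rhs((10.0, 20.0), 0.3, params, stp)
        mu = params.neuron.tau_m / stp.tau_STP
        assert d[2] == pytest.approx(mu * (params.w["EE"] - 0.3))

    def test_stationary_weight_matches_depression_formula(self, params):
        stp = STPParams(q=0.3, tau_STP=50.0)
        rho_E = 20.0
        w_st = params.w["EE"] / (1 + stp.tau_STP * stp.q * rho_E * 1e-3)
        d = mf.slow_fast_rhs((rho_E, 0.0), w_st, params, stp)
        assert d[2] == pytest.approx(0.0, abs=1e-12)


class TestUpDown:
    def test_q_zero_conditions_exclusive(self, params):
        stp = STPParams(q=0.0, tau_STP=50.0)
        c1, c2 = mf.up_down_conditions(params, stp, 100.0)
        assert not (c1 and c2)

    def test_updown_parameter_set(self):
        """w0=0.74, W_EI=2, q=0.4: both switching conditions hold at the
        high-state rate."""
        p = mf.MeanFieldParams(
            w={"EE": 0.74, "EI": 2.0, "IE": 0.75, "II": 2.0},
            drive=DriveParams(rho_ext_E=400.0, rho_ext_I=150.0))
        fps = mf.find_fixed_points(p, grid_n=100)
        rho_H = max(fp.rho_E for fp in fps)
        assert rho_H > 100.0
        stp = STPParams(q=0.4, tau_STP=50.0)
        c1, c2 = mf.up_down_conditions(p, stp, rho_H)
        assert c1 and c2

    def test_matches_direct_inequalities(self, rng, params):
        for _ in range(20):
            w0 = rng.uniform(0.1, 2.0)
            wEI = rng.uniform(0.1, 3.0)
            rho_H = rng.uniform(10.0, 400.0)
            q = rng.uniform(0.05, 0.9)
            p = replace(params, w={**params.w, "EE": w0, "EI": wEI})
            stp = STPParams(q=q, tau_STP=50.0)
            c1, c2 = mf.up_down_conditions(p, stp, rho_H)
            kEE, kEI = p.k["EE"], p.k["EI"]
            assert c1 == (kEE * w0 > kEI * wEI)
            assert c2 == (kEE * w0 / (1 + 50.0 * q * rho_H * 1e-3)
                          < kEI * wEI)


class TestScan:
    def test_regime_labels_far_corners(self, params):
        labels = mf.scan_bifurcation(params, [0.3], [100.0], grid_n=60)
        assert labels[0, 0] == ("Q",)

    def test_labels_change_with_drive(self, params):
        labels = mf.scan_bifurcation(params, [0.54],
                                     [100.0, 230.0, 380.0], grid_n=80)
        assert len(set(labels[0])) >= 2
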