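import numpy as np
import pytest
from scipy import integrate

from critnet import plasticity as pl
from critnet.network import SynapseTable, build_network
from critnet.params import (ConfigError, NetworkConfig, STDPKernel,
                            STPParams, default_kernels)
from critnet.synthetic import poisson_train
from tests_support_allpairs import all_pairs_totals


class TestSTDPRule:
    def test_single_pair_delta(self):
        k = default_kernels()["E"]
        for d in (0.0, 3.0, 25.0):
            assert pl.stdp_delta(d, k) == pytest.approx(
                k.A_plus * np.exp(-d / k.tau_plus))
        assert pl.stdp_delta(-4.0, k) == pytest.approx(
            -k.A_minus * np.exp(-4.0 / k.tau_minus))

    def test_isolated_pre_spike_no_change(self, small_net):
        tr = pl.TraceState.zeros(small_net.N)
        d = pl.stdp_on_spike(tr, small_net, default_kernels(), 0, "pre")
        assert np.all(d == 0.0)

    def test_trace_replay_equals_all_pairs(self, small_net):
        """Trace algorithm vs exhaustive summation on a 1 s record."""
        rng = np.random.default_rng(7)
        events = []
        for nid in range(small_net.N):
            for t in poisson_train(20.0, 1000.0, seed=100 + nid):
                events.append((t, nid))
        events.sort()
        times = np.array([e[0] for e in events])
        ids = np.array([e[1] for e in events])
        kernels = default_kernels()
        w0 = np.zeros(small_net.n_edges)
        syn = SynapseTable(small_net.N_exc, small_net.N_inh, small_net.pre,
                           small_net.post, w0, small_net.cls)
        w_final = pl.replay_stdp(times, ids, syn, kernels, clip=False)
        oracle = all_pairs_totals(times, ids, syn, kernels)
        assert np.max(np.abs((w_final - w0) - oracle)) < 1e-10

    def test_uncorrelated_poisson_mean_drift(self):
        """Independent trains: mean total change ~ rho^2 T Khat."""
        kernels = default_kernels()
        kE = kernels["E"]
        syn = SynapseTable(2, 0, pre=[0], post=[1], weight=[1e6], cls=[0])
        T, rate = 2000.0, 50.0
        tot = []
        for s in range(40):
            tp = poisson_train(rate, T, seed=2 * s)
            ti = poisson_train(rate, T, seed=2 * s + 1)
            times = np.concatenate([tp, ti])
            ids = np.concatenate([np.zeros(tp.size, int),
                                  np.ones(ti.size, int)])
            tot.append(all_pairs_totals(times, ids, syn, kernels)[0])
        expect = (rate * 1e-3) ** 2 * T * kE.integral
        tot = np.array(tot)
        se = tot.std(ddof=1) / np.sqrt(tot.size)
        assert abs(tot.mean() - expect) < 4 * se

    def test_weights_never_leave_bounds(self, small_net):
        """Clipping contract under an aggressive random spike sequence."""
        from critnet.simulate import simulate
        from critnet.params import DriveParams
        kernels = {
            "E": STDPKernel(A_plus=0.05, A_minus=0.06, kind="E"),
            "I": STDPKernel(A_plus=0.05, A_minus=0.04, kind="I"),
        }
        syn = build_network(NetworkConfig(
            N_exc=40, N_inh=10, k_EE=5, k_EI=2, k_IE=5, k_II=2, seed=4))
        wmax = np.array([4 * syn.weight[syn.cls == c].mean()
                         for c in range(4)])
        drive = DriveParams(rho_ext_E=2000.0, rho_ext_I=1500.0, w_ext=0.54)
        res = simulate(syn, drive, 2000.0, dt=0.1, seed=1, stdp=kernels)
        assert res.spikes.n_spikes > 100
        assert np.all(syn.weight >= 0.0)
        for c in range(4):
            assert np.all(syn.weight[syn.cls == c] <= wmax[c] + 1e-12)


class TestSTP:
    def test_depletion_step(self):
        assert pl.stp_on_pre_spike(1.0, 0.3) == pytest.approx(0.7)
        assert pl.stp_on_pre_spike(0.5, 0.0) == 0.5

    def test_recovery(self):
        assert pl.stp_decay(1.0, 5.0, 50.0) == 1.0
        assert pl.stp_decay(0.5, 50.0, 50.0) == pytest.approx(
            1 - 0.5 * np.exp(-1))

    def test_periodic_train_fixed_point(self):
        """Iterated jump-decay map converges to the closed form."""
        q, tau, T = 0.25, 80.0, 30.0
        u = 1.0
        for _ in range(500):
            u = pl.stp_decay(pl.stp_on_pre_spike(u, q), T, tau)
        expect = (1 - np.exp(-T / tau)) / (1 - (1 - q) * np.exp(-T / tau))
        assert u == pytest.approx(expect, rel=1e-10)

    def test_poisson_mean_efficacy(self):
        """Long-run mean under Poisson input ~ 1/(1 + tau q rho)."""
        stp = STPParams(q=0.2, tau_STP=100.0)
        rate = 40.0
        spikes = poisson_train(rate, 400_000.0, seed=3)
        u, t_last, acc, t_acc = 1.0, 0.0, 0.0, 0.0
        for t in spikes:
            # time-average of the exponential segment between spikes
            dt = t - t_last
            if dt > 0:
                seg = dt + (u - 1.0) * stp.tau_STP * (
                    1 - np.exp(-dt / stp.tau_STP))
                acc += seg
                t_acc += dt
            u = pl.stp_on_pre_spike(pl.stp_decay(u, dt, stp.tau_STP),
                                    stp.q)
            t_last = t
        mean_u = acc / t_acc
        expect = pl.stationary_efficacy(rate, stp)
        assert mean_u == pytest.approx(expect, rel=0.05)

    def test_effective_weight(self):
        assert pl.effective_weight(0.54, 0.5) == pytest.approx(0.27)


class TestAveragedODE:
    def test_zero_rates_zero_drift(self):
        d = pl.mean_weight_ode_rhs(
            (0.0, 0.0), (0.5, 1.5, 0.75, 2.0), default_kernels(),
            {"E": pl.CorrelationKernel(), "I": pl.CorrelationKernel()},
            (-57.0, -57.0))
        assert np.all(d == 0.0)

    def test_stationary_ratio_matches_quadrature(self):
        kernels = default_kernels()
        gammas = {"E": pl.CorrelationKernel(gamma_bar=1.3, tau_gamma=4.0),
                  "I": pl.CorrelationKernel(gamma_bar=0.8, tau_gamma=6.0)}
        r = pl.stationary_ratio_from_kernels(kernels, gammas)
        num = {}
        for cls in ("E", "I"):
            k = kernels[cls]
            num[cls], _ = integrate.quad(
                lambda d: k.A_plus * np.exp(-d / k.tau_plus)
                * gammas[cls](d), 0, np.inf)
        expect = (kernels["I"].integral * num["E"]) / (
            kernels["E"].integral * num["I"])
        assert r == pytest.approx(expect, rel=1e-6)

    def test_ratio_scale_invariant(self):
        gammas = {"E": pl.CorrelationKernel(), "I": pl.CorrelationKernel()}
        a = pl.stationary_ratio_from_kernels(default_kernels(1.0), gammas)
        b = pl.stationary_ratio_from_kernels(default_kernels(7.0), gammas)
        assert a == pytest.approx(b)

    def test_sign_violation_rejected(self):
        gammas = {"E": pl.CorrelationKernel(), "I": pl.CorrelationKernel()}
        ks = default_kernels()
        with pytest.raises(pl.StabilityError):
            # I-type kernel passed in the E slot has a positive integral
            pl.stationary_ratio_from_kernels(
                {"E": ks["I"], "I": ks["I"]}, gammas)

    def test_ode_stationary_state_satisfies_balance_ratio(self):
        """The zero-drift weights obey the common coupling-ratio condition.

        At the stationary point of the averaged system the ratios
        c_EI/c_EE and c_II/c_IE (with c_xy ~ w_xy (V_R_y - <V_x>), equal
        degree factors) coincide at the kernel-determined value."""
        from scipy.optimize import brentq
        from critnet.params import NeuronParams
        kernels = default_kernels()
        gammas = {"E": pl.CorrelationKernel(gamma_bar=1.0),
                  "I": pl.CorrelationKernel(gamma_bar=1.0)}
        rates = (8.0, 20.0)
        VE, VI = -56.0, -58.0
        n = NeuronParams()

        def comp(idx, w):
            weights = [0.5, 1.5, 0.75, 2.0]
            weights[idx] = w
            return pl.mean_weight_ode_rhs(rates, weights, kernels, gammas,
                                          (VE, VI))[idx]

        wst = [brentq(lambda w: comp(i, w), 1e-9, 1e4) for i in range(4)]
        wEE, wEI, wIE, wII = wst
        ratio1 = (wEI * (n.V_R_inh - VE)) / (wEE * (n.V_R_exc - VE))
        ratio2 = (wII * (n.V_R_inh - VI)) / (wIE * (n.V_R_exc - VI))
        target = pl.stationary_ratio_from_kernels(kernels, gammas)
        assert ratio1 == pytest.approx(target, rel=1e-8)
        assert ratio2 == pytest.approx(target, rel=1e-8)

    def test_stable_lines_converge_to_stationary_weights(self):
        """The inhibitory-presynaptic lines relax to their fixed points
        (the excitatory lines are Hebbian-unstable at fixed rates)."""
        from scipy.integrate import solve_ivp
        kernels = default_kernels()
        gammas = {"E": pl.CorrelationKernel(), "I": pl.CorrelationKernel()}
        rates = (8.0, 20.0)
        pots = (-56.0, -58.0)

        def rhs(t, w):
            d = pl.mean_weight_ode_rhs(rates, [0.5, w[0], 0.75, w[1]],
                                       kernels, gammas, pots)
            return [d[1], d[3]]

        sol = solve_ivp(rhs, (0, 1e7), [0.1, 5.0], rtol=1e-10, atol=1e-12)
        wEI, wII = sol.y[:, -1]
        assert rhs(0, [wEI, wII])[0] == pytest.approx(0.0, abs=1e-12)
        assert rhs(0, [wEI, wII])[1] == pytest.approx(0.0, abs=1e-12)
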