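import numpy as np
import pytest

from oscmem import meanfield_models as mf
from oscmem import dynamics_analysis as da

OMEGA = 2 * np.pi * 8.0 / 1000.0


class TestGain:
    def test_gain_zero_is_one(self):
        assert mf.gain(0.0) == 1.0

    def test_matches_monte_carlo(self):
        # intrinsic error of the erf substitution peaks at ~0.021 (delta=0.5)
        rng = np.random.default_rng(0)
        z = rng.standard_normal(1_000_000)
        for delta in (0.5, 1.0, 2.0, 5.0):
            mc = np.mean(1.0 - np.tanh(delta * z) ** 2)
            assert abs(mf.gain(delta**2) - mc) < 0.025

    def test_strictly_decreasing(self):
        assert mf.gain(4.0) < mf.gain(1.0) < mf.gain(0.0)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            mf.gain(-0.1)

    def test_bounds(self):
        vals = mf.gain(np.linspace(0, 100, 50))
        assert np.all(vals > 0) and np.all(vals <= 1.0)

    def test_exact_gain_quadrature(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(500_000)
        for delta in (0.0, 0.5, 1.0, 3.0):
            mc = np.mean(1.0 - np.tanh(delta * z) ** 2)
            assert abs(mf.gain_exact(delta**2) - mc) < 2e-3


class TestMeanfieldRhs:
    def test_zero_covariance_pure_decay(self):
        mix = mf.MixtureConnectivity.empty(2, 2, ["I_osc", "I_s1", "I_s2"])
        kappa = np.array([0.7, -0.4])
        inputs = {"I_osc": 0.3, "I_s1": 0.0, "I_s2": 0.0}
        rhs = mf.meanfield_rhs(mix, kappa, inputs, tau=20.0)
        np.testing.assert_allclose(rhs, -kappa / 20.0, atol=1e-10)

    def test_skew_symmetric_rotation_rate(self):
        """Single population with rotational structure: angular velocity matches
        sigma_{n1 m2} * gain with Delta^2 = sigma_m^2 r^2."""
        mix = mf.MixtureConnectivity.empty(1, 2, ["I_osc"])
        rho, eta, sm = 2.0, 1.5, 1.2
        mix.weights = np.array([1.0])
        for v in ("m1", "m2"):
            mix.set(0, v, v, sm**2)
        for v in ("n1", "n2"):
            mix.set(0, v, v, 8.0)
        mix.set(0, "m1", "n1", rho)
        mix.set(0, "m2", "n2", rho)
        mix.set(0, "m1", "n2", eta)
        mix.set(0, "m2", "n1", -eta)
        r = 0.8
        kappa = np.array([r, 0.0])
        rhs = mf.meanfield_rhs(mix, kappa, {"I_osc": 0.0}, tau=20.0)
        g = mf.gain(sm**2 * r**2)
        phidot = (kappa[0] * rhs[1] - kappa[1] * rhs[0]) / r**2
        assert phidot == pytest.approx(eta * g / 20.0, rel=1e-10)

    def test_dimension_mismatch_raises(self):
        mix = mf.MixtureConnectivity.empty(1, 2, ["I_osc"])
        with pytest.raises(ValueError):
            mf.meanfield_rhs(mix, [0.1], {"I_osc": 0.0})

    def test_phi_contributions_sum(self):
        mix = mf.design_two_stim(calibrate=False)
        fld = mf.MeanFieldKappaField(mix)
        kappa = np.array([0.9, 0.3])
        contribs = fld.phi_contributions(kappa, 0.7)
        rhs = fld.rhs_batch(kappa[None, :], 0.7)[0]
        total = (kappa[0] * rhs[1] - kappa[1] * rhs[0]) / (kappa @ kappa)
        # contributions exclude the -kappa decay term, which is tangentially zero
        assert np.sum(contribs) / fld.tau == pytest.approx(total, rel=1e-9)

    def test_analytic_jacobian_matches_fd(self):
        mix = mf.design_two_stim(calibrate=False)
        fld = mf.MeanFieldKappaField(mix)
        kappa = np.array([0.8, -0.5])
        J = fld.jac(kappa, 1.1)
        Jfd = da.FieldBase.jac(fld, kappa, 1.1)
        np.testing.assert_allclose(J, Jfd, atol=1e-6)


class TestSampleNetwork:
    def test_component_covariances_recovered(self):
        mix = mf.design_two_stim(calibrate=False)
        net = mf.sample_network(mix, 4096, seed=0)
        # block allocation: first component occupies the first w_0*N units
        n0 = int(round(mix.weights[0] * 4096))
        m1 = net.m[:n0, 0]
        n1 = net.n[:n0, 0]
        est = np.cov(m1, n1)[0, 1]
        true = mix.get(0, "m1", "n1")
        sd = np.sqrt(
            (mix.get(0, "m1", "m1") * mix.get(0, "n1", "n1") + true**2) / n0
        )
        assert abs(est - true) < 3 * sd

    def test_single_population(self):
        mix = mf.MixtureConnectivity.empty(1, 2, ["I_osc"])
        mix.weights = np.array([1.0])
        for v in ("m1", "m2", "n1", "n2", "I_osc", "w"):
            mix.set(0, v, v, 1.0)
        net = mf.sample_network(mix, 64, seed=1)
        assert net.N == 64
        assert net.m.shape == (64, 2)

    def test_determinism(self):
        mix = mf.design_two_stim(calibrate=False)
        a = mf.sample_network(mix, 256, seed=5)
        b = mf.sample_network(mix, 256, seed=5)
        np.testing.assert_array_equal(a.m, b.m)

    def test_tiny_component_raises(self):
        mix = mf.MixtureConnectivity.empty(2, 2, ["I_osc"])
        mix.weights = np.array([0.999, 0.001])
        with pytest.raises(ValueError):
            mf.sample_network(mix, 100, seed=0)


class TestDesignTwoStim:
    @pytest.fixture(scope="class")
    def mix(self):
        return mf.design_two_stim()

    def test_oscillator_unconnected_to_inputs(self, mix):
        for inp in ("I_osc", "I_s1", "I_s2"):
            assert mix.get(0, inp, inp) < 1e-6

    def test_printed_sign_pattern(self, mix):
        # sigma_{I n1}^{p2} = -sigma_{I n2}^{p2} = -sigma_{I n1}^{p3} = sigma_{I n2}^{p3}
        g = mix.get(1, "I_osc", "n1")
        assert g != 0
        assert mix.get(1, "I_osc", "n2") == pytest.approx(-g)
        assert mix.get(2, "I_osc", "n1") == pytest.approx(-g)
        assert mix.get(2, "I_osc", "n2") == pytest.approx(g)

    def test_two_locked_zeros_of_coupling(self, mix):
        from oscmem import phase_reduction as pr

        fld = mf.MeanFieldKappaField(mix, h=1.0)
        coup = pr.extract_coupling(fld, n_theta=48, n_phi=48)
        locked = pr.census_attractors(coup, n_init=12, n_cycles=60)
        assert len(locked) == 2
        assert abs(abs(locked[1] - locked[0]) - np.pi) < 0.35

    def test_stimulus_saturates_population(self, mix):
        fld = mf.MeanFieldKappaField(mix, h=1.0).with_stimulus(0, 2.0)
        gains = fld.population_gains(np.array([1.0, 0.0]), 0.0)
        assert gains[1] < 0.1  # population 2 inhibited by stimulus a
        assert gains[2] > 0.2

    def test_tonic_stimulus_then_release_selects_cycle(self, mix):
        fld = mf.MeanFieldKappaField(mix, h=1.0)
        targets = {}
        for stim in (0, 1):
            ends = []
            for psi0 in np.linspace(0, 2 * np.pi, 8, endpoint=False):
                k = np.array([[np.cos(psi0), np.sin(psi0)]])
                f_s = fld.with_stimulus(stim, 2.0)
                for _ in range(15):
                    k = f_s.map_batch(k, 1)
                for _ in range(25):
                    k = fld.map_batch(k, 1)
                ends.append(np.arctan2(k[0, 1], k[0, 0]))
            spread = np.abs(np.angle(np.exp(1j * (np.array(ends) - ends[0]))))
            assert np.max(spread) < 0.2  # all initial phases -> same cycle
            targets[stim] = ends[0]
        diff = abs(np.angle(np.exp(1j * (targets[0] - targets[1]))))
        assert abs(diff - np.pi) < 0.35


class TestDesignFourStim:
    @pytest.fixture(scope="class")
    def mix(self):
        return mf.design_four_stim()

    def test_four_locked_phases(self, mix):
        fld = mf.MeanFieldKappaField(mix, h=2.0)
        angles = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        k = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        for _ in range(60):
            k = fld.map_batch(k, 1)
        psi = np.mod(np.arctan2(k[:, 1], k[:, 0]), 2 * np.pi)
        clusters = np.unique(np.round(psi / np.pi, 1))
        assert len(clusters) == 4

    def test_stimulus_collapses_to_single_phase(self, mix):
        fld = mf.MeanFieldKappaField(mix, h=2.0)
        ends = []
        for stim in range(4):
            f_s = fld.with_stimulus(stim, 2.0)
            angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
            k = np.stack([np.cos(angles), np.sin(angles)], axis=1)
            for _ in range(50):
                k = f_s.map_batch(k, 1)
            psi = np.arctan2(k[:, 1], k[:, 0])
            spread = np.abs(np.angle(np.exp(1j * (psi - psi[0]))))
            assert np.max(spread) < 0.2
            ends.append(psi[0])
        # the four selected phases are pairwise distinct
        for i in range(4):
            for j in range(i + 1, 4):
                assert abs(np.angle(np.exp(1j * (ends[i] - ends[j])))) > 0.5

    def test_stimulus_inhibits_all_but_one(self, mix):
        fld = mf.MeanFieldKappaField(mix, h=2.0).with_stimulus(1, 2.0)
        gains = fld.population_gains(np.array([1.0, 0.0]), 0.0)
        # populations are [oscillator, c1, c2, c3, c4]; stimulus 2 spares c2
        assert gains[2] > 0.2
        for idx in (1, 3, 4):
            assert gains[idx] < 0.1

    def test_coupling_has_cos4_component(self, mix):
        from oscmem import phase_reduction as pr

        fld = mf.MeanFieldKappaField(mix, h=2.0)
        coup = pr.extract_coupling(fld, n_theta=48, n_phi=64)
        # averaged coupling over theta at locked difference psi:
        psis = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ths = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        gbar = np.array([np.mean(coup(ths, ths + p)) for p in psis])
        spec = np.abs(np.fft.rfft(gbar - gbar.mean()))
        assert spec[4] > spec[1]  # cos(4 psi)-type term dominates
        # 4 stable zeros = 8 sign changes... at least 8 crossings
        crossings = np.sum(np.diff(np.sign(gbar)) != 0)
        assert crossings >= 8


class TestDesignRateCodingRank1:
    @pytest.fixture(scope="class")
    def mix(self):
        return mf.design_rate_coding_rank1()

    def test_three_stable_zeros(self, mix):
        grid = np.linspace(-4, 4, 801)
        zeros = mf.stable_zeros_1d(grid, mf.flow_1d(mix, grid))
        assert len(zeros) == 3
        assert min(abs(z) for z in zeros) < 0.05  # one at the origin
        assert zeros[0] == pytest.approx(-zeros[2], abs=0.05)

    def test_outputs_antiphase(self, mix):
        grid = np.linspace(-4, 4, 801)
        zeros = mf.stable_zeros_1d(grid, mf.flow_1d(mix, grid))
        ths = np.linspace(0, 2 * np.pi, 64, endpoint=False)

        def lag(kap):
            outs = np.array(
                [
                    mf.meanfield_readout(mix, [kap], mf.input_values(mix, 1.0, OMEGA, 20.0, th, {}), "tanh_out")
                    for th in ths
                ]
            )
            cs = 2 * np.mean(outs * np.sin(ths))
            cc = 2 * np.mean(outs * np.cos(ths))
            return np.arctan2(-cc, cs), np.hypot(cs, cc)

        l0, a0 = lag(zeros[1])
        lp, ap = lag(zeros[2])
        assert a0 > 0.1 and ap > 0.1
        assert abs(np.angle(np.exp(1j * (l0 - lp)))) == pytest.approx(np.pi, abs=0.15)

    def test_stimulus_steering_of_flow(self, mix):
        grid = np.linspace(-4, 4, 801)
        za = mf.stable_zeros_1d(grid, mf.flow_1d(mix, grid, stim_values={"I_s1": 1.0}))
        assert len(za) == 1 and abs(za[0]) < 0.1
        zb = mf.stable_zeros_1d(grid, mf.flow_1d(mix, grid, stim_values={"I_s2": 1.0}))
        assert len(zb) == 1 and abs(zb[0]) > 1.0


class TestDesignPhasePrecession:
    @pytest.fixture(scope="class")
    def mix(self):
        return mf.design_phase_precession()

    def _locked_phase(self, mix, s):
        fld = mf.MeanFieldKappaField(mix, h=2.0, stim_values=mf.precession_inputs(s))
        k = np.array([[1.0, 0.3]])
        for _ in range(50):
            k = fld.map_batch(k, 1)
        return np.arctan2(k[0, 1], k[0, 0])

    def test_monotone_in_s(self, mix):
        phases = [self._locked_phase(mix, s) for s in np.linspace(0, 1, 6)]
        diffs = np.angle(np.exp(1j * np.diff(phases)))
        assert np.all(diffs < 0) or np.all(diffs > 0)

    def test_continuity(self, mix):
        p1 = self._locked_phase(mix, 0.5)
        p2 = self._locked_phase(mix, 0.52)
        assert abs(np.angle(np.exp(1j * (p1 - p2)))) < 0.1

    def test_coupling_translates_between_endpoints(self, mix):
        from oscmem import phase_reduction as pr

        grids = {}
        for s in (0.0, 1.0):
            fld = mf.MeanFieldKappaField(mix, h=2.0, stim_values=mf.precession_inputs(s))
            coup = pr.extract_coupling(fld, r=1.0, n_theta=32, n_phi=64)
            ths = coup.theta_grid
            psis = np.linspace(0, 2 * np.pi, 64, endpoint=False)
            grids[s] = np.array([np.mean(coup(ths, ths + p)) for p in psis])
        a = grids[0.0] - grids[0.0].mean()
        b = grids[1.0] - grids[1.0].mean()
        # best circular shift correlation is high: translated versions
        corr = np.fft.ifft(np.fft.fft(a) * np.conj(np.fft.fft(b))).real
        best = corr.max() / (np.linalg.norm(a) * np.linalg.norm(b))
        assert best > 0.9
        assert int(np.argmax(corr)) != 0  # nonzero translation


class TestMeanFieldConsistency:
    def test_sampled_network_tracks_meanfield(self):
        from oscmem import rnn_core as rc

        mix = mf.design_two_stim()
        fld = mf.MeanFieldKappaField(mix, h=0.5)
        fps = [f for f in da.find_fixed_points(fld, tol=1e-8) if f.stable]
        assert len(fps) == 2
        k0 = fps[0].kappa_star
        ths, mftraj = fld.orbit(k0, n_periods=10)
        net = mf.sample_network(mix, 4096, seed=3)
        wt = fld.omega * fld.tau
        v0 = 1 / np.sqrt(wt**2 + 1) * np.sin(-np.arctan(wt))
        x0 = net.m[:, 0] * k0[0] + net.m[:, 1] * k0[1] + net.I_osc * v0
        u = np.sin(ths)[None, :]
        xs, _ = rc.simulate_batch(net, u, np.zeros((1, len(ths), 2)), 0.5, x0=x0)
        mm = (net.m**2).sum(axis=0)
        knet = np.stack([(xs[:, 0, :] @ net.m[:, i]) / mm[i] for i in range(2)], axis=1)
        rel = np.sqrt(np.mean((knet - mftraj) ** 2)) / np.sqrt(np.mean(mftraj**2))
        assert rel < 0.1


class TestFitMixture:
    def test_parameter_recovery_three_components(self):
        mix = mf.design_two_stim(calibrate=False)
        net = mf.sample_network(mix, 3000, seed=7)
        res = mf.fit_mixture(net, L_range=[3], seed=0)
        fitted = res[3]["mixture"]
        # match fitted components to truth by closest covariance distance
        X, names = mf.connectivity_matrix(net)
        assert names == mix.names
        used = set()
        for l_true in range(3):
            dists = []
            for l_fit in range(3):
                d = np.linalg.norm(fitted.covs[l_fit] - mix.covs[l_true])
                dists.append((d, l_fit))
            d, best = min(dists)
            rel = d / np.linalg.norm(mix.covs[l_true])
            assert rel < 0.35, f"component {l_true} not recovered (rel {rel:.2f})"
            used.add(best)
        assert len(used) == 3

    def test_strong_mean_prior(self):
        from sklearn.mixture import BayesianGaussianMixture

        mix = mf.design_two_stim(calibrate=False)
        net = mf.sample_network(mix, 1500, seed=2)
        X, _ = mf.connectivity_matrix(net)
        gm = BayesianGaussianMixture(
            n_components=3, covariance_type="full",
            mean_precision_prior=1e6, mean_prior=np.zeros(X.shape[1]),
            max_iter=300, random_state=0,
        ).fit(X)
        assert np.all(np.linalg.norm(gm.means_, axis=1) < 1e-2)

    def test_resampled_networks_recover_task(self, sine_ref, task_cfg):
        from oscmem import task_generator as tg

        mix = mf.design_two_stim()
        net = mf.sample_network(mix, 2048, seed=3)
        trials = [tg.make_trial(sine_ref, k % 2, task_cfg, seed=900 + k) for k in range(16)]
        res = mf.fit_mixture(net, L_range=[3], seed=1, n_resample=5, eval_trials=trials)
        losses = res[3]["losses"]
        model_loss = res[3]["model_loss"]
        # a nonzero fraction of resampled networks performs comparably
        assert np.sum(np.asarray(losses) < max(2 * model_loss, 0.5)) >= 1
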