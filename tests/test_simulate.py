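"""Closed-form dynamics, integrator properties, and sFC correctness."""

import numpy as np
import pytest

import parcelfit as pf
from parcelfit.exceptions import (DivergenceError, InvalidArgumentError,
                                  UndefinedCorrelationError)


def _pair_network(w=1.0, length=10.0):
    weights = np.array([[0.0, w], [w, 0.0]])
    lengths = np.array([[0.0, length], [length, 0.0]])
    return pf.ModelNetwork(weights=weights, lengths=lengths)


def _silent(n):
    """Config factory for noise-free runs."""
    def make(**kw):
        kw.setdefault("noise_amplitude", 0.0)
        return pf.SimulationConfig(**kw)
    return make


class TestClosedFormDynamics:
    def test_uncoupled_hopf_radius_and_period(self):
        # radial equation r' = (a - r^2) r has stable fixed point sqrt(a)
        a, f = 0.25, 0.05
        net = _pair_network(w=0.0)
        params = pf.RegionalParameters(frequencies=[f, f], amplitudes=[a, a])
        config = pf.SimulationConfig(duration=400.0, transient=300.0,
                                     noise_amplitude=0.0, seed=4,
                                     model_kind="limit_cycle")
        run = pf.simulate_network(net, params, 0.0, 0.0, config)
        x = run.observables[:, 0]
        # amplitude of x = Re(z) equals the orbit radius
        assert abs(np.max(np.abs(x)) - np.sqrt(a)) < 1e-3
        # period from mean spacing of upward zero crossings: 1/f = 20 s
        up = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
        period = np.diff(run.times[up]).mean()
        assert abs(period - 1.0 / f) <= run.config.dt

    def test_uncoupled_phase_matches_analytic(self):
        freqs = np.array([0.03, 0.05, 0.08])
        net = pf.ModelNetwork(weights=np.zeros((3, 3)),
                              lengths=np.zeros((3, 3)))
        params = pf.RegionalParameters(frequencies=freqs)
        config = pf.SimulationConfig(duration=100.0, transient=0.0,
                                     noise_amplitude=0.0, seed=11,
                                     model_kind="phase")
        run = pf.simulate_network(net, params, 0.0, 0.0, config)
        analytic = np.sin(run.initial_state[None, :]
                          + 2 * np.pi * freqs[None, :] * run.times[:, None])
        assert np.max(np.abs(run.observables - analytic)) < 1e-6

    def test_two_identical_oscillators_synchronize(self):
        # delta' = -C w sin(delta): the in-phase state attracts
        net = _pair_network(w=1.0)
        params = pf.RegionalParameters(frequencies=[0.05, 0.05])
        config = pf.SimulationConfig(duration=400.0, transient=300.0,
                                     noise_amplitude=0.0, seed=2,
                                     model_kind="phase")
        run = pf.simulate_network(net, params, 1.0, 0.0, config)
        assert np.max(np.abs(run.observables[:, 0]
                             - run.observables[:, 1])) < 1e-4

    @pytest.mark.parametrize("margin,locked", [(1.2, True), (0.8, False)])
    def test_locking_threshold(self, margin, locked):
        # two detuned oscillators lock iff 2 pi |df| <= C w; probe both
        # sides at C w = 2 pi |df| * (1 +/- 0.2)
        df = 0.02
        w = 1.0
        # phase difference obeys d' = 2 pi df - C w sin(d) for N = 2
        c = margin * 2 * np.pi * df / w
        net = _pair_network(w=w)
        params = pf.RegionalParameters(frequencies=[0.05 - df / 2,
                                                    0.05 + df / 2])
        config = pf.SimulationConfig(duration=4000.0, transient=500.0,
                                     noise_amplitude=0.0, seed=8,
                                     model_kind="phase")
        run = pf.simulate_network(net, params, c, 0.0, config)
        # locked: both observables share one spectral peak; drifting: they
        # keep distinct mean frequencies
        t = run.observables.shape[0]
        freqs = np.fft.rfftfreq(t, d=config.dt)
        power = np.abs(np.fft.rfft(run.observables - run.observables.mean(0),
                                   axis=0)) ** 2
        peaks = freqs[np.argmax(power, axis=0)]
        gap = abs(peaks[0] - peaks[1])
        bin_width = freqs[1] - freqs[0]
        if locked:
            assert gap <= bin_width
        else:
            assert gap > 5 * bin_width

    def test_noise_free_error_shrinks_with_dt(self):
        # deterministic Heun is consistent: halving dt shrinks the error
        # against the exact uncoupled-Hopf radius relaxation
        a = 0.25
        net = _pair_network(w=0.0)
        params = pf.RegionalParameters(frequencies=[0.05, 0.05],
                                       amplitudes=[a, a])
        errors = []
        for dt in (0.06, 0.03):
            config = pf.SimulationConfig(dt=dt, duration=150.0,
                                         transient=100.0,
                                         noise_amplitude=0.0, seed=13,
                                         model_kind="limit_cycle")
            run = pf.simulate_network(net, params, 0.0, 0.0, config)
            x = run.observables[:, 0]
            errors.append(abs(np.max(np.abs(x)) - np.sqrt(a)))
        assert errors[1] < errors[0] / 2 or errors[1] < 1e-9


class TestIntegratorContracts:
    def test_determinism(self, small_network, regional_params):
        config = pf.SimulationConfig(duration=100.0, transient=10.0, seed=21)
        a = pf.simulate_network(small_network, regional_params, 0.2, 5.0,
                                config)
        b = pf.simulate_network(small_network, regional_params, 0.2, 5.0,
                                config)
        np.testing.assert_array_equal(a.observables, b.observables)

    def test_retained_length_and_bounds(self, small_network, regional_params):
        config = pf.SimulationConfig(duration=120.0, transient=30.0, seed=1)
        run = pf.simulate_network(small_network, regional_params, 0.3, 4.0,
                                  config)
        assert run.observables.shape == (int(90 / 0.06), 24)
        assert np.all(np.abs(run.observables) <= 1.0)

    def test_full_synchronization_limit(self):
        # identical frequencies, no delay, homogeneous strong coupling:
        # noise-driven spread vanishes as C grows, so sFC approaches 1
        n = 10
        w = np.ones((n, n)) - np.eye(n)
        net = pf.ModelNetwork(weights=w, lengths=np.zeros((n, n)))
        params = pf.RegionalParameters(frequencies=np.full(n, 0.05))
        config = pf.SimulationConfig(duration=700.0, transient=500.0, seed=6,
                                     model_kind="phase")
        run = pf.simulate_network(net, params, 10.0, 0.0, config)
        sfc = pf.compute_sfc(run)
        assert np.min(sfc) > 0.99

    def test_divergence_reported_with_parameter_point(self):
        net = _pair_network(w=1.0)
        params = pf.RegionalParameters(frequencies=[0.05, 0.05],
                                       amplitudes=[4000.0, 4000.0])
        config = pf.SimulationConfig(duration=50.0, transient=0.0,
                                     noise_amplitude=0.0, seed=3,
                                     model_kind="limit_cycle")
        with pytest.raises(DivergenceError, match="C=0.1"):
            pf.simulate_network(net, params, 0.1, 2.0, config)

    def test_negative_coupling_rejected(self, small_network, regional_params):
        config = pf.SimulationConfig(duration=10.0, transient=0.0, seed=0)
        with pytest.raises(InvalidArgumentError):
            pf.simulate_network(small_network, regional_params, -0.1, 0.0,
                                config)


class TestSimulatedFC:
    def test_shared_signal_gives_unit_matrix(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=200)
        x = np.stack([base, 2 * base + 1, 0.5 * base - 3], axis=1)
        sfc = pf.compute_sfc(x)
        np.testing.assert_allclose(sfc, 1.0, atol=1e-12)

    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=200)
        sfc = pf.compute_sfc(np.stack([base, -base], axis=1))
        assert sfc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_bruteforce_pairwise_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(200, 5))
        sfc = pf.compute_sfc(x)
        for i in range(5):
            for j in range(5):
                xi = x[:, i] - x[:, i].mean()
                xj = x[:, j] - x[:, j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                if i == j:
                    expected = 1.0
                assert abs(sfc[i, j] - expected) < 1e-12

    def test_affine_invariance_per_region(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(150, 4))
        scale = rng.uniform(0.5, 3.0, 4)
        shift = rng.normal(size=4)
        np.testing.assert_allclose(pf.compute_sfc(x),
                                   pf.compute_sfc(x * scale + shift),
                                   atol=1e-12)

    def test_constant_region_rejected(self):
        x = np.ones((100, 3))
        x[:, 0] = np.arange(100)
        x[:, 1] = np.sin(np.arange(100))
        with pytest.raises(UndefinedCorrelationError, match="2"):
            pf.compute_sfc(x)
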