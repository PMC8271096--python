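"""Stochastic Heun integration of the delayed oscillator networks.

Two whole-brain models are supported, both driven by additive uniform noise
and coupled through the subject's structural connectome:

* ``phase``: Kuramoto-type phase oscillators,
  dphi_j/dt = 2 pi f_j + (C/N) sum_n w_jn sin(phi_n(t - tau_jn) - phi_j) + eta_j,
  with BOLD observable x_j = sin(phi_j);
* ``limit_cycle``: Hopf normal-form oscillators,
  dz_j/dt = (a_j + i 2 pi f_j - |z_j|^2) z_j
            + (C/N) sum_n w_jn (z_n(t - tau_jn) - z_j) + xi_j,
  with observable x_j = Re(z_j).

Delays are heterogeneous per connection (path length scaled by the global
delay ``tau``) and discretized to integer multiples of the step ``dt``.  Noise
is uniform in [-amplitude, +amplitude] per step and region, added after the
Heun corrector; by default the increment is scaled by sqrt(dt) (diffusion
convention), with ``noise_convention="dt"`` scaling by dt instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .derive import ModelNetwork, RegionalParameters, scale_delays
from .exceptions import (DivergenceError, InvalidArgumentError,
                         UndefinedCorrelationError)

MODEL_KINDS = ("phase", "limit_cycle")


@dataclass
class SimulationConfig:
    """Integration settings.

    Defaults follow the study protocol: dt = 0.06 s steps over 4000 s with the
    first 500 s discarded as transient, and uniform noise of amplitude 0.3.
    """

    dt: float = 0.06
    duration: float = 4000.0
    transient: float = 500.0
    noise_amplitude: float = 0.3
    noise_convention: str = "sqrt_dt"
    seed: int = 0
    model_kind: str = "phase"

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if not 0 <= self.transient < self.duration:
            raise InvalidArgumentError(
                "need 0 <= transient < duration")
        if self.noise_amplitude < 0:
            raise InvalidArgumentError("noise_amplitude must be >= 0")
        if self.noise_convention not in ("sqrt_dt", "dt"):
            raise InvalidArgumentError(
                f"unknown noise_convention {self.noise_convention!r}")
        if self.model_kind not in MODEL_KINDS:
            raise InvalidArgumentError(
                f"model_kind must be one of {MODEL_KINDS}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_transient(self) -> int:
        return int(round(self.transient / self.dt))


@dataclass
class SimulationRun:
    """Retained observable trajectory of one model run."""

    observables: np.ndarray  # (n_retained, N)
    coupling: float
    delay: float
    config: SimulationConfig
    network: ModelNetwork = field(repr=False, default=None)
    params: RegionalParameters = field(repr=False, default=None)
    initial_state: np.ndarray = field(repr=False, default=None)

    @property
    def n_regions(self) -> int:
        return self.observables.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time of each retained sample; sample i is the state after step
        n_transient + i + 1."""
        n = self.observables.shape[0]
        return (np.arange(n) + self.config.n_transient + 1) * self.config.dt


def _noise_scale(config: SimulationConfig) -> float:
    return np.sqrt(config.dt) if config.noise_convention == "sqrt_dt" \
        else config.dt


def simulate_network(network: ModelNetwork, params: RegionalParameters,
                     coupling: float, delay: float,
                     config: SimulationConfig) -> SimulationRun:
    """Integrate one model run at global coupling ``C`` and delay ``tau``.

    Initial conditions are random (phases uniform on [0, 2 pi); limit-cycle
    states uniform in the complex unit disk), the delay history is held
    constant at the initial state, and the transient is removed from the
    returned trajectory.  The run is a pure function of its arguments and
    ``config.seed``.
    """
    if coupling < 0 or delay < 0:
        raise InvalidArgumentError("coupling and delay must be nonnegative")
    n = network.n_regions
    w = np.ascontiguousarray(network.weights, dtype=np.float64)
    dsteps = scale_delays(network.lengths, delay, config.dt,
                          network.mean_convention)
    rng = np.random.default_rng(config.seed)
    n_steps = config.n_steps
    n_transient = config.n_transient
    scale = _noise_scale(config) * config.noise_amplitude
    two_pi_f = 2 * np.pi * np.asarray(params.frequencies, dtype=np.float64)
    cn = coupling / n

    if config.model_kind == "phase":
        phi0 = rng.uniform(0, 2 * np.pi, n)
        if config.noise_amplitude > 0:
            noise = rng.uniform(-1.0, 1.0, (n_steps, n)) * scale
        else:
            noise = np.zeros((n_steps, n))
        obs = _kernels.integrate_phase(two_pi_f, w, dsteps, cn, config.dt,
                                       n_steps, n_transient, noise, phi0)
        initial_state = phi0
    else:
        a = np.asarray(params.amplitudes, dtype=np.float64)
        r0 = np.sqrt(rng.uniform(0, 1, n))
        th0 = rng.uniform(0, 2 * np.pi, n)
        x0 = r0 * np.cos(th0)
        y0 = r0 * np.sin(th0)
        if config.noise_amplitude > 0:
            noise_x = rng.uniform(-1.0, 1.0, (n_steps, n)) * scale
            noise_y = rng.uniform(-1.0, 1.0, (n_steps, n)) * scale
        else:
            noise_x = np.zeros((n_steps, n))
            noise_y = np.zeros((n_steps, n))
        obs, status = _kernels.integrate_hopf(a, two_pi_f, w, dsteps, cn,
                                              config.dt, n_steps, n_transient,
                                              noise_x, noise_y, x0, y0)
        if status >= 0:
            raise DivergenceError(
                f"limit-cycle integration diverged at step {status} "
                f"(C={coupling}, tau={delay}, seed={config.seed})")
        initial_state = x0 + 1j * y0
    return SimulationRun(observables=obs, coupling=coupling, delay=delay,
                         config=config, network=network, params=params,
                         initial_state=initial_state)


def compute_sfc(run) -> np.ndarray:
    """Simulated FC: pairwise Pearson correlation of the retained observables.

    Accepts a SimulationRun or a (T, N) trajectory array.  Raises if any
    region's signal is constant (its correlations are undefined).
    """
    x = run.observables if hasattr(run, "observables") else np.asarray(run)
    if x.shape[0] < 3:
        raise InvalidArgumentError(
            "need at least 3 retained steps to correlate")
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise UndefinedCorrelationError(
            f"region(s) {bad.tolist()} have constant signal; "
            "correlation undefined")
    fc = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return fc
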