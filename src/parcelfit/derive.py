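"""Personalized model inputs derived from subject-level connectome data.

A subject's network model is parameterized by four ingredients, all read off
the empirical-style data at a given parcellation:

* coupling weights ``w_jn`` — streamline counts normalized by their ensemble
  mean, so that the average weight is one and the global coupling ``C`` alone
  sets the interaction scale;
* coupling delays — streamline path lengths rescaled so that their ensemble
  mean equals a global delay ``tau`` (equivalently, a propagation velocity
  ``V = <L>/tau``), then discretized to integration steps;
* natural frequencies ``f_j`` — the dominant spectral peak of each region's
  BOLD signal inside the resting-state band [0.01, 0.1] Hz;
* Hopf amplitude parameters ``a_j`` — the regional BOLD temporal standard
  deviations mapped affinely so that, across regions, mean(a) = 0.5 and
  population SD(a) = 0.4.

The ensemble average ``<.>`` over a zero-diagonal N x N matrix is ambiguous
between dividing by N^2 and by N(N-1); both are supported through
``mean_convention`` ("full", the default, vs "offdiag").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, InvalidArgumentError

DEFAULT_BAND = (0.01, 0.1)

AMPLITUDE_MEAN = 0.5
AMPLITUDE_SD = 0.4


def matrix_mean(m: np.ndarray, mean_convention: str = "full") -> float:
    """Ensemble average of a zero-diagonal square matrix.

    ``full`` divides the total by N^2 (the diagonal zeros count toward the
    denominator); ``offdiag`` divides by N(N-1).
    """
    n = m.shape[0]
    total = float(m.sum())
    if mean_convention == "full":
        return total / (n * n)
    if mean_convention == "offdiag":
        return total / (n * (n - 1))
    raise InvalidArgumentError(f"unknown mean_convention {mean_convention!r}")


@dataclass
class ModelNetwork:
    """Coupling weights and length scaffold of one personalized network."""

    weights: np.ndarray
    lengths: np.ndarray
    mean_convention: str = "full"

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def mean_length(self) -> float:
        return matrix_mean(self.lengths, self.mean_convention)


@dataclass
class RegionalParameters:
    """Per-region natural frequencies (Hz) and Hopf amplitude parameters."""

    frequencies: np.ndarray
    amplitudes: np.ndarray = field(default=None)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.amplitudes is None:
            self.amplitudes = np.full_like(self.frequencies, AMPLITUDE_MEAN)
        else:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)


def normalize_weights(counts: np.ndarray,
                      mean_convention: str = "full") -> np.ndarray:
    """Streamline counts divided by their ensemble mean; diagonal stays zero."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise InvalidArgumentError("counts must be a square matrix")
    if np.any(counts < 0):
        raise InvalidArgumentError("counts must be nonnegative")
    mean = matrix_mean(counts, mean_convention)
    if mean == 0:
        raise DegenerateInputError("all-zero count matrix cannot be normalized")
    w = counts / mean
    np.fill_diagonal(w, 0.0)
    return w


def scale_delays(lengths: np.ndarray, tau_global: float, dt: float,
                 mean_convention: str = "full") -> np.ndarray:
    """Integer delay steps from path lengths and a global delay.

    Continuous delays are ``tau_global * L_jn / <L>``; they are discretized by
    round-half-to-even of ``tau_jn / dt``.  ``tau_global = 0`` gives all-zero
    delays regardless of the lengths.
    """
    lengths = np.asarray(lengths, dtype=float)
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    if tau_global < 0:
        raise InvalidArgumentError("tau_global must be nonnegative")
    n = lengths.shape[0]
    if tau_global == 0:
        return np.zeros((n, n), dtype=np.int64)
    mean = matrix_mean(lengths, mean_convention)
    if mean == 0:
        raise DegenerateInputError(
            "all-zero length matrix with positive tau_global")
    tau = tau_global * lengths / mean
    steps = np.round(tau / dt).astype(np.int64)
    np.fill_diagonal(steps, 0)
    return steps


def periodogram_peak_frequencies(signals: np.ndarray, tr: float,
                                 band=DEFAULT_BAND) -> np.ndarray:
    """Frequency of the largest in-band periodogram ordinate per column."""
    signals = np.asarray(signals, dtype=float)
    t = signals.shape[0]
    if t < 128:
        raise InvalidArgumentError(
            f"need at least 128 samples per region, got {t}")
    if tr <= 0:
        raise InvalidArgumentError("tr must be positive")
    freqs = np.fft.rfftfreq(t, d=tr)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise InvalidArgumentError(
            f"no Fourier bin falls inside the band {band} for {t} samples "
            f"at TR={tr}")
    centered = signals - signals.mean(axis=0)
    power = np.abs(np.fft.rfft(centered, axis=0)) ** 2
    band_freqs = freqs[in_band]
    peak = np.argmax(power[in_band, :], axis=0)
    return band_freqs[peak]


def extract_natural_frequencies(bold, band=DEFAULT_BAND) -> np.ndarray:
    """Dominant in-band BOLD frequency per region, from the concatenated scan."""
    return periodogram_peak_frequencies(bold.concatenated, bold.tr, band)


def calibrate_amplitudes(bold) -> np.ndarray:
    """Affinely standardized regional BOLD SDs: mean 0.5, population SD 0.4.

    The ordering of ``a_j`` follows the ordering of the temporal standard
    deviations; values below zero are permitted and correspond to regions in
    the subcritical (noise-driven) Hopf regime.
    """
    x = np.asarray(bold.concatenated, dtype=float)
    if x.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 regions")
    s = x.std(axis=0)
    spread = s.std()
    if spread < 1e-12 * max(1.0, abs(s.mean())):
        warnings.warn("all regions have identical BOLD SD; "
                      "returning uniform amplitudes a = 0.5")
        return np.full(x.shape[1], AMPLITUDE_MEAN)
    return AMPLITUDE_MEAN + AMPLITUDE_SD * (s - s.mean()) / spread


def build_network(connectome, mean_convention: str = "full") -> ModelNetwork:
    """ModelNetwork from a StructuralConnectome (counts -> weights)."""
    w = normalize_weights(connectome.counts, mean_convention)
    lengths = np.asarray(connectome.lengths, dtype=float).copy()
    np.fill_diagonal(lengths, 0.0)
    return ModelNetwork(weights=w, lengths=lengths,
                        mean_convention=mean_convention)


def derive_subject(bundle, mean_convention: str = "full",
                   band=DEFAULT_BAND):
    """All personalized model inputs for one subject bundle.

    Returns ``(ModelNetwork, RegionalParameters)``.
    """
    network = build_network(bundle.connectome, mean_convention)
    f = extract_natural_frequencies(bundle.bold, band)
    a = calibrate_amplitudes(bundle.bold)
    return network, RegionalParameters(frequencies=f, amplitudes=a)
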