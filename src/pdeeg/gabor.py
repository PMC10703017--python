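"""Gabor transform: Gaussian-windowed complex-exponential time-frequency analysis.

The transform of a signal x at analysis time t and frequency f is the
inner product of x with the translated, modulated Gaussian kernel

    g(u, f) = exp(-u^2 / (2 sigma_t^2)) * exp(j 2 pi f u),

i.e.  X(t, f) = (1/fs) * sum_tau  x(tau) * conj(g(tau - t, f)),

a Riemann-sum discretization of the continuous windowed transform.  The
kernel is truncated at +/- truncation * sigma_t and the signal is
zero-padded at the edges.  |X(t, f)| peaks at a tone's true frequency and
the transform is linear in the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class GaborConfigError(ValueError):
    """Raised for invalid analysis grids."""


@dataclass
class GaborConfig:
    """Analysis grid for the Gabor transform.

    sigma_t : Gaussian window SD in seconds (time/frequency trade-off).
    freqs : analysis frequencies in Hz, strictly ascending, all < fs/2.
    hop : step between analysis instants in samples; mutually exclusive
        with n_steps.
    n_steps : evenly spaced analysis instants covering the signal (the
        default, 178, matches the classifier's input sequence length).
    truncation : kernel support half-width in multiples of sigma_t.
    log_magnitude / log_floor : feature reduction log(|X| + floor).
    """

    sigma_t: float = 0.1
    freqs: np.ndarray = field(default_factory=lambda: np.arange(1.0, 46.0))
    hop: int | None = None
    n_steps: int | None = 178
    truncation: float = 6.0
    log_magnitude: bool = True
    log_floor: float = 1e-8

    def validate(self, fs: float) -> None:
        if self.sigma_t <= 0:
            raise GaborConfigError("sigma_t must be positive")
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or len(f) == 0 or np.any(np.diff(f) <= 0):
            raise GaborConfigError("freqs must be non-empty and strictly ascending")
        if f[-1] >= fs / 2:
            raise GaborConfigError(
                f"max analysis frequency {f[-1]} Hz must be below Nyquist ({fs/2} Hz)")
        if self.hop is not None and self.hop < 1:
            raise GaborConfigError("hop must be >= 1")
        if self.hop is None and (self.n_steps is None or self.n_steps < 1):
            raise GaborConfigError("one of hop or n_steps must be set")
        if self.truncation < 3:
            raise GaborConfigError("truncation must be >= 3 window SDs")


@dataclass
class Spectrogram:
    """Time x frequency array with explicit axes (complex or magnitude)."""

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.times), len(self.freqs)):
            raise ValueError("values shape must be (len(times), len(freqs))")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def gabor_kernel(t, f, sigma_t: float):
    """Gaussian-windowed complex exponential exp(-t^2/2sigma^2) exp(j2pi f t)."""
    if sigma_t <= 0:
        raise ValueError("sigma_t must be positive")
    t = np.asarray(t, dtype=float)
    return np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * f * t)


def _analysis_indices(n: int, cfg: GaborConfig) -> np.ndarray:
    if cfg.hop is not None:
        return np.arange(0, n, cfg.hop)
    steps = min(cfg.n_steps, n)
    idx = np.round(np.linspace(0, n - 1, steps)).astype(int)
    return np.unique(idx)


def gabor_transform(x: np.ndarray, fs: float, cfg: GaborConfig) -> Spectrogram:
    """Transform a single-channel signal onto the configured (t, f) grid."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("x must be a non-empty 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    cfg.validate(fs)

    freqs = np.asarray(cfg.freqs, dtype=float)
    half = int(np.ceil(cfg.truncation * cfg.sigma_t * fs))
    u = np.arange(-half, half + 1) / fs  # kernel support, seconds
    # conj(g(u, f)) sampled on the support, one row per frequency
    kernel = np.exp(-(u[None, :] ** 2) / (2.0 * cfg.sigma_t**2)) \
        * np.exp(-2j * np.pi * freqs[:, None] * u[None, :])

    idx = _analysis_indices(len(x), cfg)
    xp = np.pad(x, half)
    windows = sliding_window_view(xp, 2 * half + 1)[idx]  # (T, L)
    values = windows @ kernel.T / fs  # (T, F)
    return Spectrogram(values=values, times=idx / fs, freqs=freqs)


def to_feature_sequence(specs: list[Spectrogram], cfg: GaborConfig) -> np.ndarray:
    """Concatenate per-channel magnitudes into a T x (channels * freqs) sequence.

    Channels are concatenated in list order; log scaling (when enabled)
    applies log(m + log_floor) element-wise.
    """
    if not specs:
        raise ValueError("need at least one spectrogram")
    t0 = specs[0].times
    for s in specs[1:]:
        if len(s.times) != len(t0) or not np.allclose(s.times, t0):
            raise ValueError("spectrograms must share a common time axis")
    mags = [s.magnitude() for s in specs]
    feat = np.concatenate(mags, axis=1)
    if cfg.log_magnitude:
        feat = np.log(feat + cfg.log_floor)
    return feat


def recording_features(data: np.ndarray, fs: float, cfg: GaborConfig) -> np.ndarray:
    """Feature sequence for a channels x samples array (one segment)."""
    specs = [gabor_transform(ch, fs, cfg) for ch in np.asarray(data, dtype=float)]
    return to_feature_sequence(specs, cfg)
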