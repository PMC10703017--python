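"""The Gabor transform against its analytic properties and a dense
untruncated brute-force oracle."""

import numpy as np
import pytest

from pdeeg.gabor import (GaborConfig, GaborConfigError, Spectrogram,
                         gabor_kernel, gabor_transform, to_feature_sequence)


def dense_oracle(x, fs, times_idx, freqs, sigma_t):
    """Untruncated full-sum evaluation over every sample, per (t, f)."""
    n = len(x)
    tau = np.arange(n) / fs
    out = np.empty((len(times_idx), len(freqs)), dtype=complex)
    for ti, t_idx in enumerate(times_idx):
        t = t_idx / fs
        for fi, f in enumerate(freqs):
            w = np.exp(-((tau - t) ** 2) / (2 * sigma_t**2))
            out[ti, fi] = np.sum(x * w * np.exp(-2j * np.pi * f * (tau - t))) / fs
    return out


def test_kernel_analytic_values():
    assert gabor_kernel(0.0, 123.0, 0.1) == pytest.approx(1.0 + 0j)
    assert abs(gabor_kernel(0.1, 0.0, 0.1)) == pytest.approx(np.exp(-0.5))
    # modulus independent of frequency
    for f in (0.0, 7.0, 40.0):
        assert abs(gabor_kernel(0.05, f, 0.1)) == pytest.approx(
            np.exp(-0.05**2 / (2 * 0.1**2)))
    with pytest.raises(ValueError):
        gabor_kernel(0.0, 1.0, -1.0)


def test_zero_signal_gives_zero_spectrogram():
    cfg = GaborConfig(freqs=np.arange(2.0, 20.0, 2.0), hop=16, n_steps=None)
    spec = gabor_transform(np.zeros(256), 128.0, cfg)
    assert np.all(spec.values == 0)


def test_invalid_inputs_rejected():
    cfg = GaborConfig(freqs=np.arange(2.0, 20.0, 2.0), hop=16, n_steps=None)
    with pytest.raises(ValueError):
        gabor_transform(np.array([]), 128.0, cfg)
    bad = GaborConfig(freqs=np.array([10.0, 70.0]), hop=16, n_steps=None)
    with pytest.raises(GaborConfigError):
        gabor_transform(np.zeros(64), 128.0, bad)


def test_linearity(rng):
    fs = 128.0
    cfg = GaborConfig(freqs=np.arange(2.0, 40.0, 2.0), hop=8, n_steps=None)
    x, y = rng.standard_normal(128), rng.standard_normal(128)
    a, b = 2.3, -0.7
    lhs = gabor_transform(a * x + b * y, fs, cfg).values
    rhs = a * gabor_transform(x, fs, cfg).values \
        + b * gabor_transform(y, fs, cfg).values
    assert np.max(np.abs(lhs - rhs)) <= 1e-9 * max(1.0, np.max(np.abs(rhs)))


def test_tone_localizes_at_its_frequency():
    fs = 256.0
    t = np.arange(int(2 * fs)) / fs
    x = np.cos(2 * np.pi * 10.0 * t)
    cfg = GaborConfig(sigma_t=0.1, freqs=np.arange(2.0, 41.0), hop=32,
                      n_steps=None)
    spec = gabor_transform(x, fs, cfg)
    mag = spec.magnitude()
    interior = (spec.times > 0.4) & (spec.times < 1.6)
    for row in mag[interior]:
        assert spec.freqs[np.argmax(row)] == 10.0


def test_frequency_separation_from_tone():
    # magnitude at f0 strictly exceeds all grid frequencies >= 3/(2 pi sigma) away
    fs, sigma = 256.0, 0.1
    t = np.arange(int(2 * fs)) / fs
    x = np.sin(2 * np.pi * 20.0 * t)
    cfg = GaborConfig(sigma_t=sigma, freqs=np.arange(2.0, 41.0), hop=64,
                      n_steps=None)
    spec = gabor_transform(x, fs, cfg)
    mag = spec.magnitude()
    interior = (spec.times > 0.4) & (spec.times < 1.6)
    far = np.abs(spec.freqs - 20.0) >= 3.0 / (2 * np.pi * sigma)
    at_tone = mag[interior][:, spec.freqs == 20.0]
    assert np.all(at_tone > mag[interior][:, far].max(axis=1, keepdims=True))


def test_shift_covariance_of_magnitude(rng):
    fs, hop, d = 128.0, 8, 24  # delay is a multiple of hop
    x = rng.standard_normal(256)
    cfg = GaborConfig(freqs=np.arange(2.0, 40.0, 2.0), hop=hop, n_steps=None)
    shifted = np.r_[np.zeros(d), x[:-d]]
    m0 = gabor_transform(x, fs, cfg).magnitude()
    m1 = gabor_transform(shifted, fs, cfg).magnitude()
    steps = d // hop
    interior = slice(10, m0.shape[0] - 10)
    assert np.max(np.abs(m1[steps:][interior] - m0[:-steps][interior])) <= 1e-6


def test_matches_dense_untruncated_oracle(rng):
    fs = 128.0
    x = rng.standard_normal(200)
    cfg = GaborConfig(sigma_t=0.08, freqs=np.arange(4.0, 40.0, 4.0), hop=32,
                      n_steps=None, truncation=6.0)
    spec = gabor_transform(x, fs, cfg)
    idx = np.arange(0, 200, 32)
    ref = dense_oracle(x, fs, idx, cfg.freqs, cfg.sigma_t)
    scale = np.max(np.abs(ref))
    assert np.max(np.abs(spec.values - ref)) <= 1e-6 * scale


def test_wider_window_narrows_frequency_profile():
    fs = 256.0
    t = np.arange(int(2 * fs)) / fs
    x = np.cos(2 * np.pi * 15.0 * t)
    spreads = []
    for sigma in (0.05, 0.1, 0.2):
        cfg = GaborConfig(sigma_t=sigma, freqs=np.arange(2.0, 41.0), hop=64,
                          n_steps=None)
        spec = gabor_transform(x, fs, cfg)
        mid = spec.magnitude()[len(spec.times) // 2]
        prof = mid / mid.sum()
        mean_f = np.sum(prof * spec.freqs)
        spreads.append(np.sum(prof * (spec.freqs - mean_f) ** 2))
    assert spreads[0] > spreads[1] > spreads[2]


def test_feature_sequence_layout(rng):
    fs = 128.0
    cfg = GaborConfig(freqs=np.arange(2.0, 42.0, 2.0), n_steps=32,
                      log_magnitude=False)
    x = rng.standard_normal(256)
    s1 = gabor_transform(x, fs, cfg)
    feat = to_feature_sequence([s1], cfg)
    assert feat.shape == (32, 20)
    # two identical channels tile the single-channel vector
    feat2 = to_feature_sequence([s1, s1], cfg)
    assert feat2.shape == (32, 40)
    assert np.allclose(feat2[:, :20], feat2[:, 20:])
    # log floor on silence
    zero = gabor_transform(np.zeros(256), fs, cfg)
    logcfg = GaborConfig(freqs=cfg.freqs, n_steps=32, log_magnitude=True,
                         log_floor=1e-8)
    flog = to_feature_sequence([zero], logcfg)
    assert np.allclose(flog, np.log(1e-8))


def test_feature_sequence_rejects_mismatched_time_axes(rng):
    fs = 128.0
    cfg = GaborConfig(freqs=np.arange(2.0, 40.0, 2.0), n_steps=16)
    a = gabor_transform(rng.standard_normal(256), fs, cfg)
    cfg2 = GaborConfig(freqs=cfg.freqs, n_steps=8)
    b = gabor_transform(rng.standard_normal(256), fs, cfg2)
    with pytest.raises(ValueError):
        to_feature_sequence([a, b], cfg)


def test_spectrogram_axis_validation():
    with pytest.raises(ValueError):
        Spectrogram(values=np.zeros((3, 2)), times=np.array([0.0, 1.0]),
                    freqs=np.array([1.0, 2.0]))
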