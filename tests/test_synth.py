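"""The synthetic cohort generator: determinism, class counts, spectral
content against a Welch periodogram oracle, line noise, blink ground
truth."""

import numpy as np
import pytest
from scipy import signal as sps

from pdeeg.synth import (DEFAULT_BAND_POWERS, SyntheticCohortSpec,
                         generate_cohort, generate_recording)


def welch_band_power(data, fs, lo, hi):
    f, pxx = sps.welch(data, fs=fs, nperseg=min(data.shape[-1], 1024), axis=-1)
    band = (f >= lo) & (f < hi)
    return float(np.mean(pxx[..., band].sum(axis=-1)))


def test_recording_shape_follows_fs_and_duration():
    spec = SyntheticCohortSpec(n_channels=32, fs=512.0, duration=180.0)
    rec = generate_recording(spec, label=1, subject_id="s0", seed=0)
    assert rec.data.shape == (32, 92160)
    assert len(rec.channel_names) == 32


def test_bit_identical_for_identical_inputs(tiny_spec):
    a = generate_recording(tiny_spec, 0, "subj", seed=5)
    b = generate_recording(tiny_spec, 0, "subj", seed=5)
    assert np.array_equal(a.data, b.data)
    assert a.artifact_truth == b.artifact_truth
    c = generate_recording(tiny_spec, 0, "subj", seed=6)
    assert not np.array_equal(a.data, c.data)


def test_cohort_counts_and_ids(tiny_spec):
    records, manifest = generate_cohort(tiny_spec)
    assert len(records) == 4
    labels = [r.label for r in records]
    assert labels.count(1) == 2 and labels.count(0) == 2
    assert len({r.subject_id for r in records}) == 4
    assert list(manifest.columns) == ["subject_id", "label", "path"]


def test_published_cohort_sizes():
    spec = SyntheticCohortSpec(n_pd=15, n_hc=16, n_channels=2, fs=256.0,
                               duration=2.0, blink_rate=0.0,
                               band_powers={"control": {"alpha": 1.0},
                                            "pd": {"alpha": 1.0}})
    records, _ = generate_cohort(spec)
    labels = [r.label for r in records]
    assert len(records) == 31 and labels.count(1) == 15 and labels.count(0) == 16


def test_degenerate_single_subject_cohort(tiny_spec):
    import dataclasses

    spec = dataclasses.replace(tiny_spec, n_pd=0, n_hc=1)
    records, _ = generate_cohort(spec)
    assert len(records) == 1 and records[0].label == 0
    empty = dataclasses.replace(tiny_spec, n_pd=0, n_hc=0)
    with pytest.raises(ValueError):
        generate_cohort(empty)


def test_different_seeds_same_structure(tiny_spec):
    import dataclasses

    other = dataclasses.replace(tiny_spec, seed=99)
    r1, m1 = generate_cohort(tiny_spec)
    r2, m2 = generate_cohort(other)
    assert list(m1["subject_id"]) == list(m2["subject_id"])
    assert not np.array_equal(r1[0].data, r2[0].data)


def test_beta_power_ratio_matches_welch_oracle():
    """PD beta power set to 2x control: the Welch-estimated 13-30 Hz band
    power ratio, averaged over 20 seeds, is within 10% of the analytic
    expectation (oscillation ratio diluted by the broadband noise floor)."""
    control = {**DEFAULT_BAND_POWERS, "gamma": 0.0}
    base = SyntheticCohortSpec(
        n_channels=4, fs=256.0, duration=30.0, blink_rate=0.0, line_amp=0.0,
        gain_spread=0.0,
        band_powers={"control": control,
                     "pd": {**control, "beta": control["beta"] * 2.0}})
    ratios = []
    for seed in range(20):
        pd_rec = generate_recording(base, 1, f"pd{seed}", seed=seed)
        hc_rec = generate_recording(base, 0, f"hc{seed}", seed=seed + 1000)
        p_pd = welch_band_power(pd_rec.data, 256.0, 13.0, 30.0)
        p_hc = welch_band_power(hc_rec.data, 256.0, 13.0, 30.0)
        ratios.append(p_pd / p_hc)
    from pdeeg.synth import OSC_AMP_UV

    beta_var = OSC_AMP_UV**2 * control["beta"]
    noise_in_band = base.noise_sd**2 * (30.0 - 13.0) / 128.0
    expected = (2 * beta_var + noise_in_band) / (beta_var + noise_in_band)
    assert np.mean(ratios) == pytest.approx(expected, rel=0.10)
    assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)


def test_nonzero_band_beats_zero_band():
    powers = {"delta": 0.0, "theta": 0.0, "alpha": 1.5, "beta": 0.0,
              "gamma": 0.0}
    spec = SyntheticCohortSpec(
        n_channels=2, fs=256.0, duration=20.0, blink_rate=0.0, line_amp=0.0,
        noise_sd=1.0, band_powers={"control": powers, "pd": powers})
    rec = generate_recording(spec, 0, "s", seed=0)
    alpha = welch_band_power(rec.data, 256.0, 8.0, 13.0)
    theta = welch_band_power(rec.data, 256.0, 4.0, 8.0)
    assert alpha > theta


def test_dominant_line_noise_is_largest_spectral_peak():
    powers = {"alpha": 0.5}
    spec = SyntheticCohortSpec(
        n_channels=2, fs=256.0, duration=10.0, blink_rate=0.0,
        line_freq=50.0, line_amp=50.0, noise_sd=1.0,
        band_powers={"control": powers, "pd": powers})
    rec = generate_recording(spec, 0, "s", seed=3)
    f, pxx = sps.welch(rec.data[0], fs=256.0, nperseg=2048)
    assert f[np.argmax(pxx)] == pytest.approx(50.0, abs=0.5)


def test_blink_truth_intervals_mark_high_amplitude_cores(tiny_spec):
    import dataclasses

    spec = dataclasses.replace(tiny_spec, blink_rate=60.0)
    rec = generate_recording(spec, 1, "blinky", seed=2)
    assert rec.artifact_truth, "expected blinks at the default rate"
    frontal = rec.data[0]
    sd = np.median(np.abs(frontal)) / 0.6745  # robust SD
    for start, end in rec.artifact_truth:
        assert 0 <= start < end <= rec.n_samples
        assert np.max(np.abs(frontal[start:end])) > 3 * sd


def test_invalid_spec_errors_name_the_field():
    with pytest.raises(ValueError, match="n_pd"):
        SyntheticCohortSpec(n_pd=-1).validate()
    with pytest.raises(ValueError, match="duration"):
        SyntheticCohortSpec(duration=0).validate()
    with pytest.raises(ValueError, match="gamma"):
        # gamma extends to 100 Hz: unreachable at fs=128
        SyntheticCohortSpec(fs=128.0).validate()


def test_with_beta_ratio_scales_only_beta():
    spec = SyntheticCohortSpec().with_beta_ratio(3.0)
    assert spec.band_powers["pd"]["beta"] == pytest.approx(
        3.0 * spec.band_powers["control"]["beta"])
    assert spec.band_powers["pd"]["alpha"] == spec.band_powers["control"]["alpha"]
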