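"""Synthetic multichannel EEG cohorts with known class structure.

Generates band-structured oscillatory EEG (filtered Gaussian noise per
canonical band rather than pure tones), mains-frequency line noise,
low-frequency blink-like frontal transients with ground-truth intervals,
and a controllable class-dependent spectral difference between "PD-like"
and "control-like" subjects.  Everything is driven by a single integer
seed so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

#: Canonical EEG frequency bands, Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}

CONTROL, PD = 0, 1

#: Default relative band variances for a resting-state control subject
#: (alpha-dominant, weak gamma).
DEFAULT_BAND_POWERS: dict[str, float] = {
    "delta": 1.0,
    "theta": 0.7,
    "alpha": 1.5,
    "beta": 0.8,
    "gamma": 0.3,
}

#: RMS (µV) of a band with relative power 1.0.
OSC_AMP_UV = 5.0


def default_band_powers_for(fs: float) -> dict[str, float]:
    """Default band powers with bands unreachable at this rate zeroed
    (a band needs fs > 2x its upper edge)."""
    return {band: (p if fs > 2.0 * BANDS[band][1] else 0.0)
            for band, p in DEFAULT_BAND_POWERS.items()}

#: Blink transient shape: one-sided exponential decay.
BLINK_TAU_S = 0.075          # decay time constant, s
BLINK_SUPPORT_S = 0.3        # bump support (~4 tau), s
BLINK_TRUTH_S = 0.15         # recorded high-amplitude core (~2 tau), s
BLINK_AMP_RANGE = (5.0, 10.0)   # amplitude in multiples of background SD
BLINK_NONFRONTAL_WEIGHT = 0.15


@dataclass
class EEGRecording:
    """One subject's multichannel recording, channels x samples, in µV."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str
    label: int
    artifact_truth: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("rows(data) must equal len(channel_names)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.data.shape[1]
        for a, b in self.artifact_truth:
            if not (0 <= a < b <= n):
                raise ValueError(f"artifact interval ({a}, {b}) outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SyntheticCohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate the real cohort the pipeline targets: 15 PD-like and
    16 control-like subjects, 32 channels at 512 Hz, 3 minutes each.  The
    class effect is a band-power ratio (elevated beta for PD-like by
    default); it is a controllable stand-in, not a claim about PD
    electrophysiology.
    """

    n_pd: int = 15
    n_hc: int = 16
    n_channels: int = 32
    fs: float = 512.0
    duration: float = 180.0
    band_powers: dict = field(default_factory=lambda: {
        "control": dict(DEFAULT_BAND_POWERS),
        "pd": {**DEFAULT_BAND_POWERS, "beta": DEFAULT_BAND_POWERS["beta"] * 2.0},
    })
    noise_sd: float = 5.0
    line_freq: float = 50.0
    line_amp: float = 2.0
    blink_rate: float = 10.0     # expected transients per minute
    gain_spread: float = 0.1     # per-subject gain ~ U(1-g, 1+g)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pd < 0:
            raise ValueError("n_pd must be >= 0")
        if self.n_hc < 0:
            raise ValueError("n_hc must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.line_amp < 0:
            raise ValueError("line_amp must be >= 0")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be >= 0")
        for cls, powers in self.band_powers.items():
            for band, p in powers.items():
                if band not in BANDS:
                    raise ValueError(f"band_powers[{cls!r}]: unknown band {band!r}")
                if p < 0:
                    raise ValueError(f"band_powers[{cls}][{band}] must be >= 0")
                if p > 0 and self.fs <= 2.0 * BANDS[band][1]:
                    raise ValueError(
                        f"band_powers[{cls}][{band}]: fs={self.fs} must exceed "
                        f"twice the band edge {BANDS[band][1]} Hz"
                    )
        if self.line_freq >= self.fs / 2:
            raise ValueError("line_freq must be below Nyquist")

    def powers_for(self, label: int) -> dict[str, float]:
        return self.band_powers["pd" if label == PD else "control"]

    def background_sd(self, label: int) -> float:
        """Analytic SD (µV) of oscillations + broadband noise, before gain."""
        osc_var = OSC_AMP_UV**2 * sum(self.powers_for(label).values())
        return float(np.sqrt(osc_var + self.noise_sd**2))

    def with_beta_ratio(self, ratio: float) -> "SyntheticCohortSpec":
        """Copy of this spec with PD beta power = ratio x control beta power."""
        control = dict(self.band_powers["control"])
        pd_pow = dict(control)
        pd_pow["beta"] = control["beta"] * ratio
        return replace(self, band_powers={"control": control, "pd": pd_pow})


def _subject_rng(spec_seed: int, subject_id: str, label: int, seed: int) -> np.random.Generator:
    # crc32 gives a stable (unsalted) hash of the subject id
    sid_hash = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng([spec_seed & 0x7FFFFFFF, seed & 0x7FFFFFFF,
                                  sid_hash, label])


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (4th-order Butterworth, zero phase)."""
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    lo_n, hi_n = max(lo / nyq, 1e-6), min(hi / nyq, 0.999)
    sos = sps.butter(4, [lo_n, hi_n], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_recording(spec: SyntheticCohortSpec, label: int, subject_id: str,
                       seed: int) -> EEGRecording:
    """Synthesize one subject's recording.

    The signal is a sum of per-band filtered-noise oscillations (variance set
    by the class's relative band powers), broadband Gaussian noise, a
    mains-frequency sinusoid, and blink-like one-sided exponential transients
    weighted onto the first quarter of channels.  Bit-identical output for
    identical (spec, label, subject_id, seed).
    """
    spec.validate()
    if label not in (CONTROL, PD):
        raise ValueError("label must be 0 (control) or 1 (PD)")
    rng = _subject_rng(spec.seed, subject_id, label, seed)
    n = int(round(spec.fs * spec.duration))
    nch = spec.n_channels
    powers = spec.powers_for(label)

    data = np.zeros((nch, n))
    for ch in range(nch):
        for band, p in powers.items():
            if p <= 0:
                continue
            lo, hi = BANDS[band]
            data[ch] += OSC_AMP_UV * np.sqrt(p) * _band_noise(rng, n, spec.fs, lo, hi)
        if spec.noise_sd > 0:
            data[ch] += spec.noise_sd * rng.standard_normal(n)

    if spec.line_amp > 0:
        t = np.arange(n) / spec.fs
        phase = rng.uniform(0, 2 * np.pi)
        data += spec.line_amp * np.sin(2 * np.pi * spec.line_freq * t + phase)[None, :]

    # blink transients: frontal-weighted one-sided exponential bumps
    artifact_truth: list[tuple[int, int]] = []
    n_blinks = rng.poisson(spec.blink_rate * spec.duration / 60.0)
    support = int(round(BLINK_SUPPORT_S * spec.fs))
    truth_len = max(1, int(round(BLINK_TRUTH_S * spec.fs)))
    n_frontal = max(1, nch // 4)
    bg_sd = spec.background_sd(label)
    if n_blinks > 0 and n > support:
        bump = np.exp(-np.arange(support) / (BLINK_TAU_S * spec.fs))
        weights = np.full(nch, BLINK_NONFRONTAL_WEIGHT)
        weights[:n_frontal] = 1.0
        starts = np.sort(rng.integers(0, n - support, size=n_blinks))
        for s in starts:
            amp = rng.uniform(*BLINK_AMP_RANGE) * bg_sd
            data[:, s:s + support] += amp * np.outer(weights, bump)
            artifact_truth.append((int(s), int(s + truth_len)))

    # per-subject, per-channel gains (electrode-impedance-like variability);
    # gives each subject a stable multichannel amplitude fingerprint
    gains = 1.0 + spec.gain_spread * rng.uniform(-1.0, 1.0, size=nch)
    data *= gains[:, None]

    names = [f"CH{i:02d}" for i in range(nch)]
    return EEGRecording(data=data, fs=spec.fs, channel_names=names,
                        subject_id=subject_id, label=label,
                        artifact_truth=artifact_truth)


def generate_cohort(spec: SyntheticCohortSpec,
                    out_dir: Optional[str | Path] = None,
                    file_format: str = "hdf5",
                    ) -> tuple[list[EEGRecording], pd.DataFrame]:
    """Generate the full cohort and its manifest.

    When ``out_dir`` is given, recordings are written there (EDF or HDF5 per
    ``file_format``) together with ``manifest.csv`` (subject_id, label, path)
    and a JSON sidecar with the full spec.
    """
    spec.validate()
    if spec.n_pd + spec.n_hc < 1:
        raise ValueError("cohort must contain at least one subject (n_pd + n_hc >= 1)")
    subjects = [(f"pd{i:02d}", PD) for i in range(spec.n_pd)]
    subjects += [(f"hc{i:02d}", CONTROL) for i in range(spec.n_hc)]

    records, rows = [], []
    for i, (sid, label) in enumerate(subjects):
        rec = generate_recording(spec, label, sid, seed=spec.seed + i)
        records.append(rec)
        rows.append({"subject_id": sid, "label": label, "path": ""})
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        from . import io as eeg_io  # avoid importing mne unless writing
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ext = {"edf": "edf", "hdf5": "h5"}[file_format]
        for rec, row in zip(records, rows):
            path = out / f"{rec.subject_id}.{ext}"
            eeg_io.write_eeg(rec, path)
            row["path"] = str(path)
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out / "manifest.csv", index=False)
        sidecar = asdict(spec)
        (out / "cohort_spec.json").write_text(json.dumps(sidecar, indent=2))
    return records, manifest
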