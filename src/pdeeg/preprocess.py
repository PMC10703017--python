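"""EEG preprocessing: filtering, segmentation, artifact rejection, normalization.

Filters are zero-phase Butterworth band-pass (4th order, forward-backward)
and an IIR notch at the mains frequency.  Segmentation cuts fixed-length
windows on a hop grid, each carrying its source subject and label.
Artifact rejection combines an optional ICA step (components with spiky,
high-kurtosis time courses are zeroed; the decomposition itself is
delegated to scikit-learn's FastICA, the rejection rule is ours) with a
peak-amplitude threshold.  Sample indices are 0-based; intervals are
half-open [start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .synth import EEGRecording

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Raised for filter settings that are invalid at the given sampling rate."""


@dataclass
class FilterConfig:
    band_low: float = 0.5
    band_high: float = 100.0
    notch_freq: float = 50.0
    notch_q: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.band_low < self.band_high):
            raise ConfigurationError("must satisfy 0 < band_low < band_high")
        if self.band_high >= nyq:
            raise ConfigurationError(
                f"band_high={self.band_high} must be below Nyquist ({nyq} Hz)")
        if self.notch_freq >= nyq:
            raise ConfigurationError(
                f"notch_freq={self.notch_freq} must be below Nyquist ({nyq} Hz)")
        if self.order < 1:
            raise ConfigurationError("order must be >= 1")


@dataclass
class SegmentSet:
    """Windowed segments (n x channels x window) with per-segment provenance."""

    segments: np.ndarray
    window_len: int
    hop: int
    fs: float
    subject_ids: list[str]
    labels: np.ndarray
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.segments)
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids/labels length must match segment count")
        if self.kept_mask is None:
            self.kept_mask = np.ones(n, dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def kept(self) -> "SegmentSet":
        """Subset containing only the kept segments."""
        m = self.kept_mask
        return SegmentSet(self.segments[m], self.window_len, self.hop, self.fs,
                          [s for s, k in zip(self.subject_ids, m) if k],
                          self.labels[m], np.ones(int(m.sum()), dtype=bool))


def _apply_sos(rec: EEGRecording, sos: np.ndarray, zero_phase: bool) -> EEGRecording:
    filt = sps.sosfiltfilt if zero_phase else sps.sosfilt
    data = np.vstack([filt(sos, ch) for ch in rec.data])
    return EEGRecording(data=data, fs=rec.fs, channel_names=rec.channel_names,
                        subject_id=rec.subject_id, label=rec.label,
                        artifact_truth=list(rec.artifact_truth))


def bandpass_filter(rec: EEGRecording, cfg: FilterConfig) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    cfg.validate(rec.fs)
    nyq = rec.fs / 2.0
    sos = sps.butter(cfg.order, [cfg.band_low / nyq, cfg.band_high / nyq],
                     btype="bandpass", output="sos")
    return _apply_sos(rec, sos, cfg.zero_phase)


def highpass_filter(rec: EEGRecording, cutoff: float = 0.5, order: int = 4,
                    zero_phase: bool = True) -> EEGRecording:
    """Zero-phase Butterworth high-pass (drift removal)."""
    nyq = rec.fs / 2.0
    if not (0 < cutoff < nyq):
        raise ConfigurationError(f"cutoff must lie in (0, {nyq})")
    sos = sps.butter(order, cutoff / nyq, btype="highpass", output="sos")
    return _apply_sos(rec, sos, zero_phase)


def notch_filter(rec: EEGRecording, cfg: FilterConfig) -> EEGRecording:
    """IIR notch at the mains frequency (quality factor cfg.notch_q)."""
    cfg.validate(rec.fs)
    b, a = sps.iirnotch(cfg.notch_freq, cfg.notch_q, fs=rec.fs)
    filt = (lambda x: sps.filtfilt(b, a, x)) if cfg.zero_phase \
        else (lambda x: sps.lfilter(b, a, x))
    data = np.vstack([filt(ch) for ch in rec.data])
    return EEGRecording(data=data, fs=rec.fs, channel_names=rec.channel_names,
                        subject_id=rec.subject_id, label=rec.label,
                        artifact_truth=list(rec.artifact_truth))


def segment(rec: EEGRecording, window_len: int, hop: int | None = None) -> SegmentSet:
    """Cut a recording into windows of ``window_len`` samples every ``hop``.

    Yields floor((samples - window_len)/hop) + 1 segments; a window longer
    than the recording yields zero segments (with a logged warning, not an
    exception).
    """
    if hop is None:
        hop = window_len
    if window_len < 1 or hop < 1:
        raise ValueError("window_len and hop must be >= 1")
    n = rec.n_samples
    if window_len > n:
        logger.warning("window_len=%d exceeds recording length %d for %s; "
                       "0 segments", window_len, n, rec.subject_id)
        segs = np.empty((0, rec.n_channels, window_len))
        return SegmentSet(segs, window_len, hop, rec.fs, [], np.empty(0, int))
    n_seg = (n - window_len) // hop + 1
    starts = np.arange(n_seg) * hop
    segs = np.stack([rec.data[:, s:s + window_len] for s in starts])
    return SegmentSet(segs, window_len, hop, rec.fs,
                      [rec.subject_id] * n_seg,
                      np.full(n_seg, rec.label, dtype=int))


def concat_segment_sets(sets: list[SegmentSet]) -> SegmentSet:
    """Stack per-subject segment sets into one cohort-level set."""
    sets = [s for s in sets if s.n_segments > 0]
    if not sets:
        raise ValueError("no segments to concatenate")
    w, h, fs = sets[0].window_len, sets[0].hop, sets[0].fs
    for s in sets:
        if (s.window_len, s.hop, s.fs) != (w, h, fs):
            raise ValueError("segment sets have mismatched windowing")
    return SegmentSet(np.concatenate([s.segments for s in sets]),
                      w, h, fs,
                      sum((s.subject_ids for s in sets), []),
                      np.concatenate([s.labels for s in sets]),
                      np.concatenate([s.kept_mask for s in sets]))


def reject_artifacts(segs: SegmentSet, amp_threshold: float,
                     use_ica: bool = False, kurtosis_threshold: float = 5.0,
                     seed: int = 0) -> SegmentSet:
    """Flag artifact segments; optionally scrub spiky ICA components first.

    A segment is dropped (kept_mask False) when its peak absolute amplitude
    across channels exceeds ``amp_threshold`` µV.  With ``use_ica``, a
    FastICA decomposition is fitted on the concatenated segments and every
    component whose time course has excess kurtosis above
    ``kurtosis_threshold`` is zeroed before thresholding — targeting spiky
    blink/muscle components.  Without ICA, kept segments' samples are never
    modified.
    """
    if amp_threshold <= 0:
        raise ValueError("amp_threshold must be positive")
    segments = segs.segments
    if use_ica and segs.n_segments > 0:
        from sklearn.decomposition import FastICA

        n, nch, w = segments.shape
        X = segments.transpose(1, 0, 2).reshape(nch, n * w)  # channels x time
        ica = FastICA(n_components=min(nch, 20), random_state=seed,
                      whiten="unit-variance", max_iter=500, tol=1e-3)
        sources = ica.fit_transform(X.T)  # time x comps
        kurt = spstats.kurtosis(sources, axis=0)  # excess kurtosis
        bad = kurt > kurtosis_threshold
        if bad.any():
            logger.info("ICA: zeroing %d/%d high-kurtosis components",
                        int(bad.sum()), len(bad))
            sources[:, bad] = 0.0
            X_clean = ica.inverse_transform(sources).T
            segments = X_clean.reshape(nch, n, w).transpose(1, 0, 2)

    peaks = np.max(np.abs(segments), axis=(1, 2)) if segs.n_segments else np.empty(0)
    keep = segs.kept_mask & (peaks <= amp_threshold)
    n_removed = int(segs.kept_mask.sum() - keep.sum())
    logger.info("artifact rejection: removed %d of %d segments",
                n_removed, segs.n_segments)
    if segs.n_segments > 0 and not keep.any():
        raise ValueError(
            "all segments rejected; review amp_threshold "
            f"(={amp_threshold} µV) against the data's amplitude range")
    return SegmentSet(segments, segs.window_len, segs.hop, segs.fs,
                      list(segs.subject_ids), segs.labels.copy(), keep)


@dataclass
class NormStats:
    """Per-channel normalization statistics (for reuse on held-out data)."""

    mean: np.ndarray   # (channels,)
    sd: np.ndarray     # (channels,)

    def apply(self, segments: np.ndarray) -> np.ndarray:
        return (segments - self.mean[None, :, None]) / self.sd[None, :, None]


def normalize(segs: SegmentSet, stats_source: str = "train_only",
              stats: NormStats | None = None) -> tuple[SegmentSet, NormStats]:
    """Zero-mean unit-variance per channel.

    ``stats_source='train_only'`` computes one mean/SD per channel from the
    kept segments (or applies precomputed ``stats``); ``'per_segment'``
    standardizes every segment independently.  Zero-variance channels are
    floored at machine epsilon and logged.
    """
    if stats_source not in ("train_only", "per_segment"):
        raise ValueError(f"unknown stats_source {stats_source!r}")
    kept = segs.segments[segs.kept_mask]
    if kept.size == 0:
        raise ValueError("no kept segments to normalize")

    if stats_source == "per_segment":
        mean = segs.segments.mean(axis=2, keepdims=True)
        sd = segs.segments.std(axis=2, keepdims=True)
        floored = sd < np.finfo(float).eps
        if floored.any():
            logger.warning("normalize: %d zero-variance channel-segments floored",
                           int(floored.sum()))
        sd = np.maximum(sd, np.finfo(float).eps)
        data = (segs.segments - mean) / sd
        out_stats = NormStats(mean=np.zeros(segs.segments.shape[1]),
                              sd=np.ones(segs.segments.shape[1]))
    else:
        if stats is None:
            mean = kept.mean(axis=(0, 2))
            sd = kept.std(axis=(0, 2))
            floored = sd < np.finfo(float).eps
            if floored.any():
                logger.warning("normalize: %d zero-variance channels floored",
                               int(floored.sum()))
            sd = np.maximum(sd, np.finfo(float).eps)
            stats = NormStats(mean=mean, sd=sd)
        data = stats.apply(segs.segments)
        out_stats = stats

    out = SegmentSet(data, segs.window_len, segs.hop, segs.fs,
                     list(segs.subject_ids), segs.labels.copy(),
                     segs.kept_mask.copy())
    return out, out_stats
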