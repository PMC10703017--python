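"""Cohort-level feature extraction: recordings -> per-subject Gabor sequences.

Chains the preprocessing stages (band-pass, notch, segmentation,
amplitude-based artifact rejection) and the Gabor transform into the
per-subject feature tensors the classifiers consume.  Normalization of
the features themselves is deliberately left to the cross-validation
loop, which computes statistics on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gabor import GaborConfig, recording_features
from .preprocess import FilterConfig, bandpass_filter, notch_filter, segment
from .synth import EEGRecording


@dataclass
class FeatureConfig:
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    window_len: int = 1024
    hop: int | None = None           # default: non-overlapping
    amp_thresh_sd: float = 5.0       # rejection threshold in robust SDs
    gabor_cfg: GaborConfig = field(default_factory=GaborConfig)


class SubjectDataset:
    """Per-subject feature sequences with class labels.

    features_for(sid) returns an (n_segments, T, F) array; the accessor is
    the only route to a subject's data, so evaluation code can be audited
    for when it touches held-out subjects.
    """

    def __init__(self, features: dict[str, np.ndarray], labels: dict[str, int]):
        if set(features) != set(labels):
            raise ValueError("features and labels must cover the same subjects")
        self._features = features
        self._labels = labels

    @property
    def subjects(self) -> list[str]:
        return sorted(self._features)

    def label_for(self, sid: str) -> int:
        return self._labels[sid]

    @property
    def labels(self) -> np.ndarray:
        return np.array([self._labels[s] for s in self.subjects], dtype=int)

    def features_for(self, sid: str) -> np.ndarray:
        return self._features[sid]

    def with_permuted_labels(self, seed: int) -> "SubjectDataset":
        """Same features, labels randomly reassigned across subjects."""
        rng = np.random.default_rng(seed)
        sids = self.subjects
        permuted = rng.permutation([self._labels[s] for s in sids])
        return SubjectDataset(dict(self._features),
                              {s: int(l) for s, l in zip(sids, permuted)})

    @classmethod
    def from_records(cls, records: list[EEGRecording],
                     cfg: FeatureConfig) -> "SubjectDataset":
        features: dict[str, np.ndarray] = {}
        labels: dict[str, int] = {}
        for rec in records:
            feats = subject_features(rec, cfg)
            if len(feats) == 0:
                continue
            features[rec.subject_id] = feats
            labels[rec.subject_id] = rec.label
        return cls(features, labels)


def subject_features(rec: EEGRecording, cfg: FeatureConfig) -> np.ndarray:
    """Filter, segment, reject and transform one recording.

    Returns (n_kept_segments, T, F).  The rejection threshold is
    amp_thresh_sd times the recording's robust background SD (median of
    per-segment SDs), an automated surrogate for manual artifact curation.
    """
    from .preprocess import reject_artifacts

    filtered = notch_filter(bandpass_filter(rec, cfg.filter_cfg), cfg.filter_cfg)
    segs = segment(filtered, cfg.window_len, cfg.hop)
    if segs.n_segments == 0:
        return np.empty((0, 0, 0))
    robust_sd = float(np.median(segs.segments.std(axis=2)))
    segs = reject_artifacts(segs, amp_threshold=cfg.amp_thresh_sd * robust_sd)
    kept = segs.kept()
    return np.stack([recording_features(s, rec.fs, cfg.gabor_cfg)
                     for s in kept.segments])
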