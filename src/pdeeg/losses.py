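"""Classification loss and multi-scale score fusion."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of raw scores against one-hot labels.

    For each row: -sum_i y_i * (phi_i - log sum_k exp(phi_k)), i.e. the
    negative log-softmax of the true class, stabilized via log-sum-exp.
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    if logits.shape != labels.shape:
        raise ValueError("logits and labels must share a shape")
    if logits.shape[1] < 2:
        raise ValueError("need at least 2 classes")
    onehot = (np.all((labels == 0) | (labels == 1), axis=None)
              and np.allclose(labels.sum(axis=1), 1.0))
    if not onehot:
        raise ValueError("labels must be one-hot rows")
    log_z = logsumexp(logits, axis=1, keepdims=True)
    return float(-np.sum(labels * (logits - log_z)) / logits.shape[0])


@dataclass
class FusionConfig:
    """Sliding-window widths for combining per-step class scores."""

    window_widths: list[int] = field(default_factory=lambda: [1, 3, 5])
    literal: bool = False  # use the raw printed divisor (T-p)p instead of
    #                        mean-of-window-means

    def validate(self, T: int) -> None:
        for p in self.window_widths:
            if not (1 <= p <= T):
                raise ValueError(f"window width {p} must lie in [1, {T}]")


def multiscale_fusion(E: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    """Combine per-step scores E (T x C) into a single score vector.

    For each width p, every length-p window's scores are averaged, the
    window means are averaged, and the final score is the mean over widths.
    Constant inputs are fixed points of this reading.  ``literal=True``
    instead evaluates the raw double sum with divisor (T-p)*p (windows of
    p+1 steps starting at n = 1..T-p), kept for comparison.
    """
    E = np.atleast_2d(np.asarray(E, dtype=float))
    T = E.shape[0]
    cfg.validate(T)
    per_width = []
    for p in cfg.window_widths:
        if cfg.literal:
            if p >= T:
                raise ValueError(f"literal divisor undefined for p={p}, T={T}")
            acc = np.zeros(E.shape[1])
            for n in range(T - p):
                acc += E[n:n + p + 1].sum(axis=0)
            per_width.append(acc / ((T - p) * p))
        else:
            # mean over all T-p+1 windows of each window's mean
            c = np.cumsum(np.vstack([np.zeros(E.shape[1]), E]), axis=0)
            window_sums = c[p:] - c[:-p]
            per_width.append(window_sums.mean(axis=0) / p)
    return np.mean(per_width, axis=0)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
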