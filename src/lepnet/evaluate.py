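"""Support-recovery scoring: sensitivity, PPV, F1 and edge-frequency maps.

All counts are over the p(p-1)/2 unordered off-diagonal pairs (each
potential edge counted once).  Sensitivity (recall) is the fraction of true
edges recovered; PPV (precision) is the fraction of estimated edges that
are true; F1 is their harmonic mean.  Degenerate 0/0 ratios are reported as
0 and flagged so repetition averages stay well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvaluationResult",
    "confusion",
    "metrics",
    "evaluate_support",
    "relative_frequency_matrix",
]


@dataclass(frozen=True)
class EvaluationResult:
    sensitivity: float
    ppv: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    degenerate: bool = False  # some 0/0 ratio was reported as 0


def _check_support(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=bool)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.array_equal(m, m.T):
        raise ValueError(f"{name} must be symmetric; assemble the network first")
    return m


def confusion(true_support: np.ndarray, est_support: np.ndarray):
    """(tp, fp, fn, tn) over unordered off-diagonal pairs."""
    t = _check_support(true_support, "true_support")
    e = _check_support(est_support, "est_support")
    if t.shape != e.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {e.shape}")
    iu = np.triu_indices(t.shape[0], k=1)
    tv, ev = t[iu], e[iu]
    tp = int(np.count_nonzero(tv & ev))
    fp = int(np.count_nonzero(~tv & ev))
    fn = int(np.count_nonzero(tv & ~ev))
    tn = int(np.count_nonzero(~tv & ~ev))
    return tp, fp, fn, tn


def metrics(tp: int, fp: int, fn: int, tn: int = 0) -> EvaluationResult:
    """Sensitivity, PPV and F1 from confusion counts."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = False
    if tp + fn > 0:
        sens = tp / (tp + fn)
    else:
        sens, degenerate = 0.0, True
    if tp + fp > 0:
        ppv = tp / (tp + fp)
    else:
        ppv, degenerate = 0.0, True
    f1 = f1_score(sens, ppv)
    return EvaluationResult(sens, ppv, f1, tp, fp, fn, tn, degenerate)


def f1_score(sensitivity: float, ppv: float) -> float:
    """Harmonic mean 2*sens*ppv/(sens+ppv); 0 when both are 0."""
    if sensitivity + ppv <= 0.0:
        return 0.0
    return 2.0 * sensitivity * ppv / (sensitivity + ppv)


def evaluate_support(true_support, est_support) -> EvaluationResult:
    """Convenience: confusion + metrics in one call."""
    return metrics(*confusion(true_support, est_support))


def relative_frequency_matrix(supports: list[np.ndarray]) -> np.ndarray:
    """Per-entry fraction of repetitions in which an edge was estimated.

    The diagonal is reported as 1 by convention (mirroring the convention
    that a gene is trivially 'connected' to itself in frequency plots).
    """
    if len(supports) == 0:
        raise ValueError("need at least one support matrix")
    mats = [_check_support(s, f"supports[{k}]") for k, s in enumerate(supports)]
    shape = mats[0].shape
    for k, m in enumerate(mats):
        if m.shape != shape:
            raise ValueError(f"supports[{k}] has shape {m.shape}, expected {shape}")
    freq = np.mean([m.astype(float) for m in mats], axis=0)
    np.fill_diagonal(freq, 1.0)
    return freq
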