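"""Baseline fusion rules the DCCA fusion is compared against.

Feature level: z-scored concatenation of the two feature blocks, and
convex combination of modality kernels (multiple-kernel style, with fixed
weights). Decision level: MAX fusion (the class whose best probability
over classifiers is largest), the discrete Choquet integral with respect
to a Sugeno lambda-fuzzy measure built from per-source densities, and an
adaptive rule that up-weights the EEG score once it exceeds 0.4.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["concat_fuse", "combine_kernels", "max_fuse", "FuzzyMeasure",
           "sugeno_lambda_measure", "choquet_fuse", "choquet_label",
           "adaptive_fuse"]

logger = logging.getLogger(__name__)


def concat_fuse(i1: np.ndarray, i2: np.ndarray,
                stats: tuple | None = None):
    """Z-normalize each modality's columns, then concatenate.

    ``stats`` carries the normalization statistics of the training split
    as ``(mu1, sd1, mu2, sd2)``; when None they are computed from the
    inputs and returned alongside the fused matrix so a caller can reuse
    them on held-out rows. Zero-variance columns are dropped (logged).

    Returns ``(fused, stats)``.
    """
    i1 = np.atleast_2d(np.asarray(i1, float))
    i2 = np.atleast_2d(np.asarray(i2, float))
    if i1.size and i2.size and i1.shape[0] != i2.shape[0]:
        raise ValueError("modalities must share rows")
    if stats is None:
        stats = (i1.mean(axis=0) if i1.size else np.zeros(0),
                 i1.std(axis=0, ddof=1) if i1.size else np.zeros(0),
                 i2.mean(axis=0) if i2.size else np.zeros(0),
                 i2.std(axis=0, ddof=1) if i2.size else np.zeros(0))
    mu1, sd1, mu2, sd2 = stats
    blocks = []
    for x, mu, sd, tag in ((i1, mu1, sd1, "modality-1"),
                           (i2, mu2, sd2, "modality-2")):
        if x.size == 0:
            continue
        keep = sd > 0
        if not keep.all():
            logger.warning("%s: dropping %d zero-variance column(s)",
                           tag, int((~keep).sum()))
        blocks.append((x[:, keep] - mu[keep]) / sd[keep])
    fused = np.hstack(blocks) if blocks else np.zeros((i1.shape[0], 0))
    return fused, stats


def combine_kernels(kernels: list[np.ndarray],
                    weights=None) -> np.ndarray:
    """Convex combination of Gram matrices; PSD is preserved."""
    if not kernels:
        raise ValueError("need at least one kernel")
    shape = kernels[0].shape
    for k in kernels:
        if k.shape != shape:
            raise ValueError("kernels must share shape")
    if weights is None:
        weights = np.full(len(kernels), 1.0 / len(kernels))
    weights = np.asarray(weights, float)
    if len(weights) != len(kernels) or (weights < 0).any() or \
            abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must lie on the simplex")
    out = sum(w * k for w, k in zip(weights, kernels))
    return 0.5 * (out + out.T)  # enforce exact symmetry


def max_fuse(probs: np.ndarray) -> np.ndarray:
    """MAX decision fusion over a (U classifiers, T trials, V classes) table.

    Per trial, pick the class whose maximum probability over the U
    classifiers is largest; ties break toward the lowest class index.
    """
    probs = np.asarray(probs, float)
    if probs.ndim != 3 or probs.size == 0:
        raise ValueError("expected a non-empty (U, T, V) probability table")
    best_over_classifiers = probs.max(axis=0)  # (T, V)
    return best_over_classifiers.argmax(axis=1)  # argmax: first max wins


@dataclass
class FuzzyMeasure:
    """Sugeno lambda-fuzzy measure over n information sources.

    ``values`` maps each subset (as a frozenset of source indices) to its
    measure; lambda is the Sugeno interaction parameter (0 = additive).
    """

    densities: np.ndarray
    lam: float
    values: dict[frozenset, float] = field(default_factory=dict)

    def __call__(self, subset) -> float:
        return self.values[frozenset(subset)]


def sugeno_lambda_measure(densities) -> FuzzyMeasure:
    """Build the lambda-fuzzy measure from per-source densities in (0, 1).

    lambda is the unique root > -1 (and != 0) of
    prod(1 + lambda * g_i) = 1 + lambda; densities summing to 1 give the
    additive special case lambda = 0. Subset values follow the recursion
    m(A + {i}) = m(A) + g_i + lambda * g_i * m(A).
    """
    g = np.asarray(densities, float)
    if g.ndim != 1 or len(g) < 2:
        raise ValueError("need at least 2 source densities")
    if (g <= 0).any() or (g >= 1).any():
        raise ValueError("densities must lie strictly in (0, 1)")
    total = g.sum()
    if abs(total - 1.0) < 1e-12:
        lam = 0.0
    else:
        def f(lam_):
            return np.prod(1.0 + lam_ * g) - (1.0 + lam_)
        if total < 1.0:  # lambda > 0
            hi = 1.0
            while f(hi) < 0:
                hi *= 2.0
            lam = optimize.brentq(f, 1e-12, hi, xtol=1e-14, rtol=1e-15)
        else:  # -1 < lambda < 0
            lam = optimize.brentq(f, -1.0 + 1e-12, -1e-12,
                                  xtol=1e-14, rtol=1e-15)
    n = len(g)
    values: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            prev = frozenset(subset[:-1])
            i = subset[-1]
            m_prev = values[prev]
            values[frozenset(subset)] = m_prev + g[i] + lam * g[i] * m_prev
    # the recursion gives m(full) = 1 up to root-finding precision; pin it
    full = frozenset(range(n))
    if abs(values[full] - 1.0) > 1e-10:
        raise ArithmeticError("lambda-measure failed to normalize")
    values[full] = 1.0
    return FuzzyMeasure(densities=g, lam=float(lam), values=values)


def choquet_fuse(h, measure: FuzzyMeasure) -> float:
    """Discrete Choquet integral of non-negative scores h w.r.t. a measure.

    Scores are sorted ascending (h(x_0) = 0) and the increments
    h(x_i) - h(x_{i-1}) are weighted by the measure of the sources from
    rank i upward.
    """
    h = np.asarray(h, float)
    if h.ndim != 1 or len(h) != len(measure.densities):
        raise ValueError("one score per source required")
    if (h < 0).any():
        raise ValueError("scores must be non-negative")
    order = np.argsort(h, kind="stable")
    total, prev = 0.0, 0.0
    for rank, idx in enumerate(order):
        upper = frozenset(order[rank:].tolist())
        total += (h[idx] - prev) * measure(upper)
        prev = h[idx]
    return float(total)


def choquet_label(probs: np.ndarray,
                  measures) -> np.ndarray:
    """Per-trial labels from Choquet-fused class scores.

    ``probs`` is a (U, T, V) table; ``measures`` is one FuzzyMeasure (used
    for every class) or a sequence of V class-specific measures. The label
    is the class with the largest integral.
    """
    probs = np.asarray(probs, float)
    u, t, v = probs.shape
    if isinstance(measures, FuzzyMeasure):
        measures = [measures] * v
    fused = np.empty((t, v))
    for ti in range(t):
        for vi in range(v):
            fused[ti, vi] = choquet_fuse(probs[:, ti, vi], measures[vi])
    return fused.argmax(axis=1)


def adaptive_fuse(y_eeg: float, y_face: float) -> float:
    """Adaptive decision rule over two scores in [0, 1].

    Below the 0.4 threshold on the EEG score the two scores are simply
    averaged; above it the EEG score receives slightly more weight,
    growing linearly with its margin over 0.4 (continuous at the
    threshold).
    """
    for s in (y_eeg, y_face):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score {s} outside [0, 1]")
    if y_eeg > 0.4:
        return (y_face + (1.0 + (y_eeg - 0.4) / 100.0) * y_eeg) / 2.0
    return (y_eeg + y_face) / 2.0
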