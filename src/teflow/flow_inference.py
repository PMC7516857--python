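"""Pairwise transfer-entropy matrices, detection scoring and ROC analysis.

From a recording of a behaving brain we estimate the plug-in transfer
entropy for every ordered neuron pair and compare the thresholded TE
matrix against the ground-truth influence map: an edge with TE above the
threshold is a *hit* if the influence map contains it and a *false alarm*
otherwise; true edges with TE at or below the threshold are *misses*.
Sweeping the threshold over [0, 1] yields an ROC curve; a two-Gaussian
signal-detection model fitted to the TE values of edge and non-edge pairs
gives the smooth reference curve

    f(x) = 1/2 · erfc( (mu2 − mu1)/(sqrt(2)·sigma1) + (sigma2/sigma1)·erfcinv(2x) )

where (mu1, sigma1) describe TE given an edge is present and (mu2, sigma2)
TE given it is absent.  When the two distributions coincide the curve is
the chance diagonal f(x) = x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import erfc, erfcinv

from .info_theory import TransitionDataset, processed_information, transfer_entropy
from .markov_brain import Brain, influence_map
from . import tasks

__all__ = [
    "te_matrix",
    "DetectionResult",
    "score_detection",
    "ROCCurve",
    "roc",
    "GaussianROC",
    "fit_gaussian_roc",
    "edge_values",
    "FlowAnalysis",
    "analyze_brain",
]


def te_matrix(ds: TransitionDataset, include_self: bool = False) -> np.ndarray:
    """Pairwise TE (bits) from pooled within-trial transitions.

    Entry [i, j] is TE(i → j); the diagonal holds the processed
    information I(Z_t : Z_{t+1}) when ``include_self`` is set and zero
    otherwise (and is then excluded from scoring).
    """
    n = ds.n_neurons
    m = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(n):
            if i == j:
                if include_self:
                    m[i, j] = processed_information(ds, i)
            else:
                m[i, j] = transfer_entropy(ds, i, j)
    return m


@dataclass(frozen=True)
class DetectionResult:
    hits: int
    misses: int
    false_alarms: int
    hit_rate: float
    false_alarm_rate: float
    n_edges: int
    n_nonedges: int


def score_detection(
    te: np.ndarray,
    truth: np.ndarray,
    threshold: float = 0.0,
    include_diagonal: bool = False,
) -> DetectionResult:
    """Score TE > threshold against the binary influence map.

    The strict inequality means exact zeros are never detections, matching
    the convention that "any non-zero TE implies some flow" at threshold 0.
    """
    te = np.asarray(te, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if te.shape != truth.shape:
        raise ValueError(f"shape mismatch: {te.shape} vs {truth.shape}")
    mask = np.ones_like(truth, dtype=bool)
    if not include_diagonal:
        np.fill_diagonal(mask, False)
    detected = (te > threshold) & mask
    edges = truth & mask
    hits = int(np.sum(detected & edges))
    misses = int(np.sum(edges & ~detected))
    false_alarms = int(np.sum(detected & ~edges))
    n_edges = int(np.sum(edges))
    n_nonedges = int(np.sum(mask & ~edges))
    return DetectionResult(
        hits=hits,
        misses=misses,
        false_alarms=false_alarms,
        hit_rate=hits / n_edges if n_edges else 0.0,
        false_alarm_rate=false_alarms / n_nonedges if n_nonedges else 0.0,
        n_edges=n_edges,
        n_nonedges=n_nonedges,
    )


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC: thresholds (descending) and (false-alarm, hit) points."""

    thresholds: tuple[float, ...]
    points: tuple[tuple[float, float], ...]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.asarray(self.points)
        return pts[:, 0], pts[:, 1]


def roc(
    te: np.ndarray,
    truth: np.ndarray,
    thresholds: Sequence[float] | None = None,
    include_diagonal: bool = False,
) -> ROCCurve:
    """Detection scores over a grid of thresholds, sorted descending.

    Lowering the threshold can only add detections, so both rates are
    weakly increasing along the returned point list; the last point is the
    vanishing-threshold analysis (highest hit rate).
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    ts = sorted((float(t) for t in thresholds), reverse=True)
    points = []
    for t in ts:
        r = score_detection(te, truth, threshold=t, include_diagonal=include_diagonal)
        points.append((r.false_alarm_rate, r.hit_rate))
    return ROCCurve(thresholds=tuple(ts), points=tuple(points))


@dataclass(frozen=True)
class GaussianROC:
    """Two-Gaussian signal-detection ROC model."""

    mu1: float      # mean TE when an edge is present
    sigma1: float
    mu2: float      # mean TE when no edge is present
    sigma2: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            arg = (self.mu2 - self.mu1) / (math.sqrt(2.0) * self.sigma1) + (
                self.sigma2 / self.sigma1
            ) * erfcinv(2.0 * x)
        return 0.5 * erfc(arg)


def edge_values(
    te: np.ndarray, truth: np.ndarray, include_diagonal: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Split TE entries into edge-present and edge-absent samples."""
    te = np.asarray(te, dtype=float)
    truth = np.asarray(truth).astype(bool)
    mask = np.ones_like(truth, dtype=bool)
    if not include_diagonal:
        np.fill_diagonal(mask, False)
    return te[truth & mask], te[~truth & mask]


def fit_gaussian_roc(
    edge_te_values: Sequence[float], nonedge_te_values: Sequence[float]
) -> GaussianROC:
    """Fit class means/SDs by moments; error on degenerate (zero-SD) classes."""
    a = np.asarray(edge_te_values, dtype=float)
    b = np.asarray(nonedge_te_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both TE samples must be non-empty")
    s1 = float(a.std(ddof=1)) if a.size > 1 else 0.0
    s2 = float(b.std(ddof=1)) if b.size > 1 else 0.0
    if s1 <= 0.0 or s2 <= 0.0:
        raise ValueError(
            "zero variance in a class; the Gaussian fit is degenerate — "
            "use the empirical ROC instead"
        )
    return GaussianROC(mu1=float(a.mean()), sigma1=s1, mu2=float(b.mean()), sigma2=s2)


@dataclass(frozen=True)
class FlowAnalysis:
    """End-to-end result for one brain: record → TE → truth → score."""

    te: np.ndarray
    truth: np.ndarray
    detection: DetectionResult
    curve: ROCCurve


def analyze_brain(brain: Brain, task: str, include_self: bool = False) -> FlowAnalysis:
    """Record the brain on its task and score TE flow detection at threshold 0."""
    if task == "md":
        trials = tasks.md_trials(sensors=(brain.sensory[0], brain.sensory[1]))
    elif task == "sl":
        trials = tasks.sl_trials(sensors=(brain.sensory[0], brain.sensory[1]))
    else:
        raise ValueError(f"unknown task {task!r}")
    ds = tasks.record(brain, trials)
    te = te_matrix(ds, include_self=include_self)
    truth = influence_map(brain)
    det = score_detection(te, truth, threshold=0.0, include_diagonal=include_self)
    curve = roc(te, truth, include_diagonal=include_self)
    return FlowAnalysis(te=te, truth=truth, detection=det, curve=curve)
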