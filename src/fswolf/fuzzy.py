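"""Fuzzy scoring head: class distributions, window centroids, redistribution.

Classes are indexed 1..m (the math convention used throughout this
module; callers translate from 0-based labels). Given per-class
energies E_i from the network's output layer, the class distribution
is the normalized negative exponential

    P_i = exp(-E_i) / sum_j exp(-E_j),

a softmax over -E. For a class i, a fuzzy window [i-a, i+b] (clipped to
[1, m]) around it defines the window centroid V0 — the
probability-weighted mean class index over the window — and the
redistributed probability

    Ptilde_i = (|i - V0| / (a + b)) * sum_{j in window} P_j.

The window width a+b normalizes the centroid distance so that
0 <= |i - V0|/(a+b) < 1 always holds. The plain backpropagation error
eps_i = y_i - P_i is replaced at the output layer by the fuzzy error
epstilde_i = y_i - Ptilde_i; their induced difference
phi = Ptilde_i - P_i is nonpositive whenever class i carries the
largest probability inside its window, so confident samples contribute
a damped error signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FuzzyScoringConfig",
    "FuzzyScoringState",
    "class_distribution",
    "window_bounds",
    "window_centroid",
    "fuzzy_redistribute",
    "redistributed_vector",
    "fuzzy_errors",
    "GaussianMemberships",
    "fit_gaussian_memberships",
    "tune_memberships_grid",
]


@dataclass
class FuzzyScoringConfig:
    """Window extents, score anchors and decision thresholds of the head.

    a extends the window toward lower class indices (benign-ward), b
    toward higher ones (malignant-ward). Score anchors default to the
    class indices 1..m so the continuous score Stilde = V0 reads as a
    decimal-valued class index.
    """

    m: int = 2
    a: int = 1
    b: int = 1
    anchors: tuple[float, ...] | None = None
    thresholds: tuple[float, ...] | None = None
    spread_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least two classes")
        if self.a < 0 or self.b < 0 or self.a + self.b < 1:
            raise ValueError("window extents must be nonnegative with a + b >= 1")
        if self.anchors is None:
            self.anchors = tuple(float(i) for i in range(1, self.m + 1))
        if self.thresholds is None:
            self.thresholds = tuple(0.5 for _ in range(self.m))
        if any(not (0 < t < 1) for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class FuzzyScoringState:
    """Per-sample quantities of one fuzzy scoring evaluation."""

    energies: np.ndarray
    P: np.ndarray
    V0: float
    P_tilde: float
    eps: float
    eps_tilde: float
    phi: float


def class_distribution(energies: np.ndarray) -> np.ndarray:
    """P_i proportional to exp(-E_i), stabilized by subtracting min E."""
    E = np.asarray(energies, dtype=np.float64)
    if not np.all(np.isfinite(E)):
        raise ValueError("energies must be finite")
    z = np.exp(-(E - E.min()))
    return z / z.sum()


def window_bounds(i: int, a: int, b: int, m: int) -> tuple[int, int]:
    """Clipped fuzzy window [max(1, i-a), min(m, i+b)] (1-based, inclusive)."""
    if not 1 <= i <= m:
        raise ValueError(f"class index {i} outside [1, {m}]")
    return max(1, i - a), min(m, i + b)


def window_centroid(P: np.ndarray, i: int, a: int, b: int) -> float:
    """V0: probability-weighted mean class index over the clipped window."""
    P = np.asarray(P, dtype=np.float64)
    lo, hi = window_bounds(i, a, b, P.size)
    idx = np.arange(lo, hi + 1)
    w = P[lo - 1 : hi]
    total = w.sum()
    if total <= 0:
        raise ValueError("window probability mass is zero")
    v0 = float((idx * w).sum() / total)
    return min(max(v0, float(lo)), float(hi))  # guard float round-off at the edges


def fuzzy_redistribute(P: np.ndarray, i: int, a: int, b: int) -> float:
    """Ptilde_i = (|i - V0| / (a+b)) * sum of window probabilities."""
    if a + b < 1:
        raise ValueError("window width a + b must be >= 1")
    P = np.asarray(P, dtype=np.float64)
    lo, hi = window_bounds(i, a, b, P.size)
    v0 = window_centroid(P, i, a, b)
    return float(abs(i - v0) / (a + b) * P[lo - 1 : hi].sum())


def redistributed_vector(P: np.ndarray, a: int, b: int) -> np.ndarray:
    """Ptilde_j for every class j, each with its own window."""
    P = np.asarray(P, dtype=np.float64)
    return np.array([fuzzy_redistribute(P, j, a, b) for j in range(1, P.size + 1)])


def fuzzy_errors(
    y: np.ndarray, P: np.ndarray, i: int, a: int, b: int
) -> tuple[float, float, float]:
    """Plain error, fuzzy error and their induced delta for class i.

    eps_i = y_i - P_i; epstilde_i = y_i - Ptilde_i;
    phi = Ptilde_i - P_i (the redistribution term minus the plain
    probability, the operative definition that powers the phi <= 0
    damping property).
    """
    y = np.asarray(y, dtype=np.float64)
    P = np.asarray(P, dtype=np.float64)
    if y.shape != P.shape:
        raise ValueError("y and P must have equal shape")
    p_tilde = fuzzy_redistribute(P, i, a, b)
    eps = float(y[i - 1] - P[i - 1])
    eps_tilde = float(y[i - 1] - p_tilde)
    phi = float(p_tilde - P[i - 1])
    return eps, eps_tilde, phi


def scoring_state(
    energies: np.ndarray, y: np.ndarray, i: int, config: FuzzyScoringConfig
) -> FuzzyScoringState:
    """Evaluate the full fuzzy scoring chain for one sample and class i."""
    P = class_distribution(energies)
    v0 = window_centroid(P, i, config.a, config.b)
    eps, eps_tilde, phi = fuzzy_errors(y, P, i, config.a, config.b)
    return FuzzyScoringState(
        energies=np.asarray(energies, dtype=np.float64),
        P=P,
        V0=v0,
        P_tilde=fuzzy_redistribute(P, i, config.a, config.b),
        eps=eps,
        eps_tilde=eps_tilde,
        phi=phi,
    )


@dataclass
class GaussianMemberships:
    """Per-class Gaussian membership curves over a scalar activation summary."""

    mean: np.ndarray
    spread: np.ndarray  # floored at 1e-3
    spread_scale: float = 1.0

    def degree(self, summary: np.ndarray) -> np.ndarray:
        """Unnormalized membership degree per class; 1.0 at the class mean."""
        s = np.atleast_1d(np.asarray(summary, dtype=np.float64))[:, None]
        sd = self.spread[None, :] * self.spread_scale
        return np.exp(-0.5 * ((s - self.mean[None, :]) / sd) ** 2)


def fit_gaussian_memberships(
    activations: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray,
) -> GaussianMemberships:
    """Fit per-class membership curves from penultimate activations.

    The scalar summary of a sample for class c is the projection of its
    penultimate activation onto that class's output weight vector; the
    membership mean and spread are that summary's statistics over the
    class's training samples, spread floored at 1e-3.
    """
    activations = np.asarray(activations, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    means, spreads = [], []
    for c in classes:
        rows = activations[labels == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        summary = rows @ class_weights[int(c)]
        means.append(summary.mean())
        spreads.append(max(float(summary.std()), 1e-3))
    return GaussianMemberships(mean=np.asarray(means), spread=np.asarray(spreads))


def tune_memberships_grid(
    config: FuzzyScoringConfig,
    val_probs: np.ndarray,
    val_labels: np.ndarray,
    spread_scales=(0.5, 1.0, 2.0),
    thresholds=(0.3, 0.4, 0.5, 0.6, 0.7),
) -> FuzzyScoringConfig:
    """Grid-search spread scaling and the positive-class threshold.

    Selects the grid point maximizing validation balanced accuracy;
    deterministic tie-break prefers the larger spread, then the lower
    threshold. Binary only: a sample is called positive when its
    positive-class probability reaches the threshold.
    """
    if len(spread_scales) == 0 or len(thresholds) == 0:
        raise ValueError("grid must be nonempty")
    val_probs = np.asarray(val_probs, dtype=np.float64)
    val_labels = np.asarray(val_labels)
    if val_labels.size == 0 or len(np.unique(val_labels)) < 2:
        raise ValueError("validation set must contain both classes")
    best = None
    for scale in spread_scales:
        for thr in thresholds:
            pred = (val_probs[:, 1] >= thr).astype(int)
            accs = [
                (pred[val_labels == c] == c).mean() for c in np.unique(val_labels)
            ]
            bal = float(np.mean(accs))
            key = (bal, scale, -thr)
            if best is None or key > best[0]:
                best = (key, scale, thr)
    _, scale, thr = best
    return FuzzyScoringConfig(
        m=config.m,
        a=config.a,
        b=config.b,
        anchors=config.anchors,
        thresholds=(1 - thr, thr),
        spread_scale=float(scale),
    )
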