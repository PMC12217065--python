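"""Grey wolf optimizer and its adaptive multi-objective extension.

The single-objective core follows the canonical social-hierarchy
scheme: the three best solutions (alpha, beta, delta) guide all wolves
via randomized encircling updates

    D = |C * X_p - X|,   X' = X_p - A * D,
    A = 2a*r1 - a,       C = 2*r2,

with the exploration scalar a decaying linearly from 2 to 0 over the
run. The adaptive multi-objective variant (AGWO) adds a bounded
non-dominated archive, a hypercube grid over objective space, and
roulette leader election that favors sparsely populated cells with
probability proportional to c / N_i (occupancy N_i, constant c > 1).

Front-ends decode continuous wolf positions into feature-subset masks
(threshold rule) and CNN hyperparameters (log-uniform learning rate
and weight decay, batch size by thirds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SearchSpace",
    "Wolf",
    "ParetoArchive",
    "HypercubeGrid",
    "LeaderSet",
    "linear_decay",
    "coefficient_vectors",
    "encircle",
    "hunt_position",
    "gwo_minimize",
    "dominates",
    "update_archive",
    "cell_probabilities",
    "select_cell",
    "select_leaders",
    "agwo_minimize",
    "decode_feature_mask",
    "FeatureSelectionProblem",
    "decode_hyperparams",
]


@dataclass
class SearchSpace:
    """Axis-aligned continuous box."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=np.float64)
        self.upper = np.asarray(self.upper, dtype=np.float64)
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal shape")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clamp(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))

    @classmethod
    def unit(cls, dim: int) -> "SearchSpace":
        return cls(np.zeros(dim), np.ones(dim))


@dataclass
class Wolf:
    position: np.ndarray
    fitness: tuple[float, ...]


@dataclass
class LeaderSet:
    alpha: Wolf
    beta: Wolf
    delta: Wolf


def linear_decay(t: int, T: int) -> float:
    """Exploration scalar a = 2 * (1 - t/T), linearly lowered from 2 to 0."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 <= t <= T:
        raise ValueError("t must lie in [0, T]")
    return 2.0 * (1.0 - t / T)


def coefficient_vectors(
    a: float, rng: np.random.Generator, dim: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fresh coefficient vectors A = 2a*r1 - a (in [-a,a]) and C = 2*r2 (in [0,2])."""
    r1 = rng.uniform(size=dim)
    r2 = rng.uniform(size=dim)
    return 2.0 * a * r1 - a, 2.0 * r2


def encircle(
    position: np.ndarray,
    leader: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    space: SearchSpace | None = None,
) -> np.ndarray:
    """One encircling update: X' = X_p - A * |C*X_p - X|, clamped to bounds."""
    D = np.abs(C * leader - position)
    new = leader - A * D
    return space.clamp(new) if space is not None else new


def hunt_position(
    position: np.ndarray,
    leaders: LeaderSet,
    a: float,
    rng: np.random.Generator,
    space: SearchSpace | None = None,
) -> np.ndarray:
    """Average of encircling moves toward alpha, beta and delta."""
    parts = []
    for lead in (leaders.alpha, leaders.beta, leaders.delta):
        A, C = coefficient_vectors(a, rng, position.size)
        parts.append(encircle(position, lead.position, A, C))
    new = (parts[0] + parts[1] + parts[2]) / 3.0
    return space.clamp(new) if space is not None else new


def _check_finite(fitness, position) -> None:
    if not np.all(np.isfinite(fitness)):
        raise ValueError(f"objective returned non-finite value at position {position}")


def gwo_minimize(
    objective,
    space: SearchSpace,
    n_wolves: int = 30,
    T: int = 300,
    seed: int = 0,
) -> tuple[Wolf, list[float]]:
    """Single-objective grey wolf minimization.

    Returns the best-ever wolf and the per-iteration best-fitness
    history (monotone nonincreasing by bookkeeping).
    """
    if n_wolves < 3:
        raise ValueError("need at least 3 wolves")
    rng = np.random.default_rng(seed)
    positions = space.sample(rng, n_wolves)
    fitness = np.empty(n_wolves)
    for i in range(n_wolves):
        fitness[i] = float(objective(positions[i]))
        _check_finite(fitness[i], positions[i])
    best_idx = int(np.argmin(fitness))
    best = Wolf(positions[best_idx].copy(), (float(fitness[best_idx]),))
    history: list[float] = []
    for t in range(T):
        a = linear_decay(t, T)
        order = np.argsort(fitness, kind="stable")
        leaders = LeaderSet(
            *(Wolf(positions[j].copy(), (float(fitness[j]),)) for j in order[:3])
        )
        for i in range(n_wolves):
            positions[i] = hunt_position(positions[i], leaders, a, rng, space)
            fitness[i] = float(objective(positions[i]))
            _check_finite(fitness[i], positions[i])
        it_best = int(np.argmin(fitness))
        if fitness[it_best] < best.fitness[0]:
            best = Wolf(positions[it_best].copy(), (float(fitness[it_best]),))
        history.append(best.fitness[0])
    return best, history


def dominates(f: tuple[float, ...], g: tuple[float, ...]) -> bool:
    """Pareto dominance (minimization): f <= g everywhere, < somewhere."""
    if len(f) != len(g):
        raise ValueError("objective tuples must have equal length")
    fa, ga = np.asarray(f), np.asarray(g)
    return bool(np.all(fa <= ga) and np.any(fa < ga))


@dataclass
class HypercubeGrid:
    """Uniform grid over the archive's objective-space bounding box.

    Bounds are inflated by ``margin`` beyond the observed ranges so
    boundary members fall strictly inside; a candidate outside the grid
    triggers a rebuild.
    """

    divisions: int = 10
    margin: float = 0.1
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def rebuild(self, objectives: np.ndarray) -> None:
        lo = objectives.min(axis=0)
        hi = objectives.max(axis=0)
        span = np.maximum(hi - lo, 1e-12)
        self.lower = lo - self.margin * span
        self.upper = hi + self.margin * span

    def contains(self, f: np.ndarray) -> bool:
        if self.lower is None:
            return False
        return bool(np.all(f >= self.lower) and np.all(f <= self.upper))

    def cell_of(self, f: np.ndarray) -> tuple[int, ...]:
        rel = (np.asarray(f) - self.lower) / (self.upper - self.lower)
        idx = np.clip((rel * self.divisions).astype(int), 0, self.divisions - 1)
        return tuple(idx.tolist())


@dataclass
class ParetoArchive:
    """Bounded store of mutually non-dominated solutions."""

    capacity: int = 100
    members: list[Wolf] = field(default_factory=list)

    def objectives(self) -> np.ndarray:
        return np.asarray([m.fitness for m in self.members], dtype=np.float64)

    def cells(self, grid: HypercubeGrid) -> list[tuple[int, ...]]:
        return [grid.cell_of(np.asarray(m.fitness)) for m in self.members]


def update_archive(
    archive: ParetoArchive,
    candidate: Wolf,
    grid: HypercubeGrid,
    rng: np.random.Generator,
) -> ParetoArchive:
    """Insert a candidate, prune dominated members, evict on overflow.

    Eviction removes one member uniformly at random from the most
    occupied grid cell. A candidate outside the current grid bounds
    triggers a grid rebuild over the updated archive.
    """
    f = candidate.fitness
    for m in archive.members:
        if dominates(m.fitness, f) or m.fitness == f:
            return archive
    archive.members = [m for m in archive.members if not dominates(f, m.fitness)]
    archive.members.append(Wolf(candidate.position.copy(), tuple(candidate.fitness)))
    objs = archive.objectives()
    if not grid.contains(np.asarray(f)):
        grid.rebuild(objs)
    if len(archive.members) > archive.capacity:
        cells = archive.cells(grid)
        counts: dict[tuple[int, ...], int] = {}
        for cell in cells:
            counts[cell] = counts.get(cell, 0) + 1
        most = max(counts.values())
        crowded = sorted(c for c, k in counts.items() if k == most)[0]
        pool = [i for i, cell in enumerate(cells) if cell == crowded]
        victim = pool[rng.integers(len(pool))]
        archive.members.pop(victim)
    return archive


def cell_probabilities(occupancies: np.ndarray, c: float = 2.0) -> np.ndarray:
    """Normalized roulette weights P_i proportional to c / N_i."""
    occ = np.asarray(occupancies, dtype=np.float64)
    if np.any(occ <= 0):
        raise ValueError("occupancies must be positive")
    if c <= 1:
        raise ValueError("c must be > 1")
    w = c / occ
    return w / w.sum()


def select_cell(occupancies: np.ndarray, c: float, rng: np.random.Generator) -> int:
    """Roulette draw of one cell index under the c/N_i law."""
    p = cell_probabilities(occupancies, c)
    return int(rng.choice(len(p), p=p))


def select_leaders(
    archive: ParetoArchive,
    grid: HypercubeGrid,
    c: float,
    rng: np.random.Generator,
) -> LeaderSet:
    """Elect alpha, beta, delta from the archive by crowding-aware roulette.

    Each draw picks a cell with probability proportional to c/N_i over
    the cells still holding unchosen members, then a member uniformly
    within that cell; chosen members are excluded from later draws so
    the three leaders are distinct whenever the archive holds >= 3
    solutions (with fewer, leaders repeat).
    """
    if not archive.members:
        raise ValueError("cannot elect leaders from an empty archive")
    cells = archive.cells(grid)
    available = list(range(len(archive.members)))
    chosen: list[Wolf] = []
    for _ in range(3):
        if not available:  # tiny archive: allow repeats
            available = list(range(len(archive.members)))
        cell_ids = sorted({cells[i] for i in available})
        occ = np.array(
            [sum(1 for i in available if cells[i] == cid) for cid in cell_ids]
        )
        cid = cell_ids[select_cell(occ, c, rng)]
        pool = [i for i in available if cells[i] == cid]
        pick = pool[rng.integers(len(pool))]
        chosen.append(archive.members[pick])
        available.remove(pick)
    return LeaderSet(*chosen)


def agwo_minimize(
    objectives,
    space: SearchSpace,
    n_wolves: int = 30,
    T: int = 200,
    capacity: int = 100,
    divisions: int = 10,
    c: float = 2.0,
    seed: int = 0,
    init_positions: np.ndarray | None = None,
) -> tuple[ParetoArchive, list[dict]]:
    """Adaptive multi-objective grey wolf optimization.

    ``objectives`` maps a position to a tuple of >= 2 values (all
    minimized). ``init_positions`` optionally pins the first rows of
    the initial pack (e.g. to warm-start with an incumbent solution).
    Returns the final archive and a per-iteration history of archive
    size and best value per objective.
    """
    if n_wolves < 3:
        raise ValueError("need at least 3 wolves")
    rng = np.random.default_rng(seed)
    positions = space.sample(rng, n_wolves)
    if init_positions is not None:
        init = np.atleast_2d(np.asarray(init_positions, dtype=np.float64))
        if init.shape[0] > n_wolves or init.shape[1] != space.dim:
            raise ValueError("init_positions must fit the pack and dimension")
        positions[: init.shape[0]] = space.clamp(init)
    archive = ParetoArchive(capacity=capacity)
    grid = HypercubeGrid(divisions=divisions)

    def evaluate(pos: np.ndarray) -> tuple[float, ...]:
        f = tuple(float(v) for v in objectives(pos))
        if len(f) < 2:
            raise ValueError("agwo_minimize needs >= 2 objectives")
        _check_finite(f, pos)
        return f

    fitness = [evaluate(positions[i]) for i in range(n_wolves)]
    for i in range(n_wolves):
        update_archive(archive, Wolf(positions[i], fitness[i]), grid, rng)
    history: list[dict] = []
    for t in range(T):
        a = linear_decay(t, T)
        leaders = select_leaders(archive, grid, c, rng)
        for i in range(n_wolves):
            positions[i] = hunt_position(positions[i], leaders, a, rng, space)
            fitness[i] = evaluate(positions[i])
            update_archive(archive, Wolf(positions[i], fitness[i]), grid, rng)
        objs = archive.objectives()
        history.append(
            {
                "iteration": t,
                "archive_size": len(archive.members),
                "best_per_objective": objs.min(axis=0).tolist(),
            }
        )
    return archive, history


def decode_feature_mask(position: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Threshold decoding of a continuous position into a binary mask.

    An all-zero mask is coerced to keep the single largest coordinate,
    so downstream objectives always see >= 1 feature.
    """
    position = np.asarray(position, dtype=np.float64)
    mask = position > tau
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return mask


class FeatureSelectionProblem:
    """Bi-objective wrapper feature selection on a training table.

    Objectives (both minimized): held-out error rate of a fixed, cheap
    regularized linear classifier under seeded stratified splits of the
    training portion (k-fold cross-validation, so every training sample
    scores each mask once), and the selected-feature fraction.

    The error objective carries a small continuous confidence term
    (validation log-loss scaled well below the 1/n error quantum): the
    0/1 error cannot order masks once every borderline sample happens
    to fall on the right side, while the margin-sensitive term still
    rewards features that tighten the decision boundary. Evaluations
    are memoized per mask, since the optimizer revisits masks often.
    """

    #: log-loss weight; keeps the term below the 1/n error-rate quantum
    LOGLOSS_WEIGHT = 1e-3

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        seed: int = 0,
        tau: float = 0.5,
        folds: int = 5,
    ):
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            raise ValueError("feature selection needs both classes present")
        self.X = np.asarray(features, dtype=np.float64)
        self.y = labels
        min_class = int(np.bincount(labels).min())
        if min_class < 2:
            raise ValueError("feature selection needs >= 2 samples per class")
        skf = StratifiedKFold(
            n_splits=min(folds, min_class), shuffle=True, random_state=seed
        )
        self.folds = list(skf.split(self.X, self.y))
        self.d = features.shape[1]
        self.tau = tau
        self.seed = seed
        self._cache: dict[bytes, tuple[float, float]] = {}

    def evaluate_mask(self, mask: np.ndarray) -> tuple[float, float]:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask must keep at least one feature")
        key = np.packbits(mask).tobytes()
        if key not in self._cache:
            wrong = 0
            logloss = 0.0
            for fit_idx, val_idx in self.folds:
                clf = LogisticRegression(max_iter=500, random_state=self.seed)
                clf.fit(self.X[fit_idx][:, mask], self.y[fit_idx])
                proba = clf.predict_proba(self.X[val_idx][:, mask])
                pred = clf.classes_[proba.argmax(axis=1)]
                wrong += int((pred != self.y[val_idx]).sum())
                true_col = np.searchsorted(clf.classes_, self.y[val_idx])
                p_true = proba[np.arange(len(val_idx)), true_col]
                logloss += float(-np.log(np.clip(p_true, 1e-12, None)).sum())
            n = self.X.shape[0]
            error = wrong / n + self.LOGLOSS_WEIGHT * logloss / n
            self._cache[key] = (error, float(mask.sum()) / self.d)
        return self._cache[key]

    def __call__(self, position: np.ndarray) -> tuple[float, float]:
        return self.evaluate_mask(decode_feature_mask(position, self.tau))


def select_features_agwo(
    features: np.ndarray,
    labels: np.ndarray,
    n_wolves: int = 20,
    T: int = 40,
    capacity: int = 100,
    divisions: int = 10,
    c: float = 2.0,
    tau: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, ParetoArchive, list[dict]]:
    """Run bi-objective AGWO feature selection; return the final mask.

    The final mask is the archive member with the lowest validation
    error (tie-break: fewest selected features, then lexicographically
    smallest mask — deterministic).
    """
    problem = FeatureSelectionProblem(features, labels, seed=seed, tau=tau)
    archive, history = agwo_minimize(
        problem,
        SearchSpace.unit(features.shape[1]),
        n_wolves=n_wolves,
        T=T,
        capacity=capacity,
        divisions=divisions,
        c=c,
        seed=seed,
    )
    masks = [decode_feature_mask(m.position, tau) for m in archive.members]
    keyed = sorted(
        zip(archive.members, masks),
        key=lambda mw: (mw[0].fitness[0], mw[1].sum(), tuple(~mw[1])),
    )
    return keyed[0][1], archive, history


def decode_hyperparams(position: np.ndarray) -> tuple[float, int, float]:
    """Decode a unit-cube position into (learning rate, batch size, weight decay).

    lr is log-uniform over [1e-4, 1e-2], batch size is {32, 64, 128} by
    thirds of the second coordinate, weight decay log-uniform over
    [1e-6, 1e-2].
    """
    p = np.clip(np.asarray(position, dtype=np.float64), 0.0, 1.0)
    if p.shape != (3,):
        raise ValueError("hyperparameter position must have 3 coordinates")
    lr = 10.0 ** (-4.0 + 2.0 * p[0])
    batch = (32, 64, 128)[min(int(p[1] * 3), 2)]
    weight_decay = 10.0 ** (-6.0 + 4.0 * p[2])
    return float(lr), int(batch), float(weight_decay)


def encode_hyperparams(lr: float, batch: int, weight_decay: float) -> np.ndarray:
    """Inverse of `decode_hyperparams`; batch maps to its nearest bin center."""
    p0 = (np.log10(lr) + 4.0) / 2.0
    nearest = min((32, 64, 128), key=lambda b: abs(b - int(batch)))
    p1 = {32: 1 / 6, 64: 3 / 6, 128: 5 / 6}[nearest]
    p2 = (np.log10(weight_decay) + 6.0) / 4.0
    return np.clip(np.array([p0, p1, p2]), 0.0, 1.0)
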