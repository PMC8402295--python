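"""Phase 3: binary Whale Optimization Algorithm over a candidate feature set.

Agents ("whales") carry continuous positions, one coordinate per candidate
feature. Each iteration every agent moves either toward the current leader
(shrinking encircling), along a logarithmic spiral around the leader, or —
when its shrink-scaled coefficient is large — away toward a random agent
(exploration). Positions are squashed through a sigmoid and stochastically
thresholded into a feature mask, whose fitness trades the cross-validated
KNN error against the relative subset size:

    fitness = alpha * (1 - accuracy) + (1 - alpha) * size / dim

Lower is better. The leader is the best mask seen so far; its fitness is
non-increasing over iterations by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import Dataset
from .evaluation import stratified_folds

#: Continuous positions are clipped to this box so the sigmoid stays responsive.
POSITION_BOUND = 5.0


@dataclass(frozen=True)
class WOAConfig:
    """Search and fitness parameters.

    ``alpha`` close to 1 makes classification error dominate the fitness;
    the residual weight on subset size breaks accuracy ties toward smaller
    subsets. ``n_runs`` independent restarts are averaged by
    :func:`run_woa_repeated`.
    """

    n_agents: int = 50
    max_iter: int = 100
    spiral_b: float = 1.0
    alpha: float = 0.99
    knn_k: int = 5
    cv_folds: int = 10
    n_runs: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_agents < 1 or self.max_iter < 1 or self.n_runs < 1:
            raise ValueError("n_agents, max_iter and n_runs must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class SubsetSolution:
    """A feature mask with its fitness, accuracy and size."""

    mask: np.ndarray
    fitness: float
    accuracy: float
    size: int
    trace: tuple = field(default=(), compare=False)

    def selected(self, candidate_features) -> np.ndarray:
        """Map the mask back to dataset column indices."""
        return np.asarray(candidate_features, dtype=int)[np.flatnonzero(self.mask)]


@dataclass
class RunSummary:
    runs: list
    mean_accuracy: float
    mean_size: float


def shrink_coefficient(p: int, max_iter: int) -> float:
    """Linear shrink schedule: 2 at iteration 0 down to 0 at max_iter."""
    if not (0 <= p <= max_iter):
        raise ValueError(f"iteration {p} outside [0, {max_iter}]")
    return 2.0 - p * (2.0 / max_iter)


def update_agent(position, leader, random_agent, s, spiral_b, rng):
    """One continuous position update.

    A fair coin (t) chooses between the encircling family and the spiral.
    In the encircling family the coefficient K = 2*s*v - s (v uniform per
    coordinate) gates each coordinate: |K| < 1 moves it toward the leader,
    |K| >= 1 explores toward the supplied random agent. The spiral move
    follows a logarithmic spiral of shape ``spiral_b`` around the leader.
    """
    position = np.asarray(position, dtype=float)
    leader = np.asarray(leader, dtype=float)
    random_agent = np.asarray(random_agent, dtype=float)
    if not (position.shape == leader.shape == random_agent.shape):
        raise ValueError("position vectors must share dimension")
    if not (0 <= s <= 2):
        raise ValueError("shrink coefficient s must be in [0, 2]")
    t = rng.random()
    if t < 0.5:
        v = rng.random(position.shape)
        K = 2.0 * s * v - s
        J = 2.0 * v
        target = np.where(np.abs(K) < 1.0, leader, random_agent)
        B = np.abs(J * target - position)
        return target - K * B
    l = rng.uniform(-1.0, 1.0)
    B_prime = np.abs(leader - position)
    return B_prime * np.exp(spiral_b * l) * np.cos(2.0 * np.pi * l) + leader


def binarize(position, rng) -> np.ndarray:
    """Sigmoid transfer with stochastic thresholding; never returns an
    all-zero mask (the largest-sigmoid coordinate is forced on)."""
    position = np.asarray(position, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-position))
    mask = sig > rng.random(position.shape)
    if not mask.any():
        mask[int(np.argmax(sig))] = True
    return mask


def fitness_value(accuracy: float, size: int, dim: int, alpha: float) -> float:
    """The scalar objective: weighted error plus relative subset size."""
    return alpha * (1.0 - accuracy) + (1.0 - alpha) * (size / dim)


def _knn_cv_accuracy(X, y, folds, k) -> float:
    """Pooled stratified-CV accuracy of a k-nearest-neighbour majority vote.

    Vectorized Euclidean KNN: neighbor ties resolve to the lowest sample
    index, vote ties to the lowest class code — matching scikit-learn's
    KNeighborsClassifier conventions on continuous data.
    """
    n_classes = int(y.max()) + 1
    correct = 0
    for train, test in folds:
        diff = X[test][:, None, :] - X[train][None, :, :]
        dist = np.einsum("ijk,ijk->ij", diff, diff)
        order = np.argsort(dist, axis=1, kind="stable")[:, :k]
        votes = y[train][order]
        counts = np.apply_along_axis(np.bincount, 1, votes, minlength=n_classes)
        pred = counts.argmax(axis=1)
        correct += int((pred == y[test]).sum())
    return correct / len(y)


def fitness(d: Dataset, mask, config: WOAConfig, folds=None) -> SubsetSolution:
    """Evaluate one feature mask: KNN CV accuracy and the size penalty."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask cannot be evaluated")
    _, y = np.unique(d.labels, return_inverse=True)
    if folds is None:
        folds = stratified_folds(y, config.cv_folds, config.seed)
    acc = _knn_cv_accuracy(d.features[:, np.flatnonzero(mask)], y, folds, config.knn_k)
    size = int(mask.sum())
    return SubsetSolution(
        mask=mask,
        fitness=fitness_value(acc, size, mask.size, config.alpha),
        accuracy=acc,
        size=size,
    )


def _make_cached_fitness(d: Dataset, candidate_features, config: WOAConfig):
    """Mask -> (fitness, accuracy, size), memoized across evaluations.

    Folds are fixed once from the config seed so the map is deterministic
    and shareable across repeated runs.
    """
    candidate_features = np.asarray(candidate_features, dtype=int)
    X = d.features[:, candidate_features]
    _, y = np.unique(d.labels, return_inverse=True)
    folds = stratified_folds(y, config.cv_folds, config.seed)
    dim = candidate_features.size
    cache: dict[bytes, tuple] = {}

    def evaluate(mask: np.ndarray) -> tuple:
        key = np.packbits(mask).tobytes()
        hit = cache.get(key)
        if hit is None:
            acc = _knn_cv_accuracy(X[:, np.flatnonzero(mask)], y, folds, config.knn_k)
            size = int(mask.sum())
            hit = (fitness_value(acc, size, dim, config.alpha), acc, size)
            cache[key] = hit
        return hit

    return evaluate


def run_woa(
    d: Dataset,
    candidate_features,
    config: WOAConfig,
    rng=None,
    fitness_fn=None,
) -> SubsetSolution:
    """One seeded WOA run; returns the leader's solution with its
    per-iteration leader-fitness trace attached."""
    candidate_features = np.asarray(list(candidate_features), dtype=int)
    dim = candidate_features.size
    if dim == 0:
        raise ValueError("candidate_features is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if fitness_fn is None:
        fitness_fn = _make_cached_fitness(d, candidate_features, config)

    positions = rng.uniform(-1.0, 1.0, size=(config.n_agents, dim))
    leader_pos = None
    leader = None
    for i in range(config.n_agents):
        mask = binarize(positions[i], rng)
        fit, acc, size = fitness_fn(mask)
        if leader is None or fit < leader.fitness:
            leader = SubsetSolution(mask, fit, acc, size)
            leader_pos = positions[i].copy()
    trace = [leader.fitness]

    for p in range(config.max_iter):
        s = shrink_coefficient(p, config.max_iter)
        for i in range(config.n_agents):
            r_idx = int(rng.integers(config.n_agents))
            new = update_agent(
                positions[i], leader_pos, positions[r_idx], s, config.spiral_b, rng
            )
            positions[i] = np.clip(new, -POSITION_BOUND, POSITION_BOUND)
            mask = binarize(positions[i], rng)
            fit, acc, size = fitness_fn(mask)
            if fit < leader.fitness:
                leader = SubsetSolution(mask, fit, acc, size)
                leader_pos = positions[i].copy()
        trace.append(leader.fitness)
    return replace(leader, trace=tuple(trace))


def run_woa_repeated(
    d: Dataset, candidate_features, config: WOAConfig
) -> RunSummary:
    """``config.n_runs`` independent restarts with derived sub-seeds;
    reports every per-run solution and the means of accuracy and size."""
    candidate_features = np.asarray(list(candidate_features), dtype=int)
    fitness_fn = _make_cached_fitness(d, candidate_features, config)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    runs = [
        run_woa(
            d,
            candidate_features,
            config,
            rng=np.random.default_rng(ss),
            fitness_fn=fitness_fn,
        )
        for ss in seeds
    ]
    return RunSummary(
        runs=runs,
        mean_accuracy=float(np.mean([r.accuracy for r in runs])),
        mean_size=float(np.mean([r.size for r in runs])),
    )
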