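"""FASSO: feedback-artificial-tree / shuffled-shepherd hybrid optimizer.

The search maintains a population of Z "branches" (flat real vectors) and
minimizes an arbitrary fitness function — here the mean-squared error of a
maxout network against one-hot targets.  Each generation:

1. branches are sorted by fitness and dealt round-robin into communities,
   so every community spans the whole fitness range;
2. each branch picks a "horse" (a strictly better community member) and a
   "sheep" (a strictly worse one), falling back to itself when none exists;
3. a candidate is produced by the hybrid closed-form update, obtained by
   substituting the shepherd attraction step

       Y_temple = Y_i + delta * r o (Y_c - Y_i) + beta * r o (Y_d - Y_i)

   into the feedback-tree self-evolution operator

       Y_new = (1 - r0) * Y_i + r0 * Y_best,

   and solving for the new position.  Per coordinate, with scalar draw
   ``r0``, shared random vector ``r`` and S = delta + beta:

       Y_new = [r0 * Y_best * (1 - r S) - (delta r Y_c + beta r Y_d)(1 - r0)]
               / (r0 - r S)

   The three coefficients sum to one, so the move is an affine
   recombination of best, horse and sheep; coordinates whose denominator
   falls within ``guard_eps`` of zero get ``r`` redrawn, then fall back to
   the self-evolution operator if redraws are exhausted;
4. the candidate replaces the branch only on strict fitness improvement, so
   the best-so-far fitness is non-increasing by construction.

``beta`` decays linearly to 0 over the run (the pull toward worse members
fades) and ``delta`` grows linearly to ``delta_max`` (the pull toward
better members strengthens).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .maxout import Architecture, forward, unflatten_params


@dataclass
class Branch:
    """One candidate solution: flat position vector plus cached fitness."""

    position: np.ndarray
    fitness: float | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class FASSOConfig:
    """Search hyperparameters.

    ``pop_size``      number of branches Z;
    ``max_iter``      generations (fixed-budget termination);
    ``beta0``         initial sheep-attraction weight, decays to 0;
    ``delta0``        initial horse-attraction weight;
    ``delta_max``     final horse-attraction weight;
    ``n_communities`` round-robin communities per generation;
    ``init_range``    uniform initialization interval per coordinate;
    ``guard_eps``     denominator guard of the closed-form update;
    ``max_redraws``   redraw attempts before the per-coordinate fallback;
    ``seed``          RNG seed — the whole run is a pure function of it.
    """

    pop_size: int = 20
    max_iter: int = 200
    beta0: float = 0.5
    delta0: float = 0.5
    delta_max: float = 1.0
    n_communities: int = 4
    init_range: tuple[float, float] = (-1.0, 1.0)
    guard_eps: float = 1e-8
    max_redraws: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.pop_size < 2:
            raise ConfigurationError("pop_size must be >= 2")
        if self.max_iter < 0:
            raise ConfigurationError("max_iter must be >= 0")
        if self.beta0 < 0:
            raise ConfigurationError("beta0 must be >= 0")
        if self.delta0 > self.delta_max:
            raise ConfigurationError("delta0 must not exceed delta_max")
        if self.n_communities < 1:
            raise ConfigurationError("n_communities must be >= 1")
        if self.guard_eps <= 0:
            raise ConfigurationError("guard_eps must be > 0")
        lo, hi = self.init_range
        if not lo < hi:
            raise ConfigurationError("init_range must satisfy lo < hi")


@dataclass
class OptimizationTrace:
    """Per-generation record of the search."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    beta: list[float] = field(default_factory=list)
    delta: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "iteration": list(range(len(self.best_fitness))),
            "best_fitness": self.best_fitness,
            "mean_fitness": self.mean_fitness,
            "beta": self.beta,
            "delta": self.delta,
        }


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def initialize_population(
    n_dims: int, config: FASSOConfig, rng: np.random.Generator
) -> list[Branch]:
    """Z branches with coordinates iid uniform on ``init_range``, unevaluated."""
    if n_dims < 1:
        raise ConfigurationError("n_dims must be >= 1")
    lo, hi = config.init_range
    positions = rng.uniform(lo, hi, size=(config.pop_size, n_dims))
    return [Branch(position=p) for p in positions]


def fitness_mse(
    theta: np.ndarray, arch: Architecture, X: np.ndarray, targets: np.ndarray
) -> float:
    """Mean squared error of the network over all (sample, class) entries."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if X.shape[0] != targets.shape[0]:
        raise ConfigurationError(
            f"{X.shape[0]} samples but {targets.shape[0]} target rows"
        )
    scores = forward(unflatten_params(theta, arch), X)
    return float(np.mean((scores - targets) ** 2))


def schedule(iteration: int, config: FASSOConfig) -> tuple[float, float]:
    """Linear (beta, delta) schedule at generation ``iteration`` in [0, max_iter]."""
    if not 0 <= iteration <= config.max_iter:
        raise ConfigurationError(
            f"iteration {iteration} outside [0, {config.max_iter}]"
        )
    frac = iteration / config.max_iter if config.max_iter > 0 else 1.0
    beta = config.beta0 * (1.0 - frac)
    delta = config.delta0 + (config.delta_max - config.delta0) * frac
    return beta, delta


def partition_communities(
    ranked_indices: Sequence[int], n_communities: int
) -> list[list[int]]:
    """Deal fitness-ranked members round-robin so every community spans the range."""
    communities: list[list[int]] = [[] for _ in range(n_communities)]
    for rank, idx in enumerate(ranked_indices):
        communities[rank % n_communities].append(idx)
    return [c for c in communities if c]


def select_horse_sheep(
    member: int,
    community: Sequence[int],
    fitness: Sequence[float],
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Uniformly pick a strictly better (horse) and strictly worse (sheep)
    community member; fall back to ``member`` itself when none qualifies."""
    f_m = fitness[member]
    better = [i for i in community if fitness[i] < f_m]
    worse = [i for i in community if fitness[i] > f_m]
    horse = int(rng.choice(better)) if better else member
    sheep = int(rng.choice(worse)) if worse else member
    return horse, sheep


def fat_self_evolution(
    y_i: np.ndarray, y_best: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Feedback-tree move: one scalar draw r, convex combination toward the best."""
    r = rng.random()
    return (1.0 - r) * np.asarray(y_i) + r * np.asarray(y_best)


def ssoa_step(
    y_i: np.ndarray,
    y_c: np.ndarray,
    y_d: np.ndarray,
    beta: float,
    delta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shepherd attraction step with one shared random vector for both terms."""
    y_i = np.asarray(y_i, dtype=float)
    r = rng.random(y_i.shape)
    return y_i + delta * r * (np.asarray(y_c) - y_i) + beta * r * (np.asarray(y_d) - y_i)


def fasso_update(
    y_i: np.ndarray,
    y_c: np.ndarray,
    y_d: np.ndarray,
    y_best: np.ndarray,
    beta: float,
    delta: float,
    rng: np.random.Generator,
    guard_eps: float = 1e-8,
    max_redraws: int = 10,
) -> np.ndarray:
    """Hybrid closed-form update (see module docstring).

    Draws one scalar ``r0`` and one random vector ``r`` shared by the delta
    and beta terms.  Coordinates where ``|r0 - r*(delta+beta)| < guard_eps``
    get ``r`` redrawn up to ``max_redraws`` times; still-degenerate
    coordinates fall back to the self-evolution operator with a fresh scalar
    draw.  The output is always finite.
    """
    y_i = np.asarray(y_i, dtype=float)
    y_c = np.asarray(y_c, dtype=float)
    y_d = np.asarray(y_d, dtype=float)
    y_best = np.asarray(y_best, dtype=float)
    r0 = rng.random()
    r = rng.random(y_i.shape)
    s = delta + beta
    for _ in range(max_redraws):
        bad = np.abs(r0 - r * s) < guard_eps
        if not bad.any():
            break
        r[bad] = rng.random(int(bad.sum()))
    denom = r0 - r * s
    bad = np.abs(denom) < guard_eps
    safe_denom = np.where(bad, 1.0, denom)
    numer = r0 * y_best * (1.0 - r * s) - (delta * r * y_c + beta * r * y_d) * (1.0 - r0)
    y_new = numer / safe_denom
    if bad.any():
        rf = rng.random()
        y_new = np.where(bad, (1.0 - rf) * y_i + rf * y_best, y_new)
    return y_new


def feasibility_replace(
    branch: Branch, candidate: Branch, fitness_fn: Callable[[np.ndarray], float]
) -> Branch:
    """Greedy replacement: keep the candidate only on strict, finite improvement."""
    if branch.fitness is None:
        branch.fitness = float(fitness_fn(branch.position))
    if candidate.fitness is None:
        candidate.fitness = float(fitness_fn(candidate.position))
    if np.isfinite(candidate.fitness) and candidate.fitness < branch.fitness:
        return candidate
    return branch


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def optimize(
    fitness_fn: Callable[[np.ndarray], float],
    n_dims: int,
    config: FASSOConfig | None = None,
) -> tuple[np.ndarray, OptimizationTrace]:
    """Minimize ``fitness_fn`` over R^n_dims; returns (best position, trace).

    The run is a pure function of ``config.seed``: identical seeds give
    bit-identical results.  ``max_iter=0`` returns the best branch of the
    initial population.
    """
    config = config or FASSOConfig()
    rng = np.random.default_rng(config.seed)
    population = initialize_population(n_dims, config, rng)
    for branch in population:
        branch.fitness = float(fitness_fn(branch.position))

    def best_branch() -> Branch:
        return min(population, key=lambda b: b.fitness)

    trace = OptimizationTrace()
    best = best_branch()
    best_pos, best_fit = best.position.copy(), best.fitness

    for iteration in range(1, config.max_iter + 1):
        beta, delta = schedule(iteration, config)
        fitnesses = [b.fitness for b in population]
        ranked = sorted(range(len(population)), key=lambda i: fitnesses[i])
        communities = partition_communities(ranked, config.n_communities)
        for community in communities:
            for member in community:
                horse, sheep = select_horse_sheep(member, community, fitnesses, rng)
                candidate_pos = fasso_update(
                    population[member].position,
                    population[horse].position,
                    population[sheep].position,
                    best_pos,
                    beta,
                    delta,
                    rng,
                    guard_eps=config.guard_eps,
                    max_redraws=config.max_redraws,
                )
                candidate = Branch(position=candidate_pos)
                population[member] = feasibility_replace(
                    population[member], candidate, fitness_fn
                )
                if population[member].fitness < best_fit:
                    best_fit = population[member].fitness
                    best_pos = population[member].position.copy()
        trace.best_fitness.append(best_fit)
        trace.mean_fitness.append(float(np.mean([b.fitness for b in population])))
        trace.beta.append(beta)
        trace.delta.append(delta)

    return best_pos, trace


def optimize_network(
    arch: Architecture,
    X: np.ndarray,
    targets: np.ndarray,
    config: FASSOConfig | None = None,
) -> tuple[np.ndarray, OptimizationTrace]:
    """Train a maxout network by minimizing :func:`fitness_mse` with FASSO."""
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)

    def objective(theta: np.ndarray) -> float:
        return fitness_mse(theta, arch, X, targets)

    return optimize(objective, arch.parameter_count(), config)
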