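"""Hippopotamus optimization (HO): a bound-constrained population metaheuristic.

Each iteration runs three phases over an M-member population in an N-D box
[L_j, U_j]:

* **Phase 1 — social update.**  The first ceil(M/2) members ("males") move
  toward the best member (the leader) as
  ``x + rand * (leader - C1 * x)``; the same half then receives a
  female/calf proposal with three branches keyed on the decay scalar
  ``T = exp(-t / T_max)`` and a coin flip: toward ``leader - C2 * RG_m``
  (RG_m = mean of a random subset of the population), away from the leader,
  or a uniform restart in the box.
* **Phase 2 — defense.**  For the second half, a predator is placed uniformly
  in the box; the member responds with a Levy-flight move around the predator
  scaled by ``b / (c - d cos(2 pi g))`` and the reciprocal of its distance to
  the predator (or of ``2*dist + rand`` when the predator is no fitter).
* **Phase 3 — escape.**  Every member takes a local step inside a box that
  shrinks as 1/t: ``x + rand * (L_j/t + alpha * (U_j - L_j)/t)``.

Every proposal is clamped to the box and accepted only on a strict fitness
improvement, so the best-so-far fitness is non-increasing.  All randomness
flows from a single seeded generator: runs are exactly reproducible.

The scalars b, c, d, g of the defense step are drawn per update from
documented default ranges (b in [2,4], c in [1,1.5], d in [2,3], g in [-1,1]);
they are configurable because the originating description leaves them free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import confusion_matrix, metric_report


@dataclass
class HOConfig:
    """Settings for one optimization run.

    ``c1``/``c2`` are the social constants in [1, 2]; ``levy_exponent`` is the
    stability index beta of the heavy-tailed defense step (default 1.5).
    """

    pop_size: int
    lower: np.ndarray
    upper: np.ndarray
    max_iter: int
    c1: float = 1.5
    c2: float = 1.5
    levy_exponent: float = 1.5
    seed: int = 0
    b_range: tuple[float, float] = (2.0, 4.0)
    c_range: tuple[float, float] = (1.0, 1.5)
    d_range: tuple[float, float] = (2.0, 3.0)
    g_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.pop_size < 2:
            raise ValueError(f"population size must be >= 2, got {self.pop_size}")
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if not np.all(self.lower < self.upper):
            raise ValueError("every lower bound must be strictly below its upper bound")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if not 1.0 < self.levy_exponent <= 2.0:
            raise ValueError("levy exponent must lie in (1, 2]")

    @property
    def dim(self) -> int:
        return len(self.lower)


@dataclass
class Population:
    positions: np.ndarray  # M x N
    fitness: np.ndarray  # M
    best_position: np.ndarray
    best_fitness: float
    cur_iter: int = 0
    n_evals: int = 0

    def refresh_best(self) -> None:
        i = int(np.argmin(self.fitness))
        if self.fitness[i] < self.best_fitness:
            self.best_fitness = float(self.fitness[i])
            self.best_position = self.positions[i].copy()


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[dict] = field(default_factory=list)
    n_evals: int = 0


def _evaluate(f, x: np.ndarray, pop: Population) -> float:
    v = float(f(x))
    pop.n_evals += 1
    if not np.isfinite(v):
        raise RuntimeError(f"fitness returned a non-finite value {v} at x={x}")
    return v


def initialize(config: HOConfig, f, rng: np.random.Generator | None = None) -> Population:
    """Uniform random positions ``L_j + rand * (U_j - L_j)``, fitness evaluated."""
    rng = rng or np.random.default_rng(config.seed)
    pos = config.lower + rng.random((config.pop_size, config.dim)) * (
        config.upper - config.lower
    )
    pop = Population(pos, np.empty(config.pop_size), pos[0].copy(), np.inf)
    for i in range(config.pop_size):
        pop.fitness[i] = _evaluate(f, pos[i], pop)
    pop.refresh_best()
    return pop


def levy_step(dim: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed step via the Mantegna stable-ratio construction."""
    from math import gamma, pi, sin

    beta = exponent
    sigma_u = (
        gamma(1 + beta) * sin(pi * beta / 2) / (gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1 / beta)
    u = rng.normal(0.0, sigma_u, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return u / np.abs(v) ** (1 / beta)


def _clamp(x: np.ndarray, config: HOConfig) -> np.ndarray:
    return np.clip(x, config.lower, config.upper)


def _greedy_accept(pop: Population, i: int, proposal: np.ndarray, f, config: HOConfig) -> None:
    proposal = _clamp(proposal, config)
    fv = _evaluate(f, proposal, pop)
    if fv < pop.fitness[i]:  # strict improvement only
        pop.positions[i] = proposal
        pop.fitness[i] = fv
        pop.refresh_best()


def _draw_v(config: HOConfig, rng: np.random.Generator, dim: int) -> np.ndarray:
    """One of five random-vector scenarios, chosen uniformly per update."""
    s = rng.integers(5)
    if s == 0:
        return config.c2 * rng.random(dim) + rng.random() * rng.random(dim)
    if s == 1:
        return 2.0 * rng.random(dim) - 1.0
    if s == 2:
        return rng.random(dim)
    if s == 3:
        return config.c1 * rng.random(dim) + rng.random() * rng.random(dim)
    return rng.random(dim)


def phase1_social(pop: Population, config: HOConfig, f, rng: np.random.Generator) -> None:
    """Leader-directed male move and the T-branched female/calf move, both
    applied (greedily, in sequence) to the first half of the population."""
    half = int(np.ceil(pop.positions.shape[0] / 2))
    leader = pop.best_position
    t_decay = np.exp(-pop.cur_iter / config.max_iter)
    for i in range(half):
        male = pop.positions[i] + rng.random(config.dim) * (
            leader - config.c1 * pop.positions[i]
        )
        _greedy_accept(pop, i, male, f, config)
        # female/calf proposal
        subset = rng.choice(
            config.pop_size, size=int(rng.integers(1, config.pop_size + 1)), replace=False
        )
        rg_mean = pop.positions[subset].mean(axis=0)
        if t_decay > 0.6:
            prop = pop.positions[i] + _draw_v(config, rng, config.dim) * (
                leader - config.c2 * rg_mean
            )
        elif rng.random() > 0.5:
            prop = pop.positions[i] + _draw_v(config, rng, config.dim) * (rg_mean - leader)
        else:
            prop = config.lower + rng.random(config.dim) * (config.upper - config.lower)
        _greedy_accept(pop, i, prop, f, config)


def predator_distance(predator: np.ndarray, position: np.ndarray) -> np.ndarray:
    """Elementwise absolute distance |P_j - x_j| to the predator."""
    return np.abs(np.asarray(predator, dtype=float) - np.asarray(position, dtype=float))


def phase2_defense(
    pop: Population, config: HOConfig, f, rng: np.random.Generator, eps: float = 1e-12
) -> None:
    """Predator-response move with a Levy-flight factor for the second half."""
    half = int(np.ceil(pop.positions.shape[0] / 2))
    for i in range(half, pop.positions.shape[0]):
        predator = config.lower + rng.random(config.dim) * (config.upper - config.lower)
        f_pred = _evaluate(f, predator, pop)
        dist = predator_distance(predator, pop.positions[i])
        b = rng.uniform(*config.b_range)
        c = rng.uniform(*config.c_range)
        d = rng.uniform(*config.d_range)
        g = rng.uniform(*config.g_range)
        factor = b / (c - d * np.cos(2 * np.pi * g))
        levy = levy_step(config.dim, config.levy_exponent, rng)
        if f_pred < pop.fitness[i]:
            prop = levy * predator + factor / (dist + eps)
        else:
            prop = levy * predator + factor / (2.0 * dist + rng.random(config.dim))
        _greedy_accept(pop, i, prop, f, config)


def phase3_escape(pop: Population, config: HOConfig, f, rng: np.random.Generator) -> None:
    """Local escape inside bounds shrinking as 1/iteration, for every member."""
    t = max(pop.cur_iter, 1)
    local_lo = config.lower / t
    local_hi = config.upper / t
    for i in range(pop.positions.shape[0]):
        s = rng.integers(3)
        if s == 0:
            alpha = 2.0 * rng.random(config.dim) - 1.0
        elif s == 1:
            alpha = rng.random(config.dim)
        else:
            alpha = rng.normal(size=config.dim)
        prop = pop.positions[i] + rng.random(config.dim) * (
            local_lo + alpha * (local_hi - local_lo)
        )
        _greedy_accept(pop, i, prop, f, config)


def optimize(f, config: HOConfig, callback=None) -> OptimizeResult:
    """Run the three HO phases for ``max_iter`` iterations and track the best.

    Returns the best position/fitness and a per-iteration history of best and
    mean fitness.  Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pop = initialize(config, f, rng)
    history: list[dict] = []
    for it in range(1, config.max_iter + 1):
        pop.cur_iter = it
        phase1_social(pop, config, f, rng)
        phase2_defense(pop, config, f, rng)
        phase3_escape(pop, config, f, rng)
        history.append(
            {
                "iteration": it,
                "best_fitness": pop.best_fitness,
                "mean_fitness": float(pop.fitness.mean()),
            }
        )
        if callback is not None:
            callback(pop)
    return OptimizeResult(pop.best_position.copy(), pop.best_fitness, history, pop.n_evals)


def random_search(f, config: HOConfig, n_evals: int) -> tuple[np.ndarray, float]:
    """Uniform random search baseline with an explicit evaluation budget."""
    rng = np.random.default_rng(config.seed)
    best_x, best_f = None, np.inf
    for _ in range(n_evals):
        x = config.lower + rng.random(config.dim) * (config.upper - config.lower)
        v = float(f(x))
        if v < best_f:
            best_f, best_x = v, x
    return best_x, best_f


def precision_fitness(
    y_true, y_pred, positive_class: int | None = None, n_classes: int | None = None
) -> float:
    """Negative precision, so that maximizing precision fits the minimizer
    contract.

    With ``positive_class`` given, returns minus that class's one-vs-rest
    precision TP/(TP+FP); otherwise minus the unweighted macro precision.
    A class with no positive predictions has precision 0 by convention.
    """
    yt = np.asarray(y_true)
    k = n_classes or int(max(yt.max(initial=0), np.asarray(y_pred).max(initial=0)) + 1)
    if k == 1:
        k = 2
    cm = confusion_matrix(y_true, y_pred, k)
    report = metric_report(cm)
    if positive_class is not None:
        return -float(report.iloc[positive_class]["precision"])
    return -float(report.loc["Average", "precision"])
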