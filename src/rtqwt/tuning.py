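"""Evolutionary selection of the TQWT tuning parameters (Q, r).

Fixed tuning parameters chosen by hand rarely suit every epoch of a
non-stationary EEG recording.  Here the pair (Q, r) is selected per
signal by minimizing the decomposition mean-squared error — the
reconstruction residual of a full-depth transform — with one of three
population metaheuristics:

* particle swarm optimization (PSO), constriction form;
* artificial bee colony (ABC) with employed/onlooker/scout phases;
* cuckoo search (CS) with Mantegna Lévy-flight steps.

Because the transform is a Parseval frame, the fitness surface is flat
at floating-point round-off for every valid (Q, r); the tuner therefore
breaks ties by parsimony (smallest Q, then smallest r) among all
candidates whose fitness is within ``tie_tol`` of the minimum.  The
uniform decomposition depth used downstream is the class-balanced mean
of per-signal maximum depths, floored to an integer (``lopt``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError, NumericalError
from .tqwt import TQWTParams, decomposition_mse, lmax

__all__ = [
    "Box",
    "SearchSpace",
    "OptimizerConfig",
    "TuningResult",
    "pso_optimize",
    "abc_optimize",
    "cs_optimize",
    "optimize",
    "robust_tqwt_tune",
    "lopt",
    "abc_quality",
    "selection_probabilities",
    "levy_steps",
]

OptimizerName = Literal["pso", "abc", "cs"]


@dataclass(frozen=True)
class Box:
    """Generic box constraints for a 2-D search (used directly in tests
    and benchmarks; :class:`SearchSpace` adds the (Q, r) validity rules)."""

    low: tuple[float, float]
    high: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in zip(self.low, self.high):
            if not lo < hi:
                raise InvalidParameterError(f"bounds must satisfy low < high, got ({lo}, {hi})")

    @property
    def lower(self) -> np.ndarray:
        return np.asarray(self.low, dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.high, dtype=float)

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass(frozen=True)
class SearchSpace:
    """Box constraints for the (Q, r) search."""

    q_bounds: tuple[float, float] = (1.0, 10.0)
    r_bounds: tuple[float, float] = (3.0, 10.0)

    def __post_init__(self) -> None:
        if self.q_bounds[0] < 1:
            raise InvalidParameterError("Q lower bound must be >= 1")
        if self.r_bounds[0] <= 1:
            raise InvalidParameterError("r lower bound must be > 1")
        for low, high in (self.q_bounds, self.r_bounds):
            if not low < high:
                raise InvalidParameterError(f"bounds must satisfy low < high, got ({low}, {high})")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.q_bounds[0], self.r_bounds[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.q_bounds[1], self.r_bounds[1]])

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass(frozen=True)
class OptimizerConfig:
    """Shared and algorithm-specific optimizer settings.

    Defaults follow common practice: constriction PSO with
    ``Y = 0.729, a1 = a2 = 2.05``; ABC abandonment limit
    ``n_agents * n_dims``; CS with unit step size, Lévy stability index
    1.5 and discovery probability 0.25.
    """

    n_agents: int = 50
    n_iters: int = 200
    seed: int = 0
    # PSO
    constriction: float = 0.729
    cognitive: float = 2.05
    social: float = 2.05
    # ABC
    abandonment_limit: int | None = None
    # CS
    step_size: float = 1.0
    levy_exponent: float = 1.5
    discovery_prob: float = 0.25

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise InvalidParameterError("n_agents must be >= 2")
        if self.n_iters < 1:
            raise InvalidParameterError("n_iters must be >= 1")
        if not 0 < self.constriction <= 1:
            raise InvalidParameterError("constriction factor must lie in (0, 1]")
        if self.cognitive <= 0 or self.social <= 0:
            raise InvalidParameterError("cognitive/social factors must be positive")
        if self.step_size <= 0:
            raise InvalidParameterError("CS step size must be positive")
        if not 0 < self.levy_exponent < 2:
            raise InvalidParameterError("Levy exponent must lie in (0, 2)")
        if not 0 <= self.discovery_prob <= 1:
            raise InvalidParameterError("discovery probability must lie in [0, 1]")


@dataclass
class TuningResult:
    best_params: tuple[float, float]
    best_fitness: float
    history: np.ndarray  # best-so-far fitness, one entry per iteration (plus init)
    lmax_at_best: int | None = None
    n_evaluations: int = 0


class _Recorder:
    """Wraps a fitness function: validates finiteness, logs every evaluation."""

    def __init__(self, fn: Callable[[np.ndarray], float]):
        self.fn = fn
        self.points: list[np.ndarray] = []
        self.values: list[float] = []

    def __call__(self, x: np.ndarray) -> float:
        val = float(self.fn(x))
        if not math.isfinite(val):
            raise NumericalError(f"non-finite fitness {val!r} at point {np.asarray(x).tolist()}")
        self.points.append(np.array(x, dtype=float))
        self.values.append(val)
        return val

    @property
    def n_evaluations(self) -> int:
        return len(self.values)


def _init_population(
    space: SearchSpace, n: int, rng: np.random.Generator, initial: np.ndarray | None
) -> np.ndarray:
    pop = rng.uniform(space.lower, space.upper, size=(n, 2))
    if initial is not None:
        pop[0] = space.clip(np.asarray(initial, dtype=float))
    return pop


# ---------------------------------------------------------------------------
# particle swarm optimization
# ---------------------------------------------------------------------------


def pso_optimize(
    fitness: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: OptimizerConfig,
    initial: np.ndarray | None = None,
) -> TuningResult:
    """Constricted PSO: ``v' = Y (v + phi1 a1 (p - x) + phi2 a2 (g - x))``.

    The random factors ``phi`` are drawn per component per update.
    Positions are clipped to the search box after every move.
    """
    rng = np.random.default_rng(config.seed)
    rec = _Recorder(fitness)

    x = _init_population(space, config.n_agents, rng, initial)
    v = np.zeros_like(x)
    f = np.array([rec(xi) for xi in x])
    pbest, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest, gbest_f = x[g].copy(), float(f[g])
    history = [gbest_f]

    for _ in range(config.n_iters):
        phi1 = rng.uniform(size=x.shape)
        phi2 = rng.uniform(size=x.shape)
        v = config.constriction * (
            v
            + phi1 * config.cognitive * (pbest - x)
            + phi2 * config.social * (gbest - x)
        )
        x = space.clip(x + v)
        f = np.array([rec(xi) for xi in x])
        improved = f < pbest_f
        pbest[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        history.append(gbest_f)

    return TuningResult(
        best_params=(float(gbest[0]), float(gbest[1])),
        best_fitness=gbest_f,
        history=np.array(history),
        n_evaluations=rec.n_evaluations,
    )


# ---------------------------------------------------------------------------
# artificial bee colony
# ---------------------------------------------------------------------------


def abc_quality(values: np.ndarray) -> np.ndarray:
    """Fitness-to-quality map: ``h = 1/(1+f)`` for ``f >= 0``, ``1+|f|`` otherwise."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    pos = values >= 0
    out[pos] = 1.0 / (1.0 + values[pos])
    out[~pos] = 1.0 + np.abs(values[~pos])
    return out


def selection_probabilities(quality: np.ndarray) -> np.ndarray:
    """Roulette probabilities ``ps_i = h_i / sum(h)``."""
    quality = np.asarray(quality, dtype=float)
    total = quality.sum()
    if total <= 0:
        raise NumericalError("non-positive total quality in roulette selection")
    return quality / total


def abc_optimize(
    fitness: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: OptimizerConfig,
    initial: np.ndarray | None = None,
) -> TuningResult:
    """Artificial bee colony with employed, onlooker and scout phases.

    Candidate moves perturb one coordinate toward/away from a random
    partner: ``v = x_i + kappa (x_i - x_r)`` with ``kappa ~ U(-1, 1)``.
    A source unimproved for ``abandonment_limit`` trials is re-seeded
    uniformly (scout).
    """
    rng = np.random.default_rng(config.seed)
    rec = _Recorder(fitness)
    n, dims = config.n_agents, 2
    limit = config.abandonment_limit if config.abandonment_limit is not None else n * dims

    x = _init_population(space, n, rng, initial)
    f = np.array([rec(xi) for xi in x])
    trials = np.zeros(n, dtype=int)
    g = int(np.argmin(f))
    gbest, gbest_f = x[g].copy(), float(f[g])
    history = [gbest_f]

    def neighborhood_move(i: int) -> None:
        nonlocal gbest, gbest_f
        r = int(rng.integers(n - 1))
        r = r if r < i else r + 1
        d = int(rng.integers(dims))
        cand = x[i].copy()
        cand[d] += rng.uniform(-1.0, 1.0) * (x[i, d] - x[r, d])
        cand = space.clip(cand)
        fc = rec(cand)
        if fc < f[i]:
            x[i], f[i] = cand, fc
            trials[i] = 0
            if fc < gbest_f:
                gbest, gbest_f = cand.copy(), float(fc)
        else:
            trials[i] += 1

    for _ in range(config.n_iters):
        for i in range(n):  # employed bees
            neighborhood_move(i)
        ps = selection_probabilities(abc_quality(f))
        for _ in range(n):  # onlooker bees
            i = int(rng.choice(n, p=ps))
            neighborhood_move(i)
        exhausted = np.flatnonzero(trials > limit)
        for i in exhausted:  # scouts
            x[i] = rng.uniform(space.lower, space.upper)
            f[i] = rec(x[i])
            trials[i] = 0
            if f[i] < gbest_f:
                gbest, gbest_f = x[i].copy(), float(f[i])
        history.append(gbest_f)

    return TuningResult(
        best_params=(float(gbest[0]), float(gbest[1])),
        best_fitness=gbest_f,
        history=np.array(history),
        n_evaluations=rec.n_evaluations,
    )


# ---------------------------------------------------------------------------
# cuckoo search
# ---------------------------------------------------------------------------


def levy_steps(rng: np.random.Generator, beta: float, size: int | tuple[int, ...]) -> np.ndarray:
    """Heavy-tailed Lévy steps by Mantegna's method for stability index ``beta``."""
    if not 0 < beta < 2:
        raise InvalidParameterError("Levy stability index must lie in (0, 2)")
    sigma_u = (
        math.gamma(1.0 + beta)
        * math.sin(math.pi * beta / 2.0)
        / (math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0))
    ) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return u / np.abs(v) ** (1.0 / beta)


def cs_optimize(
    fitness: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: OptimizerConfig,
    initial: np.ndarray | None = None,
) -> TuningResult:
    """Cuckoo search: Lévy flights around the best nest plus nest discovery.

    New solutions follow ``x' = x + delta * step`` where ``step`` is a
    Mantegna Lévy draw scaled by ``0.01 (x - g)`` (the usual
    implementation of the Lévy flight, keeping moves commensurate with
    the distance to the current best ``g``).  Each iteration an expected
    ``pa`` fraction of nest components is discovered and re-built by a
    biased random walk between two randomly paired nests; replacements
    are accepted greedily, so the best nest is never lost.
    """
    rng = np.random.default_rng(config.seed)
    rec = _Recorder(fitness)
    n = config.n_agents

    x = _init_population(space, n, rng, initial)
    f = np.array([rec(xi) for xi in x])
    g = int(np.argmin(f))
    gbest, gbest_f = x[g].copy(), float(f[g])
    history = [gbest_f]

    for _ in range(config.n_iters):
        steps = levy_steps(rng, config.levy_exponent, (n, 2))
        for i in range(n):
            cand = x[i] + config.step_size * 0.01 * steps[i] * (x[i] - gbest)
            cand = space.clip(cand)
            fc = rec(cand)
            if fc < f[i]:
                x[i], f[i] = cand, fc
                if fc < gbest_f:
                    gbest, gbest_f = cand.copy(), float(fc)
        # discovery: components flagged with probability pa move along a
        # biased random walk between two random nests (greedy acceptance)
        mask = rng.uniform(size=(n, 2)) < config.discovery_prob
        walk = rng.uniform(size=(n, 1)) * (x[rng.permutation(n)] - x[rng.permutation(n)])
        for i in range(n):
            if not mask[i].any():
                continue
            cand = space.clip(x[i] + mask[i] * walk[i])
            fc = rec(cand)
            if fc < f[i]:
                x[i], f[i] = cand, fc
                if fc < gbest_f:
                    gbest, gbest_f = cand.copy(), float(fc)
        history.append(gbest_f)

    return TuningResult(
        best_params=(float(gbest[0]), float(gbest[1])),
        best_fitness=gbest_f,
        history=np.array(history),
        n_evaluations=rec.n_evaluations,
    )


_OPTIMIZERS = {"pso": pso_optimize, "abc": abc_optimize, "cs": cs_optimize}


def optimize(
    fitness: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: OptimizerConfig,
    method: OptimizerName = "cs",
    initial: np.ndarray | None = None,
) -> TuningResult:
    """Dispatch to one of the three metaheuristics by name."""
    try:
        fn = _OPTIMIZERS[method]
    except KeyError:
        raise InvalidParameterError(f"unknown optimizer {method!r}; choose from {sorted(_OPTIMIZERS)}")
    return fn(fitness, space, config, initial=initial)


# ---------------------------------------------------------------------------
# TQWT-specific tuning and the uniform decomposition depth
# ---------------------------------------------------------------------------


def robust_tqwt_tune(
    signal: Sequence[float],
    optimizer: OptimizerName = "cs",
    space: SearchSpace | None = None,
    config: OptimizerConfig | None = None,
    initial: tuple[float, float] = (1.0, 1.0),
    tie_tol: float = 1e-12,
) -> TuningResult:
    """Select (Q, r) for one signal by minimizing the reconstruction MSE.

    The nominal starting point (Q, r) = (1, 1) is clamped into the
    search box (r = 1 gives a degenerate transition band) and seeded
    into the initial population, so the returned fitness can never be
    worse than the start.  Because perfect reconstruction makes the
    fitness flat to round-off, the final answer is the parsimony
    tie-break — smallest Q, then smallest r — over every candidate
    within ``tie_tol`` of the best fitness found.
    """
    space = space or SearchSpace()
    config = config or OptimizerConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size % 2 != 0 or x.size == 0:
        raise InvalidInputError("signal must be a 1-D even-length sequence")
    if x.size < 4.0 * (space.q_bounds[1] + 1.0):
        raise InvalidInputError(
            f"signal length {x.size} shorter than 4*(Qmax+1) = {4 * (space.q_bounds[1] + 1):.0f}"
        )
    m = x.size

    def fitness(point: np.ndarray) -> float:
        q, r = float(point[0]), float(point[1])
        params = TQWTParams(q=q, r=r, levels=lmax(m, q, r))
        return decomposition_mse(x, params)

    rec = _Recorder(fitness)
    result = _OPTIMIZERS[optimizer](rec, space, config,
                                    initial=np.asarray(initial, dtype=float))
    # parsimony tie-break over everything evaluated during the run
    values = np.array(rec.values)
    fmin = float(values.min())
    near = np.flatnonzero(values <= fmin + tie_tol)
    pts = np.array([rec.points[i] for i in near])
    pick = near[np.lexsort((pts[:, 1], pts[:, 0]))[0]]
    q_best, r_best = (float(v) for v in rec.points[pick])

    result.best_params = (q_best, r_best)
    result.best_fitness = fmin
    result.lmax_at_best = lmax(m, q_best, r_best)
    result.n_evaluations = rec.n_evaluations
    return result


def lopt(lmax_by_class: Iterable[Sequence[float]]) -> int:
    """Uniform decomposition depth: class-balanced mean of Lmax, floored.

    Each class contributes the mean of its per-signal maximum depths;
    class means are averaged with equal weight and the result floored to
    an integer (depth must be a whole number of levels and must not
    exceed any class's typical maximum).
    """
    means = []
    for i, values in enumerate(lmax_by_class):
        vals = np.asarray(list(values), dtype=float)
        if vals.size == 0:
            raise InvalidInputError(f"class {i} has no Lmax values")
        means.append(vals.mean())
    if not means:
        raise InvalidInputError("at least one class of Lmax values is required")
    result = int(math.floor(float(np.mean(means))))
    return max(result, 1)
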