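"""Sinh-cosh optimizer (SCHO) and its modified variant (MSCHO).

SCHO is a mathematically inspired population metaheuristic whose move
weights are built from hyperbolic sine/cosine of uniform draws.  The run
is split into an exploration phase and an exploitation phase by the
boundary ``S = floor(T / ct)``; each phase has two candidate-update
strategies.  MSCHO augments SCHO with two mechanisms borrowed from the
artificial-bee-colony / opposition-learning literature:

* quasi-reflection-based learning (QRL): every initial position is drawn
  uniformly between the search-box midpoint and a uniform base draw,
  which spreads the population toward under-sampled half-boxes;
* trial abandonment: an agent whose fitness has not improved for
  ``trial_limit`` consecutive iterations (default 2) is discarded and
  re-seeded by the classical quasi-reflection step — a fresh uniform draw
  and its quasi-reflected counterpart are both evaluated and the better
  one survives.

All randomness flows through a single ``numpy.random.Generator`` per run;
the draw order is documented in :func:`run` so that runs are bit-identical
under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SearchSpace",
    "Agent",
    "SchoParams",
    "OptimizationResult",
    "init_population",
    "quasi_reflect",
    "phase_boundary",
    "weight_w1",
    "weight_w2",
    "weight_w3",
    "exploration_move_1",
    "exploration_move_2",
    "exploitation_move_1",
    "exploitation_move_2",
    "run",
    "run_many",
    "random_search",
    "summarize_runs",
]


class ConfigurationError(ValueError):
    """Raised for invalid search-space or parameter configuration."""


@dataclass(frozen=True)
class SearchSpace:
    """Bounded mixed continuous/integer search box.

    ``kind_per_dim`` flags dimensions that decode to integers; the
    optimizer itself always moves in the continuous box, rounding happens
    only in :meth:`decode` at objective-evaluation time so the search
    dynamics stay continuous.
    """

    lower: np.ndarray
    upper: np.ndarray
    kind_per_dim: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lb = np.asarray(self.lower, dtype=float)
        ub = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lb)
        object.__setattr__(self, "upper", ub)
        if lb.ndim != 1 or ub.shape != lb.shape:
            raise ConfigurationError("lower/upper must be 1-D vectors of equal length")
        if not np.all(lb < ub):
            raise ConfigurationError("require lower < upper elementwise")
        kinds = self.kind_per_dim or ("continuous",) * lb.size
        if len(kinds) != lb.size:
            raise ConfigurationError("kind_per_dim length mismatch")
        if any(k not in ("continuous", "integer") for k in kinds):
            raise ConfigurationError("kind_per_dim entries must be 'continuous' or 'integer'")
        object.__setattr__(self, "kind_per_dim", tuple(kinds))

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))

    def decode(self, x: np.ndarray) -> np.ndarray:
        """Round integer dimensions to the nearest in-bounds integer."""
        out = np.array(x, dtype=float)
        for j, kind in enumerate(self.kind_per_dim):
            if kind == "integer":
                out[j] = min(max(round(out[j]), math.ceil(self.lower[j])), math.floor(self.upper[j]))
        return out


@dataclass
class Agent:
    """Candidate solution: position, fitness (minimization scale), stagnation counter."""

    position: np.ndarray
    fitness: float = math.inf
    trials: int = 0

    def copy(self) -> "Agent":
        return Agent(self.position.copy(), self.fitness, self.trials)


@dataclass
class SchoParams:
    """Run parameters.

    ``ct`` controls the exploration/exploitation boundary (empirical value
    3.6); ``eps`` is the small contraction constant of the second
    exploration strategy (recommended 0.003); ``mu`` is the sinh
    sensitivity weight.  ``b1``/``b2`` decay linearly from ``b1_0``/``b2_0``
    to 0 across the run — the simplest schedule satisfying the required
    monotone decrease; both are overridable via ``b1_schedule``/
    ``b2_schedule`` (callables of (t, T)).
    """

    n_agents: int = 10
    max_iter: int = 15
    ct: float = 3.6
    mu: float = 0.5
    eps: float = 0.003
    b1_0: float = 2.0
    b2_0: float = 1.5
    b1_schedule: Callable[[int, int], float] | None = None
    b2_schedule: Callable[[int, int], float] | None = None
    trial_limit: int | None = 2
    use_qrl: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ConfigurationError("ct must be > 0")
        if self.eps < 0:
            raise ConfigurationError("eps must be >= 0")
        if self.n_agents < 2:
            raise ConfigurationError("need at least 2 agents")
        if self.trial_limit is not None and self.trial_limit < 1:
            raise ConfigurationError("trial_limit must be >= 1 or None")

    def b1(self, t: int, T: int) -> float:
        if self.b1_schedule is not None:
            return self.b1_schedule(t, T)
        return self.b1_0 * (1.0 - t / max(T, 1))

    def b2(self, t: int, T: int) -> float:
        if self.b2_schedule is not None:
            return self.b2_schedule(t, T)
        return self.b2_0 * (1.0 - t / max(T, 1))


@dataclass
class OptimizationResult:
    best: Agent
    history: np.ndarray
    evaluations: int
    seed: int | None = None
    best_indicator: float | None = None
    per_run_records: pd.DataFrame | None = None


def phase_boundary(T: int, ct: float) -> int:
    """Iteration index separating exploration (t <= S) from exploitation."""
    if ct <= 0:
        raise ConfigurationError("ct must be > 0")
    if T < 0:
        raise ConfigurationError("T must be >= 0")
    return math.floor(T / ct)


def weight_w1(r3, r4, b1: float, mu: float):
    """r3 * b1 * (cosh r4 + mu sinh r4 - 1); scalar or per-dimension vector."""
    return r3 * b1 * (np.cosh(r4) + mu * np.sinh(r4) - 1.0)


def weight_w2(r6, b2: float):
    return r6 * b2


def weight_w3(r9, r10, b1: float, mu: float):
    return r9 * b1 * (np.cosh(r10) + mu * np.sinh(r10))


def exploration_move_1(
    position: np.ndarray,
    best_position: np.ndarray,
    r1: float,
    r2: float,
    w1: float,
    space: SearchSpace,
) -> np.ndarray:
    sign = np.where(np.asarray(r2) > 0.5, 1.0, -1.0)
    return space.clip(best_position + sign * r1 * w1 * position)


def exploration_move_2(
    position: np.ndarray,
    best_position: np.ndarray,
    r5: float,
    w2: float,
    eps: float,
    space: SearchSpace,
) -> np.ndarray:
    sign = np.where(np.asarray(r5) > 0.5, 1.0, -1.0)
    return space.clip(best_position + sign * np.abs(eps * w2 * best_position - position))


def exploitation_move_1(
    position: np.ndarray,
    best_position: np.ndarray,
    r7: float,
    r8: float,
    w3: float,
    space: SearchSpace,
) -> np.ndarray:
    sign = np.where(np.asarray(r8) > 0.5, 1.0, -1.0)
    return space.clip(best_position + sign * r7 * w3 * position)


def exploitation_move_2(
    position: np.ndarray,
    best_position: np.ndarray,
    r11: float,
    r12: float,
    w2: float,
    space: SearchSpace,
) -> np.ndarray:
    # the contraction factor sinh(r12)/cosh(r12) = tanh(r12)
    return space.clip(position + r11 * np.tanh(r12) * np.abs(w2 * best_position - position))


def quasi_reflect(x: np.ndarray, space: SearchSpace, rng: np.random.Generator) -> np.ndarray:
    """Quasi-reflected counterpart: uniform draw between the box midpoint and x.

    Per dimension the draw interval is [min(m, x), max(m, x)] with
    m = (lb + ub) / 2.
    """
    x = np.asarray(x, dtype=float)
    if not space.contains(x):
        raise ValueError("quasi_reflect requires a position inside the bounds")
    mid = (space.lower + space.upper) / 2.0
    lo = np.minimum(mid, x)
    hi = np.maximum(mid, x)
    return lo + rng.random(space.dim) * (hi - lo)


def init_population(
    space: SearchSpace, n: int, rng: np.random.Generator, use_qrl: bool = False
) -> list[Agent]:
    """Uniform initial population; with QRL each draw is replaced by its quasi-reflection."""
    if n < 2:
        raise ConfigurationError("population size must be >= 2")
    agents = []
    for _ in range(n):
        pos = space.lower + rng.random(space.dim) * (space.upper - space.lower)
        if use_qrl:
            pos = quasi_reflect(pos, space, rng)
        agents.append(Agent(pos))
    return agents


def _evaluate(objective: Callable[[np.ndarray], float], pos: np.ndarray) -> float:
    val = float(objective(pos))
    if not math.isfinite(val):
        raise RuntimeError(f"objective returned non-finite value {val!r} at position {pos.tolist()}")
    return val


def run(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    params: SchoParams,
    variant: Literal["scho", "mscho"] = "mscho",
    target_fitness: float | None = None,
) -> OptimizationResult:
    """Execute one optimization run.

    Draw order per iteration, per agent (one shared Generator): the
    strategy coin (scalar), then the uniforms of the selected strategy in
    numeric order, each drawn per dimension so every coordinate moves
    independently (strategy draws: exploration-1 r1,r2,r3,r4;
    exploration-2 r5,r6; exploitation-1 r7,r8,r9,r10; exploitation-2
    r6,r11,r12).  MSCHO replacement draws (base uniform + QRL uniform per
    dimension) occur in agent order after all moves of the iteration.

    ``variant="scho"`` disables QRL initialization and trial abandonment;
    with ``use_qrl=False`` and ``trial_limit=None`` the mscho path is
    bit-identical to scho under the same seed.

    ``target_fitness`` optionally stops the run once the global best
    reaches the target (used by the accuracy-threshold stop rule of the
    framework layer); the history is padded to length ``max_iter`` with
    the final best so its length contract holds.
    """
    if variant not in ("scho", "mscho"):
        raise ConfigurationError(f"unknown variant {variant!r}")
    use_qrl = params.use_qrl if variant == "mscho" else False
    trial_limit = params.trial_limit if variant == "mscho" else None

    rng = np.random.default_rng(params.seed)
    T = params.max_iter
    S = phase_boundary(T, params.ct)

    agents = init_population(space, params.n_agents, rng, use_qrl=use_qrl)
    evaluations = 0
    for a in agents:
        a.fitness = _evaluate(objective, a.position)
        evaluations += 1

    best = min(agents, key=lambda a: a.fitness).copy()
    history = np.empty(max(T, 1), dtype=float)
    history[:] = best.fitness
    if T == 0:
        return OptimizationResult(best, history[:0], evaluations, seed=params.seed)

    for t in range(1, T + 1):
        b1 = params.b1(t, T)
        b2 = params.b2(t, T)
        explore = t <= S
        for agent in agents:
            coin = rng.random()
            if explore:
                if coin < 0.5:
                    r1, r2, r3, r4 = rng.random((4, space.dim))
                    w1 = weight_w1(r3, r4, b1, params.mu)
                    new_pos = exploration_move_1(agent.position, best.position, r1, r2, w1, space)
                else:
                    r5, r6 = rng.random((2, space.dim))
                    w2 = weight_w2(r6, b2)
                    new_pos = exploration_move_2(agent.position, best.position, r5, w2, params.eps, space)
            else:
                if coin < 0.5:
                    r7, r8, r9, r10 = rng.random((4, space.dim))
                    w3 = weight_w3(r9, r10, b1, params.mu)
                    new_pos = exploitation_move_1(agent.position, best.position, r7, r8, w3, space)
                else:
                    r6, r11, r12 = rng.random((3, space.dim))
                    w2 = weight_w2(r6, b2)
                    new_pos = exploitation_move_2(agent.position, best.position, r11, r12, w2, space)
            new_fit = _evaluate(objective, new_pos)
            evaluations += 1
            if new_fit < agent.fitness:
                agent.trials = 0
            else:
                agent.trials += 1
            agent.position = new_pos
            agent.fitness = new_fit
            if new_fit < best.fitness:
                best = agent.copy()

        if trial_limit is not None:
            for agent in agents:
                if agent.trials >= trial_limit:
                    # classical quasi-reflection step: evaluate a fresh
                    # uniform draw and its quasi-reflected counterpart,
                    # keep the better of the pair
                    base = space.lower + rng.random(space.dim) * (space.upper - space.lower)
                    reflected = quasi_reflect(base, space, rng)
                    f_base = _evaluate(objective, base)
                    f_reflected = _evaluate(objective, reflected)
                    evaluations += 2
                    if f_base <= f_reflected:
                        agent.position, agent.fitness = base, f_base
                    else:
                        agent.position, agent.fitness = reflected, f_reflected
                    agent.trials = 0
                    if agent.fitness < best.fitness:
                        best = agent.copy()

        history[t - 1] = best.fitness
        if target_fitness is not None and best.fitness <= target_fitness:
            history[t - 1 :] = best.fitness
            break

    return OptimizationResult(best, history, evaluations, seed=params.seed)


def random_search(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    n_evaluations: int,
    seed: int | None = None,
) -> OptimizationResult:
    """Uniform random-search baseline at a fixed evaluation budget."""
    rng = np.random.default_rng(seed)
    best: Agent | None = None
    history = np.empty(n_evaluations, dtype=float)
    for i in range(n_evaluations):
        pos = space.lower + rng.random(space.dim) * (space.upper - space.lower)
        fit = _evaluate(objective, pos)
        if best is None or fit < best.fitness:
            best = Agent(pos, fit)
        history[i] = best.fitness
    assert best is not None
    return OptimizationResult(best, history, n_evaluations, seed=seed)


def run_many(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    params: SchoParams,
    n_runs: int,
    base_seed: int = 0,
    variant: Literal["scho", "mscho"] = "mscho",
) -> tuple[list[OptimizationResult], pd.DataFrame]:
    """Independent repeated runs with per-run seeds ``base_seed + k``."""
    results = []
    rows = []
    for k in range(n_runs):
        p = SchoParams(**{**params.__dict__, "seed": base_seed + k})
        res = run(objective, space, p, variant=variant)
        results.append(res)
        for it, bf in enumerate(res.history, start=1):
            rows.append({"run": k, "seed": base_seed + k, "iteration": it, "best_fitness": bf})
    return results, pd.DataFrame(rows)


def summarize_runs(values: Sequence[float]) -> dict[str, float]:
    """Best/worst/mean/median/std/var summary on the minimization scale."""
    v = np.asarray(list(values), dtype=float)
    return {
        "best": float(v.min()),
        "worst": float(v.max()),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "std": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "var": float(v.var(ddof=1)) if v.size > 1 else 0.0,
    }


def write_run_records(records: pd.DataFrame, summary: dict[str, float], tsv_path, json_path) -> None:
    """Tab-separated per-iteration trace plus a JSON run summary."""
    records.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
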