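"""Simplified Swarm Optimization (SSO) for discrete hyperparameter search.

Each particle is a vector of integers. Per update, every variable is
independently replaced by the global best value, the particle's personal
best value, its current value, or a fresh uniform random value within
bounds, according to where a uniform draw rho falls in the cumulative
partition (0, Cg, Cp, Cw, 1):

    [0, Cg)  -> gbest      [Cg, Cp) -> pbest
    [Cp, Cw) -> current    [Cw, 1)  -> new random

After all variables of a particle are updated its fitness is evaluated and
the personal/global bests are replaced on strict improvement only. The
search maximizes fitness and stops after ``n_gen`` sweeps over ``n_sol``
particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SSOParams", "SSOState", "intervals_from_probabilities",
    "update_variable", "update_solution", "sso_optimize",
    "level_experiment", "random_search", "toy_fitness",
]


@dataclass(frozen=True)
class SSOParams:
    cg: float = 0.2
    cp: float = 0.6
    cw: float = 0.7
    n_gen: int = 10
    n_sol: int = 5
    n_var: int = 7
    n_run: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.cg < self.cp < self.cw < 1.0:
            raise ValueError(
                f"need 0 < Cg < Cp < Cw < 1, got ({self.cg}, {self.cp}, {self.cw})")
        for name in ("n_gen", "n_sol", "n_var", "n_run"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class SSOState:
    population: np.ndarray            # (n_sol, n_var) int
    pbest_values: np.ndarray          # (n_sol,)
    pbest_positions: np.ndarray       # (n_sol, n_var) int
    gbest: float
    G: np.ndarray                     # (n_var,) int
    iteration: int
    history: list[float] = field(default_factory=list)  # gbest after each eval


def intervals_from_probabilities(p_gbest: float, p_pbest: float,
                                 p_current: float, p_random: float
                                 ) -> tuple[float, float, float]:
    """Convert the four action probabilities into cumulative (Cg, Cp, Cw)."""
    probs = (p_gbest, p_pbest, p_current, p_random)
    if any(p <= 0 for p in probs):
        raise ValueError(f"all probabilities must be > 0, got {probs}")
    if not np.isclose(sum(probs), 1.0, atol=1e-9):
        raise ValueError(f"probabilities must sum to 1, got {sum(probs)}")
    cg = p_gbest
    cp = cg + p_pbest
    cw = cp + p_current
    return (cg, cp, cw)


def update_variable(current: int, personal_best: int, global_best: int,
                    rho: float, bounds: tuple[int, int], params: SSOParams,
                    rng: np.random.Generator) -> int:
    """Apply the four-interval step function to one variable."""
    if rho < params.cg:
        return int(global_best)
    if rho < params.cp:
        return int(personal_best)
    if rho < params.cw:
        return int(current)
    lo, hi = bounds
    return int(rng.integers(lo, hi + 1))


def update_solution(x: np.ndarray, p_i: np.ndarray, g: np.ndarray,
                    bounds, params: SSOParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Full-variable update: each of the n_var variables is updated
    independently with its own rho draw."""
    rho = rng.random(len(x))
    return np.array([
        update_variable(x[j], p_i[j], g[j], rho[j], bounds[j], params, rng)
        for j in range(len(x))
    ], dtype=int)


def _check_fitness(value, which: str) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"fitness returned a non-finite value for {which}")
    return value


def sso_optimize(fitness, bounds, params: SSOParams,
                 rng: np.random.Generator | None = None) -> SSOState:
    """Maximize ``fitness`` over the integer lattice defined by ``bounds``.

    ``bounds`` is a sequence of (lo, hi) inclusive integer ranges, one per
    variable. Personal and global bests are replaced only on strict
    improvement, so the gbest history is monotone non-decreasing. The
    global best value starts at the 0.0 floor (fitness is an accuracy);
    if no initial particle exceeds it, the first particle is recorded as G.
    """
    if len(bounds) != params.n_var:
        raise ValueError(f"bounds has {len(bounds)} entries, n_var={params.n_var}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pop = np.stack([
        np.array([rng.integers(lo, hi + 1) for lo, hi in bounds], dtype=int)
        for _ in range(params.n_sol)
    ])
    history: list[float] = []
    gbest = 0.0
    G = None
    pbest_values = np.empty(params.n_sol)
    pbest_positions = pop.copy()
    for i in range(params.n_sol):
        f = _check_fitness(fitness(tuple(pop[i])), f"initial particle {i}")
        pbest_values[i] = f
        if f > gbest:
            gbest = f
            G = pop[i].copy()
        history.append(gbest)
    if G is None:  # degenerate: nothing beat the 0.0 floor
        G = pop[0].copy()
        gbest = float(pbest_values[0])
        history = [gbest] * len(history)

    for _t in range(1, params.n_gen + 1):
        for i in range(params.n_sol):
            pop[i] = update_solution(pop[i], pbest_positions[i], G,
                                     bounds, params, rng)
            f = _check_fitness(fitness(tuple(pop[i])),
                               f"particle {i} at iteration {_t}")
            if f > pbest_values[i]:
                pbest_values[i] = f
                pbest_positions[i] = pop[i].copy()
            if f > gbest:
                gbest = f
                G = pop[i].copy()
            history.append(gbest)
    return SSOState(population=pop, pbest_values=pbest_values,
                    pbest_positions=pbest_positions, gbest=float(gbest),
                    G=G.copy(), iteration=params.n_gen, history=history)


def random_search(fitness, bounds, n_evals: int, seed: int = 0) -> float:
    """Best fitness over ``n_evals`` uniform draws; the equal-budget
    baseline SSO is compared against."""
    rng = np.random.default_rng(seed)
    best = -np.inf
    for _ in range(n_evals):
        x = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in bounds)
        best = max(best, _check_fitness(fitness(x), "random-search draw"))
    return best


def toy_fitness(target, bounds):
    """Separable toy landscape on an integer lattice with its unique
    maximizer at ``target`` (fitness 1 there), so optimizer convergence is
    checkable against exhaustive enumeration.

    The score blends an exact-match fraction with a linear distance guide,
    ``0.5 * mean(x_j == t_j) + 0.5 * (1 - mean |x_j - t_j| / width_j)``:
    the distance term gives the swarm a gradient from anywhere, the match
    term rewards locking individual variables, which is what the
    pbest/gbest copying mechanism propagates.
    """
    target = np.asarray(target, dtype=float)
    widths = np.array([hi - lo for lo, hi in bounds], dtype=float)

    def f(x):
        x = np.asarray(x, dtype=float)
        match = np.mean(x == target)
        guide = 1.0 - np.mean(np.abs(x - target) / widths)
        return float(0.5 * match + 0.5 * guide)

    return f


def level_experiment(levels: list[SSOParams], repeats: int, fitness, bounds,
                     base_seed: int = 0) -> dict:
    """Run ``repeats`` independent optimizations per parameter level and
    collect per-level best/average final gbest plus the raw groups for a
    one-way ANOVA across levels."""
    if repeats < 2:
        raise ValueError("repeats must be >= 2 for the level experiment")
    groups: list[list[float]] = []
    summary = []
    for li, level in enumerate(levels):
        finals = []
        for r in range(repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence([base_seed, li, r]))
            state = sso_optimize(fitness, bounds, level, rng=rng)
            finals.append(state.gbest)
        groups.append(finals)
        summary.append({
            "level": li + 1,
            "cg": level.cg, "cp": level.cp, "cw": level.cw,
            "best": max(finals),
            "average": float(np.mean(finals)),
        })
    return {"summary": summary, "groups": groups}
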