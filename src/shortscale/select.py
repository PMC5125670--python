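"""Item-selection strategies: stepwise CFA, ant colony, genetic algorithm.

Three ways to pick k of L items:

* ``scofa_select`` — stepwise confirmatory factor analysis: fit the one-factor
  model, drop the item with the lowest loading, refit, repeat.  A greedy
  single-criterion heuristic; fast, but blind to difficulty and validity.
* ``aco_select`` — ant colony optimization over the four-part pheromone
  objective (fit + reliability + sensitivity + validity).  Each iteration
  samples ant subsets with probability proportional to per-item pheromone,
  evaporates the trail, and deposits on the iteration-best subset.
* ``ga_select`` — genetic algorithm over inclusion masks with the
  ``I*k + (1 - R^2)`` cost: rank-proportional parent selection, uniform
  crossover, per-position mutation, steady-state replacement of the worst
  member.  ``tune_item_cost`` bisects on I until the unconstrained GA settles
  on a requested length.

All strategies are fully deterministic given (data, config, seed): every
stochastic draw goes through one seeded generator per run, and replication r
of an ACO run derives its seed as ``master + r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import cfa
from .evaluate import NonConvergentFitError, SubsetScorer
from .io import ItemResponseMatrix
from .objectives import GACostInputs, ga_cost

__all__ = [
    "ItemSubset",
    "ACOConfig",
    "GAConfig",
    "SelectionResult",
    "ScofaAbortError",
    "scofa_select",
    "aco_select",
    "ga_select",
    "tune_item_cost",
    "n_possible_short_forms",
]


def n_possible_short_forms(pool_size: int, k: int) -> int:
    """Exact size of the search space: C(pool_size, k)."""
    return math.comb(pool_size, k)


@dataclass(frozen=True)
class ItemSubset:
    """A fixed-size set of item indices, stored sorted so equality is set equality."""

    indices: tuple[int, ...]

    def __init__(self, indices: Sequence[int]) -> None:
        idx = tuple(sorted(int(i) for i in indices))
        if len(set(idx)) != len(idx):
            raise ValueError("subset indices must be distinct")
        object.__setattr__(self, "indices", idx)

    @property
    def k(self) -> int:
        return len(self.indices)

    def item_ids(self, data: ItemResponseMatrix) -> tuple[str, ...]:
        return tuple(data.item_ids[i] for i in self.indices)


@dataclass(frozen=True)
class ACOConfig:
    """Hyperparameters of the ant-colony run."""

    k: int
    n_ants: int = 30
    evaporation_rate: float = 0.1
    deposit_scale: float = 25.0
    max_iterations: int = 200
    stall_limit: int = 30
    n_replications: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if not 0.0 < self.evaporation_rate < 1.0:
            raise ValueError("evaporation_rate must be in (0, 1)")
        if self.deposit_scale <= 0:
            raise ValueError("deposit_scale must be positive")
        if self.n_ants < 1 or self.max_iterations < 1 or self.n_replications < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the genetic-algorithm run.

    ``mutation_rate=None`` means the 1/L default for a pool of L items.
    """

    item_cost_I: float = 0.05
    population_size: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float | None = None
    max_generations: int = 2000
    elitism_count: int = 1
    stall_limit: int | None = None
    seed: int = 0
    fixed_k: int | None = None

    def __post_init__(self) -> None:
        if self.item_cost_I < 0:
            raise ValueError("item_cost_I must be nonnegative")
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for name in ("crossover_rate",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.fixed_k is not None and self.fixed_k < 1:
            raise ValueError("fixed_k must be >= 1")


@dataclass
class SelectionResult:
    """Audit trail of one selection run."""

    method: str
    best_subset: ItemSubset
    best_score: float
    trajectory: list[float]
    seeds: list[int]
    evaluations: int
    config: object = None
    removal_order: list[int] | None = None
    replications: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_payload(self, data: ItemResponseMatrix | None = None) -> dict:
        payload = {
            "method": self.method,
            "best_subset": list(self.best_subset.indices),
            "best_score": self.best_score,
            "trajectory": self.trajectory,
            "seeds": self.seeds,
            "evaluations": self.evaluations,
            "replications": [
                {key: rep[key] for key in ("seed", "best_score", "best_subset")}
                for rep in self.replications
            ],
        }
        if data is not None:
            payload["item_names"] = list(self.best_subset.item_ids(data))
        if self.removal_order is not None:
            payload["removal_order"] = self.removal_order
        return payload


class ScofaAbortError(RuntimeError):
    """Stepwise selection hit a non-convergent fit; carries the partial order."""

    def __init__(self, message: str, removal_order: list[int]):
        super().__init__(message)
        self.removal_order = removal_order


# ---------------------------------------------------------------------------
# SCOFA
# ---------------------------------------------------------------------------


def scofa_select(
    data: ItemResponseMatrix,
    k: int,
    corr: cfa.CorrelationMatrix | None = None,
) -> SelectionResult:
    """Stepwise CFA: repeatedly drop the lowest-loading item until k remain.

    Ties in the lowest loading break to the lowest item position (header
    order).  The pairwise tetrachoric matrix is computed once on the full
    pool; each step refits the one-factor model on the surviving sub-matrix.
    """
    if not 3 <= k < data.n_items:
        raise ValueError("need 3 <= k < number of items")
    if corr is None:
        corr = cfa.tetrachoric_matrix(data)

    current = list(range(data.n_items))
    removal_order: list[int] = []
    trajectory: list[float] = []
    evaluations = 0
    fit = None
    while True:
        fit = cfa.fit_one_factor(corr.subset(current), data.n_persons)
        evaluations += 1
        if not fit.converged:
            raise ScofaAbortError(
                f"one-factor fit did not converge with {len(current)} items",
                removal_order,
            )
        trajectory.append(float(fit.loadings.min()))
        if len(current) == k:
            break
        drop = int(np.argmin(fit.loadings))  # argmin -> first = lowest position
        removal_order.append(current[drop])
        del current[drop]

    return SelectionResult(
        method="SCOFA",
        best_subset=ItemSubset(current),
        best_score=float(fit.loadings.min()),
        trajectory=trajectory,
        seeds=[],
        evaluations=evaluations,
        removal_order=removal_order,
    )


# ---------------------------------------------------------------------------
# ACO
# ---------------------------------------------------------------------------

_PHEROMONE_FLOOR = 1e-12


def _sample_subset(rng: np.random.Generator, tau: np.ndarray, k: int) -> tuple[int, ...]:
    """Sequential draws without replacement, probability proportional to tau."""
    weights = tau.copy()
    chosen = []
    for _ in range(k):
        p = weights / weights.sum()
        pick = int(rng.choice(len(weights), p=p))
        chosen.append(pick)
        weights[pick] = 0.0
    return tuple(sorted(chosen))


def aco_select(
    data: ItemResponseMatrix,
    covariates: pd.DataFrame | None,
    config: ACOConfig,
    scorer: SubsetScorer | None = None,
    objective_fn: Callable[[tuple[int, ...]], float] | None = None,
) -> SelectionResult:
    """Ant colony optimization of the four-part pheromone objective.

    Each replication: uniform initial pheromone; per iteration, ``n_ants``
    size-k subsets are sampled without replacement proportionally to
    pheromone and scored (a non-convergent CFA scores -inf and is logged, the
    run continues); the trail then updates by exponential smoothing at rate
    ``rho = evaporation_rate`` toward a unit exploration baseline plus the
    iteration's deposits, where every ant deposits its *advantage* — its
    score minus the iteration's worst finite score — scaled by
    ``deposit_scale / n_ants``, on its items.  Better subsets reinforce
    their items in proportion to how much they beat the iteration's worst,
    a flat objective deposits nothing and leaves the trail exactly at the
    uniform baseline, and a converged colony relaxes back toward
    exploration.  Stops at ``max_iterations`` or after ``stall_limit``
    iterations without a new best.  The overall result is the best of ``n_replications``
    independent replications (seeds ``master + 1 .. master + R``).

    ``objective_fn`` overrides the default scorer objective (used for
    algorithm-level testing and custom criteria).
    """
    if config.k >= data.n_items:
        raise ValueError("k must be smaller than the item pool")
    if objective_fn is None:
        if scorer is None:
            scorer = SubsetScorer(data, covariates)

        def objective_fn(indices: tuple[int, ...]) -> float:
            return scorer.objective(indices)

    n_items = data.n_items
    replications: list[dict] = []
    total_evals = 0
    seeds = []

    for r in range(1, config.n_replications + 1):
        seed = config.seed + r
        seeds.append(seed)
        rng = np.random.default_rng(seed)
        tau = np.ones(n_items)
        best_subset: tuple[int, ...] | None = None
        best_score = -np.inf
        trajectory: list[float] = []
        failures = 0
        evals = 0
        stall = 0
        for _ in range(config.max_iterations):
            iter_best: tuple[int, ...] | None = None
            iter_score = -np.inf
            ants: list[tuple[tuple[int, ...], float]] = []
            for _ in range(config.n_ants):
                subset = _sample_subset(rng, tau, config.k)
                evals += 1
                try:
                    score = float(objective_fn(subset))
                except NonConvergentFitError:
                    failures += 1
                    score = -np.inf
                if np.isfinite(score):
                    ants.append((subset, score))
                if score > iter_score:
                    iter_score, iter_best = score, subset
            if iter_score > best_score:
                best_score, best_subset = iter_score, iter_best
                stall = 0
            else:
                stall += 1
            trajectory.append(best_score)
            # advantage deposits: each ant reinforces its items by how much
            # it beats the iteration's worst; a flat objective deposits
            # nothing, so the trail stays at the uniform exploration baseline
            deposits = np.zeros(n_items)
            if ants:
                worst = min(score for _, score in ants)
                for subset, score in ants:
                    if score > worst:
                        deposits[list(subset)] += (score - worst) / config.n_ants
                # elitist reinforcement: the best-so-far subset deposits its
                # full advantage over the iteration's worst (zero when flat)
                if best_subset is not None and best_score > worst:
                    deposits[list(best_subset)] += best_score - worst
            rho = config.evaporation_rate
            tau = (1.0 - rho) * tau + rho * (
                1.0 + config.deposit_scale * deposits
            )
            np.clip(tau, _PHEROMONE_FLOOR, None, out=tau)
            if stall >= config.stall_limit:
                break
        total_evals += evals
        replications.append(
            {
                "seed": seed,
                "best_score": best_score,
                "best_subset": list(best_subset) if best_subset else [],
                "trajectory": trajectory,
                "evaluations": evals,
                "nonconvergent_fits": failures,
                "pheromone": tau.tolist(),
            }
        )

    winner = max(replications, key=lambda rep: rep["best_score"])
    return SelectionResult(
        method="ACO",
        best_subset=ItemSubset(winner["best_subset"]),
        best_score=float(winner["best_score"]),
        trajectory=list(winner["trajectory"]),
        seeds=seeds,
        evaluations=total_evals,
        config=config,
        replications=replications,
    )


# ---------------------------------------------------------------------------
# GA
# ---------------------------------------------------------------------------


def _repair(mask: np.ndarray, fixed_k: int | None, rng: np.random.Generator) -> None:
    """Enforce the size constraint (or at least one item) in place."""
    target = fixed_k
    if target is None:
        if mask.sum() == 0:
            mask[rng.integers(len(mask))] = True
        return
    on = np.flatnonzero(mask)
    off = np.flatnonzero(~mask)
    while len(on) > target:
        drop = on[rng.integers(len(on))]
        mask[drop] = False
        on = on[on != drop]
    while len(on) < target:
        add = off[rng.integers(len(off))]
        mask[add] = True
        off = off[off != add]
        on = np.append(on, add)


def uniform_crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-position coin flip between the two parents."""
    take_b = rng.random(len(parent_a)) < 0.5
    return np.where(take_b, parent_b, parent_a)


def mutate(mask: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each position independently with probability ``rate``."""
    flips = rng.random(len(mask)) < rate
    return mask ^ flips


def ga_select(
    data: ItemResponseMatrix,
    config: GAConfig,
    scorer: SubsetScorer | None = None,
) -> SelectionResult:
    """Genetic algorithm minimizing ``I*k + (1 - R^2)`` over inclusion masks.

    R^2 is from OLS (with intercept) of the full-pool unit-weighted total
    score on the candidate's item scores.  Parents are drawn
    rank-proportionally, offspring arise by uniform crossover (at
    ``crossover_rate``, else a clone of the first parent) and per-position
    mutation, and replace the worst population member when strictly better
    (steady-state; the best member therefore always survives).  Reported
    ``best_score`` is the *negative* cost, so higher is better and the
    trajectory is monotone non-decreasing.
    """
    if scorer is None:
        scorer = SubsetScorer(data, None)
    L = data.n_items
    rng = np.random.default_rng(config.seed)
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / L

    cost_cache: dict[bytes, float] = {}
    evaluations = 0

    def cost(mask: np.ndarray) -> float:
        nonlocal evaluations
        key = mask.tobytes()
        hit = cost_cache.get(key)
        if hit is None:
            idx = np.flatnonzero(mask)
            evaluations += 1
            hit = ga_cost(
                GACostInputs(config.item_cost_I, len(idx), scorer.r_squared(idx))
            )
            cost_cache[key] = hit
        return hit

    # initial population
    population = []
    for _ in range(config.population_size):
        if config.fixed_k is not None:
            mask = np.zeros(L, dtype=bool)
            mask[rng.choice(L, size=config.fixed_k, replace=False)] = True
        else:
            mask = rng.random(L) < 0.5
            _repair(mask, None, rng)
        population.append(mask)
    costs = np.array([cost(m) for m in population])

    best_idx = int(np.argmin(costs))
    best_mask, best_cost = population[best_idx].copy(), float(costs[best_idx])
    trajectory = [-best_cost]
    stall = 0

    for _ in range(config.max_generations):
        # rank-proportional selection: best rank gets the largest weight
        order = np.argsort(costs)  # ascending cost = descending fitness
        ranks = np.empty(len(costs))
        ranks[order] = np.arange(len(costs), 0, -1)
        p = ranks / ranks.sum()
        ia, ib = rng.choice(len(population), size=2, p=p)
        if rng.random() < config.crossover_rate:
            child = uniform_crossover(population[ia], population[ib], rng)
        else:
            child = population[ia].copy()
        child = mutate(child, mut_rate, rng)
        _repair(child, config.fixed_k, rng)
        child_cost = cost(child)

        worst = int(np.argmax(costs))
        if child_cost < costs[worst]:
            population[worst] = child
            costs[worst] = child_cost
        if child_cost < best_cost:
            best_cost, best_mask = float(child_cost), child.copy()
            stall = 0
        else:
            stall += 1
        trajectory.append(-best_cost)
        if config.stall_limit is not None and stall >= config.stall_limit:
            break

    return SelectionResult(
        method="GA",
        best_subset=ItemSubset(np.flatnonzero(best_mask)),
        best_score=-best_cost,
        trajectory=trajectory,
        seeds=[config.seed],
        evaluations=evaluations,
        config=config,
        extras={"best_cost": best_cost},
    )


def tune_item_cost(
    data: ItemResponseMatrix,
    target_k: int,
    config: GAConfig | None = None,
    bracket: tuple[float, float] = (1e-6, 1.0),
    max_bisections: int = 24,
    scorer: SubsetScorer | None = None,
) -> tuple[float, SelectionResult, bool]:
    """Bisection on the item cost I until the unconstrained GA retains target_k.

    Higher I shortens the best scale (each extra item must buy more than I of
    R^2), so k(I) is non-increasing up to search noise; the same seed is used
    at every probe to keep the map stable.  Returns ``(I, result, on_target)``;
    when no probed I yields exactly ``target_k`` within the budget, the
    closest run is returned with ``on_target=False``.
    """
    if target_k < 3:
        raise ValueError("target_k must be >= 3")
    base = config if config is not None else GAConfig()
    base = replace(base, fixed_k=None)
    if scorer is None:
        scorer = SubsetScorer(data, None)

    def probe(item_cost: float) -> SelectionResult:
        return ga_select(data, replace(base, item_cost_I=item_cost), scorer=scorer)

    lo, hi = bracket
    best: tuple[float, SelectionResult] | None = None

    def consider(item_cost: float, result: SelectionResult):
        nonlocal best
        if best is None or abs(result.best_subset.k - target_k) < abs(
            best[1].best_subset.k - target_k
        ):
            best = (item_cost, result)

    res_lo, res_hi = probe(lo), probe(hi)
    consider(lo, res_lo)
    consider(hi, res_hi)
    for _ in range(max_bisections):
        if best is not None and best[1].best_subset.k == target_k:
            break
        mid = 0.5 * (lo + hi)
        res_mid = probe(mid)
        consider(mid, res_mid)
        if res_mid.best_subset.k > target_k:
            lo = mid  # scale too long -> raise the price
        else:
            hi = mid
    item_cost, result = best
    return item_cost, result, result.best_subset.k == target_k
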