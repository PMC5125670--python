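"""Selection strategies: stepwise CFA, ant colony, genetic algorithm."""

import itertools

import numpy as np
import pytest

import shortscale.select as select_mod
from shortscale import (
    ACOConfig,
    GAConfig,
    GACostInputs,
    ItemSubset,
    SimulationConfig,
    SubsetScorer,
    aco_select,
    ga_cost,
    ga_select,
    n_possible_short_forms,
    scofa_select,
    simulate_responses,
    tune_item_cost,
)
from shortscale.select import mutate, uniform_crossover


def test_item_subset_is_canonical():
    assert ItemSubset([3, 1, 2]) == ItemSubset([2, 3, 1])
    assert ItemSubset([3, 1, 2]).indices == (1, 2, 3)
    assert ItemSubset([1, 2]).k == 2
    with pytest.raises(ValueError):
        ItemSubset([1, 1, 2])


def test_search_space_size_is_exact_binomial():
    assert n_possible_short_forms(6, 3) == 20
    assert n_possible_short_forms(10, 4) == 210


# ---------------------------------------------------------------------------
# SCOFA
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def separated_pool():
    """Six items with well-separated loadings so removal order is stable."""
    config = SimulationConfig(
        n_persons=4000,
        n_items=6,
        loading_spec=np.array([0.2, 0.35, 0.5, 0.62, 0.75, 0.88]),
        difficulty_spec=np.full(6, 0.6),
        guessing=0.0,
        seed=21,
    )
    return simulate_responses(config)


def test_scofa_retains_the_highest_loading_items(separated_pool):
    data, _, truth = separated_pool
    result = scofa_select(data, k=3)
    assert result.method == "SCOFA"
    # the three largest generating loadings are items 4, 5, 6 (0-based 3, 4, 5)
    assert result.best_subset == ItemSubset([3, 4, 5])
    # removal order follows ascending generating loadings on this fixture
    assert result.removal_order == [0, 1, 2]
    assert result.evaluations == 4  # initial fit + one refit per removal


def test_scofa_single_step_removes_argmin_loading(separated_pool):
    data, _, _ = separated_pool
    from shortscale import fit_one_factor, tetrachoric_matrix

    full = fit_one_factor(tetrachoric_matrix(data), data.n_persons)
    result = scofa_select(data, k=data.n_items - 1)
    assert result.removal_order == [int(np.argmin(full.loadings))]


def test_scofa_tie_break_prefers_lowest_position(separated_pool, monkeypatch):
    data, _, _ = separated_pool

    class FakeFit:
        converged = True
        loadings = np.array([0.5, 0.3, 0.3, 0.6, 0.7, 0.8])

        def __getattr__(self, name):  # pragma: no cover - attribute stub
            return 0.0

    calls = {"n": 0}

    def fake_fit(corr, n):
        calls["n"] += 1
        return FakeFit() if calls["n"] == 1 else _real_fit(corr, n)

    _real_fit = select_mod.cfa.fit_one_factor
    monkeypatch.setattr(select_mod.cfa, "fit_one_factor", fake_fit)
    result = scofa_select(data, k=data.n_items - 1)
    assert result.removal_order == [1]  # tie between items 1 and 2 -> lower index


def test_scofa_validates_k(separated_pool):
    data, _, _ = separated_pool
    with pytest.raises(ValueError):
        scofa_select(data, k=data.n_items)
    with pytest.raises(ValueError):
        scofa_select(data, k=2)


# ---------------------------------------------------------------------------
# ACO
# ---------------------------------------------------------------------------


def _indicator_objective(target):
    def objective(indices):
        return 4.0 if tuple(sorted(indices)) == target else 0.1

    return objective


def test_aco_finds_a_planted_optimum(pool10):
    """With one designated subset worth 4 and the rest 0.1, the colony must
    concentrate on the designated subset nearly always (C(6,3)=20 subsets)."""
    data, covariates, _ = pool10
    data6 = data.subset(range(6))
    target = (1, 3, 4)
    hits = 0
    for seed in range(100):
        result = aco_select(
            data6,
            None,
            ACOConfig(k=3, n_ants=10, max_iterations=25, stall_limit=25,
                      n_replications=1, seed=seed * 1000),
            objective_fn=_indicator_objective(target),
        )
        hits += result.best_subset.indices == target
    assert hits >= 95


def test_aco_constant_objective_keeps_pheromone_near_uniform(pool10):
    data, _, _ = pool10
    result = aco_select(
        data.subset(range(8)),
        None,
        ACOConfig(k=3, n_ants=10, max_iterations=50, stall_limit=50,
                  evaporation_rate=0.1, n_replications=1, seed=5),
        objective_fn=lambda idx: 1.0,
    )
    tau = np.array(result.replications[0]["pheromone"])
    assert tau.max() / tau.min() < 1.5


def test_aco_reports_best_of_replications(pool10, pool10_scorer):
    data, covariates, _ = pool10
    config = ACOConfig(k=4, n_ants=8, max_iterations=10, stall_limit=10,
                       n_replications=3, seed=77)
    result = aco_select(data, covariates, config, scorer=pool10_scorer)
    rep_scores = [rep["best_score"] for rep in result.replications]
    assert len(rep_scores) == 3
    assert result.best_score == max(rep_scores)
    winner = max(result.replications, key=lambda rep: rep["best_score"])
    assert list(result.best_subset.indices) == sorted(winner["best_subset"])
    assert result.seeds == [78, 79, 80]  # master + replication number


def test_aco_trajectory_monotone_and_deterministic(pool10, pool10_scorer):
    data, covariates, _ = pool10
    config = ACOConfig(k=4, n_ants=8, max_iterations=12, stall_limit=12,
                       n_replications=1, seed=3)
    a = aco_select(data, covariates, config, scorer=pool10_scorer)
    b = aco_select(data, covariates, config, scorer=pool10_scorer)
    assert a.best_subset == b.best_subset
    assert a.trajectory == b.trajectory
    traj = np.array(a.trajectory)
    assert np.all(np.diff(traj) >= 0)
    assert a.evaluations == 8 * 12


def test_aco_nonconvergent_ant_is_logged_not_fatal(pool10):
    data, _, _ = pool10
    from shortscale.evaluate import NonConvergentFitError

    target = (0, 1, 2)

    def flaky(indices):
        if tuple(sorted(indices)) != target:
            raise NonConvergentFitError(indices)
        return 1.0

    result = aco_select(
        data.subset(range(5)),
        None,
        ACOConfig(k=3, n_ants=10, max_iterations=10, stall_limit=10,
                  n_replications=1, seed=1),
        objective_fn=flaky,
    )
    assert result.best_subset.indices == target
    assert result.replications[0]["nonconvergent_fits"] > 0


# ---------------------------------------------------------------------------
# GA
# ---------------------------------------------------------------------------


def test_crossover_closure_and_zero_mutation():
    rng = np.random.default_rng(0)
    parent = np.array([True, False, True, True, False])
    child = uniform_crossover(parent, parent.copy(), rng)
    assert np.array_equal(child, parent)
    assert np.array_equal(mutate(parent, 0.0, rng), parent)


def test_ga_reaches_brute_force_optimum_single_run(pool10, pool10_scorer):
    data, _, _ = pool10
    item_cost = 0.01
    best_cost = min(
        ga_cost(GACostInputs(item_cost, 4, pool10_scorer.r_squared(list(c))))
        for c in itertools.combinations(range(10), 4)
    )
    result = ga_select(
        data,
        GAConfig(item_cost_I=item_cost, fixed_k=4, population_size=40,
                 max_generations=600, seed=2),
        scorer=pool10_scorer,
    )
    assert -result.best_score <= best_cost * 1.01 + 1e-12


def test_ga_high_item_cost_collapses_to_one_item(pool10, pool10_scorer):
    data, _, _ = pool10
    result = ga_select(
        data,
        GAConfig(item_cost_I=0.9, population_size=30, max_generations=400, seed=4),
        scorer=pool10_scorer,
    )
    assert result.best_subset.k == 1
    best_single = max(range(10), key=lambda i: pool10_scorer.r_squared([i]))
    assert result.best_subset.indices == (best_single,)


def test_ga_trajectory_monotone_and_deterministic(pool10, pool10_scorer):
    config = GAConfig(item_cost_I=0.02, fixed_k=5, population_size=20,
                      max_generations=200, seed=9)
    data, _, _ = pool10
    a = ga_select(data, config, scorer=pool10_scorer)
    b = ga_select(data, config, scorer=pool10_scorer)
    assert a.best_subset == b.best_subset
    assert a.trajectory == b.trajectory
    assert np.all(np.diff(np.array(a.trajectory)) >= 0)
    assert a.best_subset.k == 5


def test_ga_repair_prevents_empty_candidates(pool10, pool10_scorer):
    data, _, _ = pool10
    result = ga_select(
        data,
        GAConfig(item_cost_I=0.5, mutation_rate=0.9, population_size=10,
                 max_generations=100, seed=6),
        scorer=pool10_scorer,
    )
    assert result.best_subset.k >= 1


def test_ga_config_validation():
    with pytest.raises(ValueError):
        GAConfig(item_cost_I=-1)
    with pytest.raises(ValueError):
        GAConfig(population_size=2)
    with pytest.raises(ValueError):
        GAConfig(crossover_rate=1.5)


# ---------------------------------------------------------------------------
# item-cost tuning
# ---------------------------------------------------------------------------


def test_zero_item_cost_keeps_every_useful_item(pool10, pool10_scorer):
    """With I = 0 the cost is 1 - R^2, and on a pool where every item adds
    explained variance the optimum is the full pool."""
    data, _, _ = pool10
    full = pool10_scorer.r_squared(range(10))
    drop_one = max(pool10_scorer.r_squared([j for j in range(10) if j != i])
                   for i in range(10))
    assert full > drop_one  # every item genuinely adds R^2
    result = ga_select(
        data,
        GAConfig(item_cost_I=0.0, population_size=30, max_generations=800, seed=8),
        scorer=pool10_scorer,
    )
    assert result.best_subset.k == 10


def test_item_cost_monotone_trade_off(pool10, pool10_scorer):
    data, _, _ = pool10
    ks = []
    for item_cost in (0.0, 0.01, 0.05, 0.2, 0.8):
        result = ga_select(
            data,
            GAConfig(item_cost_I=item_cost, population_size=30,
                     max_generations=500, seed=10),
            scorer=pool10_scorer,
        )
        ks.append(result.best_subset.k)
    assert ks == sorted(ks, reverse=True)


def test_tune_item_cost_hits_target_length_on_large_pool():
    from shortscale import make_ppvt_like_pool

    config = make_ppvt_like_pool(31, n_persons=600)
    data, _, _ = simulate_responses(config)
    scorer = SubsetScorer(data, None)
    item_cost, result, on_target = tune_item_cost(
        data, 15,
        config=GAConfig(population_size=50, max_generations=1200, seed=31),
        scorer=scorer,
    )
    assert on_target
    assert result.best_subset.k == 15
    assert item_cost > 0
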