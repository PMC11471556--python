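"""Improved binary Human Learning Optimization: operators, fitness, convergence."""

import numpy as np
import pytest

from foliar import hlo
from foliar.hlo import (
    BinarySolution,
    FitnessContext,
    HloConfig,
    KnowledgeState,
    choose_operator,
    generate_bit,
    initialize_population,
    relearn,
    select_features,
    tune_hyperparameters,
    update_knowledge,
)
from foliar.synthetic import FeatureSpec, make_feature_matrix
from foliar.training import FeatureMatrix


@pytest.fixture(scope="module")
def tiny_ctx():
    fm, _ = make_feature_matrix(
        FeatureSpec(n=60, classes=3, informative=2, redundant=1, noise=5, effect_size=2, seed=3)
    )
    rng = np.random.default_rng(0)
    return fm, FitnessContext.from_features(fm, 0.3, rng)


class TestFitnessFormula:
    def test_direct_evaluations_match_hand_arithmetic(self):
        # cost = rho * error + sigma * fraction, rho = 0.82, sigma = 0.02
        cfg = HloConfig()
        m = 1536
        assert cfg.rho * 0.0 + cfg.sigma_feat * (m / m) == pytest.approx(0.02, abs=1e-12)
        assert cfg.rho * 0.1 + cfg.sigma_feat * (100 / m) == pytest.approx(
            0.0833020833333333, abs=1e-12
        )

    def test_perfect_accuracy_all_features_costs_sigma(self):
        # two trivially separable blobs: holdout error 0 with all columns
        x = np.vstack([np.zeros((30, 4)), np.ones((30, 4)) * 10])
        fm = FeatureMatrix(x, np.repeat([0, 1], 30))
        ctx = FitnessContext.from_features(fm, 0.3, np.random.default_rng(0))
        cfg = HloConfig(knn_k=3)
        cost = hlo.fitness(BinarySolution(np.ones(4, dtype=np.uint8)), ctx, cfg)
        assert cost == pytest.approx(0.02, abs=1e-12)

    def test_all_zero_mask_assigned_worst_error(self, tiny_ctx):
        _fm, ctx = tiny_ctx
        cost = hlo.fitness(BinarySolution(np.zeros(8, dtype=np.uint8)), ctx, HloConfig())
        assert cost == pytest.approx(0.82, abs=1e-12)

    def test_length_mismatch_rejected(self, tiny_ctx):
        _fm, ctx = tiny_ctx
        with pytest.raises(ValueError):
            hlo.fitness(BinarySolution(np.ones(3, dtype=np.uint8)), ctx, HloConfig())


class TestOperators:
    def test_rate_rule_branches(self):
        cfg = HloConfig()  # pr = 0.1, pi = 0.85
        assert choose_operator(0.05, cfg) == "REL"
        assert choose_operator(0.50, cfg) == "IL"
        assert choose_operator(0.90, cfg) == "SL"

    def test_generate_bit_copies_from_knowledge(self):
        cfg = HloConfig()
        rng = np.random.default_rng(0)
        ones = BinarySolution(np.ones(4, dtype=np.uint8), cost=0.1)
        zeros = BinarySolution(np.zeros(4, dtype=np.uint8), cost=0.2)
        state = KnowledgeState(ikd=[[ones]], skd=[zeros])
        assert generate_bit(0, 2, state, cfg, rand=0.5, rng=rng) == 1  # IL copy
        assert generate_bit(0, 2, state, cfg, rand=0.9, rng=rng) == 0  # SL copy
        assert generate_bit(0, 2, state, cfg, rand=0.05, rng=rng) in (0, 1)  # REL

    def test_population_initialization(self, tiny_ctx):
        fm, ctx = tiny_ctx
        cfg = HloConfig(seed=5)
        rng = np.random.default_rng(5)
        population, state = initialize_population(fm.width, cfg, ctx, rng)
        assert len(population) == cfg.n_solutions
        assert all(np.isin(s.bits, (0, 1)).all() for s in population)
        assert all(s.cost is not None for s in population)
        assert state.skd[0].cost == min(s.cost for s in population)
        assert all(len(entry) == 1 for entry in state.ikd)

    def test_update_knowledge_sorted_bounded_deduplicated(self):
        cfg = HloConfig(g=2, h=2)
        a = BinarySolution(np.array([1, 0], dtype=np.uint8), cost=0.3)
        b = BinarySolution(np.array([0, 1], dtype=np.uint8), cost=0.2)
        c = BinarySolution(np.array([1, 1], dtype=np.uint8), cost=0.5)
        state = KnowledgeState(ikd=[[a.copy()]], skd=[a.copy()])
        update_knowledge(0, b, state, cfg)
        assert [e.cost for e in state.skd] == [0.2, 0.3]
        update_knowledge(0, c, state, cfg)  # worse than the full database
        assert [e.cost for e in state.skd] == [0.2, 0.3]
        update_knowledge(0, b.copy(), state, cfg)  # duplicate bits: not re-inserted
        assert len(state.skd) == 2 and len(state.ikd[0]) == 2

    def test_relearn_reseeds_ikd_and_keeps_skd(self, tiny_ctx):
        fm, ctx = tiny_ctx
        cfg = HloConfig(seed=1)
        rng = np.random.default_rng(1)
        _pop, state = initialize_population(fm.width, cfg, ctx, rng)
        skd_before = [e.cost for e in state.skd]
        relearn(0, state, cfg, ctx, rng)
        assert len(state.ikd[0]) == 1
        assert state.ikd[0][0].cost is not None
        assert [e.cost for e in state.skd] == skd_before


class TestSelectFeatures:
    def test_trace_monotone_and_beats_all_ones(self, feature_fixture):
        _spec, fm, _signal = feature_fixture
        cfg = HloConfig(iterations=30, seed=0)
        mask, reduced, trace = select_features(fm, cfg)
        assert all(a >= b - 1e-15 for a, b in zip(trace, trace[1:]))
        rng = np.random.default_rng(0)
        ctx = FitnessContext.from_features(fm, cfg.holdout_ratio, rng)
        all_ones = hlo.fitness(BinarySolution(np.ones(fm.width, dtype=np.uint8)), ctx, cfg)
        assert mask.cost <= all_ones
        assert reduced.width == mask.bits.sum()

    def test_fixed_seed_reproduces_mask_and_trace(self, feature_fixture):
        _spec, fm, _signal = feature_fixture
        cfg = HloConfig(iterations=10, seed=4)
        m1, r1, t1 = select_features(fm, cfg)
        m2, r2, t2 = select_features(fm, cfg)
        assert np.array_equal(m1.bits, m2.bits)
        assert t1 == t2
        assert np.array_equal(r1.values, r2.values)

    def test_zero_iterations_returns_best_initial_member(self, feature_fixture):
        _spec, fm, _signal = feature_fixture
        cfg = HloConfig(iterations=0, seed=2)
        mask, _reduced, trace = select_features(fm, cfg)
        assert trace == []
        rng = np.random.default_rng(2)
        ctx = FitnessContext.from_features(fm, cfg.holdout_ratio, rng)
        _pop, state = initialize_population(fm.width, cfg, ctx, rng)
        assert np.array_equal(mask.bits, state.skd[0].bits)

    def test_pure_random_search_still_monotone(self, tiny_ctx):
        # pr -> 1 degenerates to random search; the global best still never worsens
        fm, _ctx = tiny_ctx
        cfg = HloConfig(pr=0.98, pi=0.99, iterations=20, seed=8)
        _mask, _reduced, trace = select_features(fm, cfg)
        assert all(a >= b - 1e-15 for a, b in zip(trace, trace[1:]))

    def test_too_few_samples_rejected(self):
        fm = FeatureMatrix(np.random.default_rng(0).random((10, 4)), np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            select_features(fm, HloConfig(knn_k=10))


class TestTuneHyperparameters:
    def test_single_point_grid(self):
        combo, cost = tune_hyperparameters(
            {"lr": [0.1]}, lambda c: c["lr"], HloConfig(iterations=2, seed=0)
        )
        assert combo == {"lr": 0.1}

    def test_finds_unique_minimum_on_2x2_grid(self):
        grid = {"lr": [0.1, 0.01], "momentum": [0.5, 0.9]}
        objective = lambda c: abs(c["lr"] - 0.01) + abs(c["momentum"] - 0.9)
        combo, cost = tune_hyperparameters(grid, objective, HloConfig(iterations=50, seed=1))
        assert combo == {"lr": 0.01, "momentum": 0.9}
        assert cost == pytest.approx(0.0)

    def test_constant_objective_returns_some_point(self):
        grid = {"lr": [0.1, 0.2], "mb": [16, 32]}
        combo, cost = tune_hyperparameters(grid, lambda c: 1.0, HloConfig(iterations=5, seed=2))
        assert combo["lr"] in grid["lr"] and combo["mb"] in grid["mb"]
        assert cost == 1.0

    def test_non_finite_objective_assigned_worst(self):
        grid = {"lr": [0.1, 0.2]}
        objective = lambda c: np.inf if c["lr"] == 0.1 else 0.5
        combo, cost = tune_hyperparameters(grid, objective, HloConfig(iterations=20, seed=3))
        assert combo == {"lr": 0.2}
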