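"""Improved binary Human Learning Optimization (HLO) wrapper feature selection.

A population of bit-string feature masks is evolved by three bit-generation
operators — random exploration (REL, a fresh uniform bit), individual
learning (IL, copying from the individual's own best solutions in its
Individual Knowledge Database), and social learning (SL, copying from the
population-wide Social Knowledge Database) — with operator rates

    bit = REL        if rand <  pr
          IL copy    if pr <= rand < pi
          SL copy    otherwise

plus a relearning operator that clears a stagnated individual's IKD.  Masks
are scored by a wrapper fitness on a fixed holdout split:

    COST = rho * ERROR + sigma * (selected / total features)
    ERROR = 1 - accuracy of a k-nearest-neighbor classifier on the holdout

with rho = 0.82, sigma = 0.02, k = 10 and a 0.3 holdout ratio.  The final
mask is refined from the SKD with a per-bit Beta(1, 1) posterior weighted by
SKD rank, falling back to the best SKD member if the thresholded mask scores
worse.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .training import FeatureMatrix

__all__ = [
    "HloConfig",
    "BinarySolution",
    "KnowledgeState",
    "FitnessContext",
    "initialize_population",
    "fitness",
    "choose_operator",
    "generate_bit",
    "update_knowledge",
    "relearn",
    "select_features",
    "tune_hyperparameters",
]


@dataclass
class HloConfig:
    n_solutions: int = 10
    iterations: int = 100
    pi: float = 0.85
    pr: float = 0.1
    knn_k: int = 10
    holdout_ratio: float = 0.3
    rho: float = 0.82
    sigma_feat: float = 0.02
    g: int = 3  # IKD size
    h: int = 3  # SKD size
    stagnation_window: int = 10
    seed: int = 0
    leakage_safe: bool = False  # document-recommended: select on training features

    def __post_init__(self) -> None:
        if not 0.0 < self.pr < self.pi < 1.0:
            raise ValueError("require 0 < pr < pi < 1")
        if not 0.0 < self.holdout_ratio < 1.0:
            raise ValueError("holdout_ratio must be in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.rho < 0 or self.sigma_feat < 0:
            raise ValueError("rho and sigma_feat must be >= 0")


@dataclass
class BinarySolution:
    bits: np.ndarray
    cost: float | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1 or self.bits.size < 1:
            raise ValueError("bits must be a non-empty 1-D vector")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")

    def copy(self) -> "BinarySolution":
        return BinarySolution(self.bits.copy(), self.cost)


@dataclass
class KnowledgeState:
    """Per-individual IKDs (<= g best personal solutions) and the global SKD (<= h)."""

    ikd: list[list[BinarySolution]]
    skd: list[BinarySolution]


@dataclass
class FitnessContext:
    """Z-scored features with a fixed train/holdout split and the KNN wrapper."""

    features: FeatureMatrix
    train_idx: np.ndarray
    holdout_idx: np.ndarray
    _xtr: np.ndarray = field(init=False, repr=False)
    _xho: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.holdout_idx).size:
            raise ValueError("train and holdout indices must be disjoint")
        x = self.features.values
        mu = x[self.train_idx].mean(axis=0)
        sd = x[self.train_idx].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        self._xtr = (x[self.train_idx] - mu) / sd
        self._xho = (x[self.holdout_idx] - mu) / sd

    @classmethod
    def from_features(
        cls, features: FeatureMatrix, holdout_ratio: float, rng: np.random.Generator
    ) -> "FitnessContext":
        n = features.n
        order = rng.permutation(n)
        n_ho = max(1, int(round(holdout_ratio * n)))
        return cls(features, np.sort(order[n_ho:]), np.sort(order[:n_ho]))

    def error(self, mask: np.ndarray, k: int) -> float:
        cols = np.flatnonzero(mask)
        if cols.size == 0:
            return 1.0
        k_eff = min(k, len(self.train_idx))
        knn = KNeighborsClassifier(n_neighbors=k_eff, metric="euclidean")
        knn.fit(self._xtr[:, cols], self.features.labels[self.train_idx])
        acc = knn.score(self._xho[:, cols], self.features.labels[self.holdout_idx])
        return 1.0 - float(acc)


def fitness(
    solution: BinarySolution, ctx: FitnessContext, cfg: HloConfig | None = None
) -> float:
    """COST = rho * ERROR + sigma * (selected / m); an all-zero mask scores rho."""
    cfg = cfg or HloConfig()
    m = solution.bits.size
    if m != ctx.features.width:
        raise ValueError("solution length must equal the feature count")
    err = ctx.error(solution.bits, cfg.knn_k)
    frac = 0.0 if solution.bits.sum() == 0 else solution.bits.sum() / m
    cost = cfg.rho * err + cfg.sigma_feat * frac
    solution.cost = float(cost)
    return solution.cost


def _insert_sorted(
    entries: list[BinarySolution], candidate: BinarySolution, max_size: int
) -> None:
    """Keep ``entries`` ascending by cost, <= max_size, without bit-duplicates."""
    key = candidate.bits.tobytes()
    if any(e.bits.tobytes() == key for e in entries):
        return
    if len(entries) >= max_size and candidate.cost >= entries[-1].cost:
        return
    entries.append(candidate.copy())
    entries.sort(key=lambda e: e.cost)
    del entries[max_size:]


def initialize_population(
    m: int,
    cfg: HloConfig,
    ctx: FitnessContext,
    rng: np.random.Generator,
) -> tuple[list[BinarySolution], KnowledgeState]:
    """Uniform random bit-strings, all evaluated; IKDs seeded per-individual, SKD global."""
    if m < 1:
        raise ValueError("m must be >= 1")
    population = [
        BinarySolution(rng.integers(0, 2, m, dtype=np.uint8)) for _ in range(cfg.n_solutions)
    ]
    for sol in population:
        fitness(sol, ctx, cfg)
    ikd = [[sol.copy()] for sol in population]
    skd: list[BinarySolution] = []
    for sol in sorted(population, key=lambda s: s.cost):
        _insert_sorted(skd, sol, cfg.h)
    return population, KnowledgeState(ikd=ikd, skd=skd)


def choose_operator(rand: float, cfg: HloConfig) -> str:
    """Operator selected for one bit draw: REL, IL or SL."""
    if not 0.0 <= rand < 1.0:
        raise ValueError("rand must be in [0, 1)")
    if rand < cfg.pr:
        return "REL"
    if rand < cfg.pi:
        return "IL"
    return "SL"


def generate_bit(
    i: int,
    j: int,
    state: KnowledgeState,
    cfg: HloConfig,
    rand: float,
    rng: np.random.Generator,
) -> int:
    """One bit of a new candidate for individual ``i`` via the rate rule."""
    op = choose_operator(rand, cfg)
    if op == "REL":
        return int(rng.integers(0, 2))
    if op == "IL":
        entries = state.ikd[i]
        if not entries:
            raise RuntimeError("empty IKD")
        return int(entries[rng.integers(len(entries))].bits[j])
    if not state.skd:
        raise RuntimeError("empty SKD")
    return int(state.skd[rng.integers(len(state.skd))].bits[j])


def _generate_candidate(
    i: int, m: int, state: KnowledgeState, cfg: HloConfig, rng: np.random.Generator
) -> BinarySolution:
    """Vectorized per-bit application of the REL/IL/SL rate rule."""
    r = rng.random(m)
    bits = np.empty(m, dtype=np.uint8)
    rel = r < cfg.pr
    il = (r >= cfg.pr) & (r < cfg.pi)
    sl = r >= cfg.pi
    bits[rel] = rng.integers(0, 2, rel.sum(), dtype=np.uint8)
    ikd = state.ikd[i]
    picks = rng.integers(0, len(ikd), il.sum())
    ikd_bits = np.stack([e.bits for e in ikd])
    bits[il] = ikd_bits[picks, np.flatnonzero(il)]
    picks = rng.integers(0, len(state.skd), sl.sum())
    skd_bits = np.stack([e.bits for e in state.skd])
    bits[sl] = skd_bits[picks, np.flatnonzero(sl)]
    return BinarySolution(bits)


def update_knowledge(
    individual: int,
    candidate: BinarySolution,
    state: KnowledgeState,
    cfg: HloConfig,
) -> KnowledgeState:
    """Insert an evaluated candidate into the individual's IKD and the SKD."""
    if candidate.cost is None:
        raise ValueError("candidate must be evaluated")
    _insert_sorted(state.ikd[individual], candidate, cfg.g)
    _insert_sorted(state.skd, candidate, cfg.h)
    return state


def relearn(
    individual: int,
    state: KnowledgeState,
    cfg: HloConfig,
    ctx: FitnessContext,
    rng: np.random.Generator,
) -> KnowledgeState:
    """Clear a stagnated individual's IKD, re-seeding with a fresh evaluated random solution."""
    m = ctx.features.width
    fresh = BinarySolution(rng.integers(0, 2, m, dtype=np.uint8))
    fitness(fresh, ctx, cfg)
    state.ikd[individual] = [fresh]
    return state


def _bayesian_refinement(
    state: KnowledgeState, ctx: FitnessContext, cfg: HloConfig
) -> BinarySolution:
    """Per-bit Beta(1, 1) posterior over inclusion from rank-weighted SKD members.

    The thresholded posterior-mean mask is kept only if it scores at least as
    well as the best SKD member.
    """
    h = len(state.skd)
    weights = np.arange(h, 0, -1, dtype=float)  # best member weighs most
    bits = np.stack([e.bits for e in state.skd]).astype(float)
    alpha = 1.0 + weights @ bits
    beta = 1.0 + weights @ (1.0 - bits)
    mask = (alpha / (alpha + beta) > 0.5).astype(np.uint8)
    candidate = BinarySolution(mask)
    fitness(candidate, ctx, cfg)
    best = state.skd[0]
    return candidate if candidate.cost <= best.cost else best.copy()


def select_features(
    features: FeatureMatrix, cfg: HloConfig | None = None
) -> tuple[BinarySolution, FeatureMatrix, list[float]]:
    """Run the full improved-HLO loop over a feature matrix.

    Returns the final mask, the reduced matrix (selected columns of the
    original values) and the per-generation global-best cost trace, which is
    non-increasing by construction.  Fixed ``cfg.seed`` reproduces the run
    exactly.
    """
    cfg = cfg or HloConfig()
    m = features.width
    if m < 1:
        raise ValueError("feature matrix has no columns")
    if features.n < 2 * cfg.knn_k:
        raise ValueError("need at least 2 * knn_k samples")
    rng = np.random.default_rng(cfg.seed)
    ctx = FitnessContext.from_features(features, cfg.holdout_ratio, rng)
    population, state = initialize_population(m, cfg, ctx, rng)

    best_cost = [e[0].cost for e in state.ikd]
    stagnation = [0] * cfg.n_solutions
    trace: list[float] = []
    for _gen in range(cfg.iterations):
        for i in range(cfg.n_solutions):
            candidate = _generate_candidate(i, m, state, cfg, rng)
            fitness(candidate, ctx, cfg)
            update_knowledge(i, candidate, state, cfg)
            if state.ikd[i][0].cost < best_cost[i] - 1e-15:
                best_cost[i] = state.ikd[i][0].cost
                stagnation[i] = 0
            else:
                stagnation[i] += 1
                if stagnation[i] >= cfg.stagnation_window:
                    relearn(i, state, cfg, ctx, rng)
                    best_cost[i] = state.ikd[i][0].cost
                    stagnation[i] = 0
        trace.append(state.skd[0].cost)

    if cfg.iterations == 0:
        final = state.skd[0].copy()
    else:
        final = _bayesian_refinement(state, ctx, cfg)
    reduced = features.select(final.bits.astype(bool))
    return final, reduced, trace


def tune_hyperparameters(
    grid: dict[str, list],
    objective,
    cfg: HloConfig | None = None,
) -> tuple[dict, float]:
    """Discrete hyperparameter search with the HLO machinery.

    Each grid axis index is binary-encoded into the solution bit-string
    (decoded modulo the axis length); the wrapper cost is the bare objective
    (non-finite objectives are assigned a worst cost).  Returns the best
    visited combination and its objective value.
    """
    cfg = cfg or HloConfig()
    axes = list(grid.items())
    if any(len(v) == 0 for _k, v in axes):
        raise ValueError("every grid axis must be non-empty")
    bit_widths = [max(1, int(np.ceil(np.log2(len(v))))) for _k, v in axes]
    m = sum(bit_widths)
    rng = np.random.default_rng(cfg.seed)

    def decode(bits: np.ndarray) -> dict:
        combo = {}
        pos = 0
        for (key, values), width in zip(axes, bit_widths):
            idx = 0
            for b in bits[pos : pos + width]:
                idx = (idx << 1) | int(b)
            combo[key] = values[idx % len(values)]
            pos += width
        return combo

    cache: dict[bytes, float] = {}
    worst = 1e18

    def evaluate(sol: BinarySolution) -> float:
        key = sol.bits.tobytes()
        if key not in cache:
            val = objective(decode(sol.bits))
            cache[key] = float(val) if np.isfinite(val) else worst
        sol.cost = cache[key]
        return sol.cost

    population = [
        BinarySolution(rng.integers(0, 2, m, dtype=np.uint8)) for _ in range(cfg.n_solutions)
    ]
    for sol in population:
        evaluate(sol)
    state = KnowledgeState(
        ikd=[[s.copy()] for s in population],
        skd=[],
    )
    for sol in sorted(population, key=lambda s: s.cost):
        _insert_sorted(state.skd, sol, cfg.h)
    best_cost = [e[0].cost for e in state.ikd]
    stagnation = [0] * cfg.n_solutions
    for _gen in range(cfg.iterations):
        for i in range(cfg.n_solutions):
            candidate = _generate_candidate(i, m, state, cfg, rng)
            evaluate(candidate)
            update_knowledge(i, candidate, state, cfg)
            if state.ikd[i][0].cost < best_cost[i] - 1e-15:
                best_cost[i] = state.ikd[i][0].cost
                stagnation[i] = 0
            else:
                stagnation[i] += 1
                if stagnation[i] >= cfg.stagnation_window:
                    fresh = BinarySolution(rng.integers(0, 2, m, dtype=np.uint8))
                    evaluate(fresh)
                    state.ikd[i] = [fresh]
                    best_cost[i] = fresh.cost
                    stagnation[i] = 0
    best = state.skd[0]
    return decode(best.bits), best.cost
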