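"""Descriptor pruning and subset search.

Two stages, mirroring standard QSAR practice:

* **Objective feature selection (OFS)** — unsupervised pruning: drop
  near-constant columns (modal value in >= 90% of molecules) and break
  highly intercorrelated pairs (|Pearson R| > 0.90), keeping the member
  more correlated with the response.

* **Subjective feature selection** — a genetic algorithm over fixed-size
  descriptor subsets, each scored by the leave-one-out cross-validated
  coefficient of determination (Q2_LOO) of the corresponding multilinear
  regression.  Tournament selection, uniform crossover with repair back to
  subset size k, swap mutation, elitism; deterministic for a fixed seed.

The optimal subset size is read off a Q2_LOO-vs-k scan: successive size
increments stop paying once the gain drops below a small threshold (the
"elevation point" of the scan curve).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .validation import q2_loo_fitness


class AllPrunedError(ValueError):
    """Objective feature selection removed every column."""


@dataclass(frozen=True)
class OFSConfig:
    near_constant_fraction: float = 0.90
    intercorrelation_cutoff: float = 0.90

    def __post_init__(self) -> None:
        for v in (self.near_constant_fraction, self.intercorrelation_cutoff):
            if not 0 < v <= 1:
                raise ValueError("OFS thresholds must be in (0, 1]")


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    generations: int = 300
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    model_size_k: int = 6
    seed: int = 0
    elitism: int = 1
    tournament_size: int = 3
    #: stop early after this many generations without improvement (None = never)
    stall_generations: int | None = 50

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.model_size_k < 1 or self.population_size < 2:
            raise ValueError("need model_size_k >= 1 and population_size >= 2")


def objective_feature_selection(table: pd.DataFrame, y, cfg: OFSConfig = OFSConfig()
                                ) -> pd.DataFrame:
    """Drop near-constant columns, then break intercorrelated pairs.

    Pair breaking is greedy on the largest |R| first; the column with the
    lower |correlation with y| is dropped (ties keep the first by name).
    """
    y = np.asarray(y, dtype=float)
    if len(table) != len(y):
        raise ValueError("table rows and response length differ")
    keep = []
    for col in table.columns:
        modal_frac = table[col].value_counts(normalize=True).iloc[0]
        if modal_frac < cfg.near_constant_fraction:
            keep.append(col)
    if not keep:
        raise AllPrunedError("all columns near constant")

    sub = table[keep]
    corr = sub.corr().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(np.abs(corr))
    with np.errstate(invalid="ignore"):
        ycorr = np.nan_to_num(np.abs(np.array(
            [np.corrcoef(sub[c], y)[0, 1] for c in keep])))
    alive = np.ones(len(keep), dtype=bool)
    while True:
        masked = np.where(np.outer(alive, alive), corr, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= cfg.intercorrelation_cutoff:
            break
        first, second = min(i, j), max(i, j)
        if ycorr[first] >= ycorr[second]:     # ties keep the first by position
            alive[second] = False
        else:
            alive[first] = False
    kept = [c for c, a in zip(keep, alive) if a]
    if not kept:
        raise AllPrunedError("intercorrelation pruning removed every column")
    return table[kept]


# ---------------------------------------------------------------------------
# GA over fixed-size subsets


def _fitness_factory(table: pd.DataFrame, y):
    Xm = table.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    cache: dict[frozenset, float] = {}

    def fitness(subset: tuple[int, ...]) -> float:
        key = frozenset(subset)
        if key not in cache:
            cache[key] = q2_loo_fitness(Xm[:, list(subset)], y)
        return cache[key]

    return fitness, cache


def _random_subset(rng, p: int, k: int) -> tuple[int, ...]:
    return tuple(sorted(rng.choice(p, size=k, replace=False)))


def _crossover(rng, a: tuple, b: tuple, k: int) -> tuple[int, ...]:
    """Uniform crossover with repair: keep the intersection, fill to size k
    from the symmetric difference in random order."""
    common = set(a) & set(b)
    pool = list(set(a) ^ set(b))
    rng.shuffle(pool)
    child = set(common)
    for g in pool:
        if len(child) >= k:
            break
        child.add(g)
    return tuple(sorted(child))


def _mutate(rng, subset: tuple, p: int) -> tuple[int, ...]:
    """Swap one member for a random non-member."""
    out = int(rng.choice(len(subset)))
    members = set(subset)
    candidates = [g for g in range(p) if g not in members]
    if not candidates:
        return subset
    members.discard(subset[out])
    members.add(int(rng.choice(candidates)))
    return tuple(sorted(members))


def ga_mlr_search(table: pd.DataFrame, y, cfg: GAConfig,
                  return_history: bool = False):
    """Evolve fixed-size descriptor subsets maximising Q2_LOO.

    Returns the deduplicated evaluated subsets as a list of
    ``(descriptor-name tuple, Q2_LOO)`` sorted by fitness descending
    (ties broken by name for determinism).  With ``return_history`` the
    per-generation best fitness trace is returned as well.
    """
    p = table.shape[1]
    k = cfg.model_size_k
    if p < k:
        raise ValueError(f"need at least k={k} columns, have {p}")
    rng = np.random.default_rng(cfg.seed)
    fitness, cache = _fitness_factory(table, y)

    pop = [_random_subset(rng, p, k) for _ in range(cfg.population_size)]
    history = []
    best, best_fit = None, -np.inf
    stall = 0
    for _ in range(cfg.generations):
        scored = sorted(pop, key=lambda s: (fitness(s), s), reverse=True)
        gen_best = scored[0]
        if fitness(gen_best) > best_fit:
            best, best_fit = gen_best, fitness(gen_best)
            stall = 0
        else:
            stall += 1
        history.append(best_fit)
        if cfg.stall_generations is not None and stall >= cfg.stall_generations:
            break

        nxt = list(scored[:cfg.elitism])
        while len(nxt) < cfg.population_size:
            contenders = [pop[i] for i in rng.integers(0, len(pop), cfg.tournament_size)]
            pa = max(contenders, key=lambda s: (fitness(s), s))
            contenders = [pop[i] for i in rng.integers(0, len(pop), cfg.tournament_size)]
            pb = max(contenders, key=lambda s: (fitness(s), s))
            child = _crossover(rng, pa, pb, k) if rng.random() < cfg.crossover_prob else pa
            if rng.random() < cfg.mutation_prob:
                child = _mutate(rng, child, p)
            nxt.append(child)
        pop = nxt

    names = list(table.columns)
    ranked = sorted(
        ((tuple(names[i] for i in subset), fit) for subset, fit in
         ((tuple(sorted(key)), val) for key, val in cache.items())),
        key=lambda t: (-t[1], t[0]),
    )
    return (ranked, history) if return_history else ranked


def exhaustive_search(table: pd.DataFrame, y, k: int) -> list[tuple[tuple, float]]:
    """Brute-force enumeration of all size-k subsets (oracle for small pools)."""
    fitness, _ = _fitness_factory(table, y)
    names = list(table.columns)
    out = [(tuple(names[i] for i in combo), fitness(combo))
           for combo in itertools.combinations(range(table.shape[1]), k)]
    return sorted(out, key=lambda t: (-t[1], t[0]))


def q2_vs_k_scan(table: pd.DataFrame, y, k_max: int, cfg: GAConfig,
                 exhaustive_limit: int = 2000) -> list[tuple[int, float]]:
    """Best-found Q2_LOO for each subset size k = 1..k_max.

    Small search spaces (<= ``exhaustive_limit`` subsets) are enumerated
    exactly; larger ones use the GA with a per-k derived seed.
    """
    if k_max >= table.shape[1]:
        raise ValueError("k_max must be below the number of columns")
    curve = []
    for k in range(1, k_max + 1):
        if math.comb(table.shape[1], k) <= exhaustive_limit:
            best = exhaustive_search(table, y, k)[0][1]
        else:
            cfg_k = replace(cfg, model_size_k=k, seed=cfg.seed + k)
            best = ga_mlr_search(table, y, cfg_k)[0][1]
        curve.append((k, float(best)))
    return curve


def elevation_point(curve: list[tuple[int, float]], min_gain: float = 0.01) -> int:
    """Optimal subset size from a Q2-vs-k scan.

    The first size whose gain over the previous one falls below
    ``min_gain`` marks the elevation point; the size just before it is
    optimal.  If the curve never flattens, the largest scanned size wins.
    """
    for (k_prev, q_prev), (k, q) in zip(curve, curve[1:]):
        if q - q_prev < min_gain:
            return k_prev
    return curve[-1][0]
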