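"""Wrapper wavelength selection with seven metaheuristics.

Each selector searches over binary wavelength-inclusion masks; the fitness
of a mask is the validation RMSE of an SVR (linear kernel by default)
refitted on the masked training columns of one fixed split.  All seven
algorithms share:

* a memoizing fitness evaluator (a mask is never refitted twice),
* cardinality repair -- an overfull mask keeps the ``k_max`` wavelengths
  with the best single-wavelength fitness ranks, an empty mask activates
  one wavelength at random,
* an elitist archive, so the best-so-far trace is non-increasing by
  construction,
* one seeded generator per run; multi-run statistics use seeds derived by
  fixed offsets.

An exhaustive enumerator over all subsets of bounded cardinality serves as
the ground-truth optimum on small candidate pools.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from . import models as _models
from .evaluation import SplitAssignment

__all__ = [
    "OptimizerConfig",
    "SelectionResult",
    "FitnessEvaluator",
    "evaluate_subset_fitness",
    "run_selector",
    "exhaustive_search",
    "summarize_selectors",
    "ALGORITHMS",
]

# Per-algorithm default hyperparameters (population sizes, rates, phase
# constants).  The shared iteration budget defaults to 30; the smaller
# per-algorithm episode/generation counts listed here are reachable through
# OptimizerConfig.iterations.
ALGORITHM_DEFAULTS: dict[str, dict] = {
    "lca": {"teams": 8, "seasons": 10, "match_time": 2, "imitation_rate": 0.3},
    "ga": {"population": 120, "generations": 10, "crossover_rate": 0.30, "mutation_rate": 0.30},
    "pso": {"particles": 40, "episodes": 10, "p_bests": 8},
    "aco": {"ants": 40, "episodes": 10, "evaporation": 0.04},
    "ica": {
        "countries": 40,
        "imperialists": 11,
        "assimilation_rate": 0.9,
        "revolution_rate": 0.1,
    },
    "la": {"generations": 10, "tries": 40, "learning_rate": 0.1},
    "hts": {"molecules": 15, "iterations": 10, "cdf": 2.0, "cof": 10.0, "rdf": 2.0},
}
DEFAULT_ITERATIONS = 30
DEFAULT_K_MAX = 15


@dataclass
class OptimizerConfig:
    """One selector run configuration.

    ``params`` overrides the per-algorithm defaults in
    :data:`ALGORITHM_DEFAULTS`; ``iterations`` is the shared budget (30 by
    default), and ``n_runs`` independent restarts are averaged in the
    selector comparison.
    """

    algorithm: str
    k_max: int = DEFAULT_K_MAX
    iterations: int = DEFAULT_ITERATIONS
    seed: int = 0
    n_runs: int = 1
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHM_DEFAULTS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from "
                f"{sorted(ALGORITHM_DEFAULTS)}"
            )
        if self.iterations < 1:
            raise ValueError("a positive iteration budget is required")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        merged = dict(ALGORITHM_DEFAULTS[self.algorithm])
        merged.update(self.params)
        self.params = merged
        for key in ("crossover_rate", "mutation_rate", "evaporation",
                    "assimilation_rate", "revolution_rate", "learning_rate",
                    "imitation_rate"):
            if key in self.params and not 0 <= self.params[key] <= 1:
                raise ValueError(f"{key} must lie in [0, 1]")


@dataclass
class SelectionResult:
    """Best subset found plus the full convergence record."""

    algorithm: str
    best_mask: np.ndarray
    best_wavelengths_nm: np.ndarray
    best_fitness: float
    trace: np.ndarray                 # best-so-far fitness per iteration (best run)
    per_run_fitness: list[float]
    per_run_test_correlation: list[float]
    per_run_traces: list[np.ndarray]
    wall_time_s: float
    evaluation_count: int             # fitness requests (memoized)
    unique_evaluations: int           # actual model refits
    seed: int

    @property
    def n_selected(self) -> int:
        return int(self.best_mask.sum())

    def to_jsonable(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "selected_wavelengths_nm": self.best_wavelengths_nm.tolist(),
            "n_selected": self.n_selected,
            "best_fitness_rmse": self.best_fitness,
            "trace": self.trace.tolist(),
            "per_run_fitness": self.per_run_fitness,
            "per_run_test_correlation": self.per_run_test_correlation,
            "wall_time_s": self.wall_time_s,
            "evaluation_count": self.evaluation_count,
            "unique_evaluations": self.unique_evaluations,
            "seed": self.seed,
        }


class FitnessEvaluator:
    """Memoized validation-RMSE fitness over wavelength masks.

    Fits ``model_spec`` on the training rows restricted to the masked
    columns and scores RMSE on the validation rows.  An empty mask returns
    +inf rather than raising, so optimizer loops never die on a degenerate
    candidate.  Validation residuals are cached per mask for the
    bootstrap-replayed matches of the league algorithm.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        wavelengths_nm: np.ndarray,
        split: SplitAssignment,
        model_spec: _models.ModelSpec | None = None,
    ) -> None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        self.wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
        self.X_train = X[split.train]
        self.y_train = y[split.train]
        self.X_val = X[split.validation]
        self.y_val = y[split.validation]
        self.X_test = X[split.test]
        self.y_test = y[split.test]
        self.model_spec = model_spec or _models.ModelSpec(family="svr", kernel="linear")
        self.n_wavelengths = self.wavelengths_nm.size
        self._memo: dict[bytes, tuple[float, np.ndarray]] = {}
        self._singleton_order: np.ndarray | None = None
        self.n_calls = 0
        self.n_unique = 0

    def _key(self, mask: np.ndarray) -> bytes:
        return np.asarray(mask, dtype=bool).tobytes()

    def evaluate(self, mask: np.ndarray) -> float:
        self.n_calls += 1
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.n_wavelengths:
            raise ValueError("mask length does not match the candidate pool")
        if not mask.any():
            return float("inf")
        key = self._key(mask)
        hit = self._memo.get(key)
        if hit is None:
            self.n_unique += 1
            fitted = _models.fit(
                self.model_spec,
                self.X_train[:, mask],
                self.y_train,
                self.wavelengths_nm[mask],
            )
            pred = _models.predict(fitted, self.X_val[:, mask])
            residuals = self.y_val - pred
            hit = (float(np.sqrt(np.mean(residuals**2))), residuals)
            self._memo[key] = hit
        return hit[0]

    def residuals(self, mask: np.ndarray) -> np.ndarray:
        self.evaluate(mask)
        return self._memo[self._key(np.asarray(mask, dtype=bool))][1]

    def test_correlation(self, mask: np.ndarray) -> float:
        """Pearson correlation of observed vs predicted on the test rows
        for the model refitted on the masked columns."""
        mask = np.asarray(mask, dtype=bool)
        fitted = _models.fit(
            self.model_spec,
            self.X_train[:, mask],
            self.y_train,
            self.wavelengths_nm[mask],
        )
        pred = _models.predict(fitted, self.X_test[:, mask])
        if np.ptp(pred) == 0 or np.ptp(self.y_test) == 0:
            return 0.0
        return float(np.corrcoef(self.y_test, pred)[0, 1])

    def singleton_order(self) -> np.ndarray:
        """Wavelength indices sorted by single-wavelength fitness, best
        first; computed once and used by cardinality repair."""
        if self._singleton_order is None:
            scores = np.empty(self.n_wavelengths)
            for j in range(self.n_wavelengths):
                mask = np.zeros(self.n_wavelengths, dtype=bool)
                mask[j] = True
                scores[j] = self.evaluate(mask)
            self._singleton_order = np.argsort(scores, kind="stable")
        return self._singleton_order


def evaluate_subset_fitness(
    mask: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    wavelengths_nm: np.ndarray,
    split: SplitAssignment,
    model_spec: _models.ModelSpec | None = None,
) -> float:
    """Validation RMSE of the model refitted on the masked wavelengths."""
    return FitnessEvaluator(X, y, wavelengths_nm, split, model_spec).evaluate(mask)


# ---------------------------------------------------------------------------
# shared optimizer plumbing


def _repair(
    mask: np.ndarray,
    k_max: int,
    rank_position: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Clamp a mask into the feasible 1..k_max cardinality band."""
    mask = np.asarray(mask, dtype=bool).copy()
    active = np.flatnonzero(mask)
    if active.size == 0:
        mask[rng.integers(mask.size)] = True
    elif active.size > k_max:
        keep = active[np.argsort(rank_position[active], kind="stable")[:k_max]]
        mask[:] = False
        mask[keep] = True
    return mask


def _init_prob(L: int, k_max: int) -> float:
    return min(0.5, 2.0 * k_max / L)


class _Archive:
    """Elitist best-ever record with a per-iteration trace."""

    def __init__(self) -> None:
        self.best_mask: np.ndarray | None = None
        self.best_fitness = float("inf")
        self.trace: list[float] = []

    def offer(self, mask: np.ndarray, fitness: float) -> None:
        if fitness < self.best_fitness:
            self.best_fitness = fitness
            self.best_mask = mask.copy()

    def tick(self) -> None:
        self.trace.append(self.best_fitness)


def _random_masks(
    rng: np.random.Generator, n: int, L: int, p0: float, k_max: int, ranks: np.ndarray
) -> list[np.ndarray]:
    """Initial population: uniform subsets of uniform cardinality 1..k_max.

    Exact-cardinality sampling keeps the initial pool diverse; drawing
    dense Bernoulli masks and repairing them would collapse every starter
    onto the same singleton-rank-favoured columns.
    """
    masks = []
    for _ in range(n):
        k = int(rng.integers(1, k_max + 1))
        cols = rng.choice(L, size=min(k, L), replace=False)
        m = np.zeros(L, dtype=bool)
        m[cols] = True
        masks.append(m)
    return masks


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


# ---------------------------------------------------------------------------
# the seven algorithms.  Each takes the evaluator, the feasibility bound,
# the shared iteration budget, its merged parameter dict and a seeded
# generator, and returns its elitist archive.


def _run_pso(ev: FitnessEvaluator, k_max: int, iters: int, prm: dict,
             rng: np.random.Generator) -> _Archive:
    """Binary PSO with a sigmoid transfer function and an lbest ring."""
    L = ev.n_wavelengths
    n = prm["particles"]
    ranks = _rank_positions(ev)
    arch = _Archive()
    pos = _random_masks(rng, n, L, _init_prob(L, k_max), k_max, ranks)
    vel = [np.zeros(L) for _ in range(n)]
    fit = np.array([ev.evaluate(m) for m in pos])
    for m, f in zip(pos, fit):
        arch.offer(m, f)
    pbest = [m.copy() for m in pos]
    pbest_fit = fit.copy()
    half = max(1, prm["p_bests"] // 2)  # ring-neighborhood size, split both ways
    for t in range(iters):
        w = 0.9 - (0.9 - 0.4) * (t / max(iters - 1, 1))
        for i in range(n):
            neigh = [(i + d) % n for d in range(-half, half + 1)]
            lbest = neigh[int(np.argmin(pbest_fit[neigh]))]
            r1, r2 = rng.random(L), rng.random(L)
            vel[i] = (
                w * vel[i]
                + 2.0 * r1 * (pbest[i].astype(float) - pos[i].astype(float))
                + 2.0 * r2 * (pbest[lbest].astype(float) - pos[i].astype(float))
            )
            np.clip(vel[i], -6.0, 6.0, out=vel[i])
            pos[i] = _repair(rng.random(L) < _sigmoid(vel[i]), k_max, ranks, rng)
            f = ev.evaluate(pos[i])
            if f < pbest_fit[i]:
                pbest_fit[i] = f
                pbest[i] = pos[i].copy()
            arch.offer(pos[i], f)
        arch.tick()
    return arch


def _run_ga(ev: FitnessEvaluator, k_max: int, iters: int, prm: dict,
            rng: np.random.Generator) -> _Archive:
    """Generational GA: tournament(2), uniform crossover, 1-elite."""
    L = ev.n_wavelengths
    n = prm["population"]
    ranks = _rank_positions(ev)
    arch = _Archive()
    pop = _random_masks(rng, n, L, _init_prob(L, k_max), k_max, ranks)
    fit = np.array([ev.evaluate(m) for m in pop])
    for m, f in zip(pop, fit):
        arch.offer(m, f)
    for _ in range(iters):
        def tournament() -> np.ndarray:
            a, b = rng.integers(n), rng.integers(n)
            return pop[a] if fit[a] <= fit[b] else pop[b]

        elite = pop[int(np.argmin(fit))].copy()
        children = [elite]
        while len(children) < n:
            p1, p2 = tournament().copy(), tournament().copy()
            if rng.random() < prm["crossover_rate"]:
                swap = rng.random(L) < 0.5
                p1[swap], p2[swap] = p2[swap], p1[swap]
            for child in (p1, p2):
                if rng.random() < prm["mutation_rate"]:
                    child ^= rng.random(L) < (1.0 / L)
                children.append(_repair(child, k_max, ranks, rng))
        pop = children[:n]
        fit = np.array([ev.evaluate(m) for m in pop])
        for m, f in zip(pop, fit):
            arch.offer(m, f)
        arch.tick()
    return arch


def _run_aco(ev: FitnessEvaluator, k_max: int, iters: int, prm: dict,
             rng: np.random.Generator) -> _Archive:
    """Per-wavelength pheromone model; the iteration-best ant deposits."""
    L = ev.n_wavelengths
    n_ants = prm["ants"]
    rho = prm["evaporation"]
    tau_min, tau_max = 0.01, 1.0
    tau = np.full(L, 0.5)
    arch = _Archive()
    k_pick = min(k_max, L)
    for _ in range(iters):
        ants, fits = [], []
        for _a in range(n_ants):
            picks = rng.choice(L, size=k_pick, replace=False, p=tau / tau.sum())
            mask = np.zeros(L, dtype=bool)
            mask[picks] = True
            f = ev.evaluate(mask)
            ants.append(mask)
            fits.append(f)
            arch.offer(mask, f)
        best = ants[int(np.argmin(fits))]
        tau = (1.0 - rho) * tau + rho * best.astype(float)
        np.clip(tau, tau_min, tau_max, out=tau)
        arch.tick()
    return arch


def _run_ica(ev: FitnessEvaluator, k_max: int, iters: int, prm: dict,
             rng: np.random.Generator) -> _Archive:
    """Imperialist competition on binary masks.

    Colonies assimilate by copying each bit that differs from their
    imperialist with a fixed per-bit probability; a revolution occasionally
    re-randomizes bits; empires compete by total cost and an empire that
    loses all colonies collapses.
    """
    L = ev.n_wavelengths
    n = prm["countries"]
    n_imp = min(prm["imperialists"], n - 1)
    ranks = _rank_positions(ev)
    arch = _Archive()
    masks = _random_masks(rng, n, L, _init_prob(L, k_max), k_max, ranks)
    fits = np.array([ev.evaluate(m) for m in masks])
    for m, f in zip(masks, fits):
        arch.offer(m, f)
    order = np.argsort(fits, kind="stable")
    imperialists = [masks[i].copy() for i in order[:n_imp]]
    imp_fit = [float(fits[i]) for i in order[:n_imp]]
    # colonies distributed proportionally to normalized imperialist power
    colony_masks = [masks[i].copy() for i in order[n_imp:]]
    cost = np.asarray(imp_fit)
    power = (cost.max() * 1.3 + 1e-12) - cost
    shares = power / power.sum()
    owners = rng.choice(n_imp, size=len(colony_masks), p=shares)
    empires: list[list[np.ndarray]] = [
        [colony_masks[c] for c in range(len(colony_masks)) if owners[c] == e]
        for e in range(n_imp)
    ]
    for _ in range(iters):
        for e in range(len(imperialists)):
            for ci, colony in enumerate(empires[e]):
                differs = colony != imperialists[e]
                if not differs.any():
                    # fully absorbed colony: it explores nothing, so it
                    # emigrates and a fresh country takes its place
                    new = _random_masks(rng, 1, L, _init_prob(L, k_max), k_max, ranks)[0]
                else:
                    copy = differs & (rng.random(L) < prm["assimilation_rate"])
                    new = colony.copy()
                    new[copy] = imperialists[e][copy]
                    if rng.random() < prm["revolution_rate"]:
                        new ^= rng.random(L) < (2.0 / L)
                    new = _repair(new, k_max, ranks, rng)
                f = ev.evaluate(new)
                arch.offer(new, f)
                empires[e][ci] = new
                if f < imp_fit[e]:
                    empires[e][ci] = imperialists[e]
                    imperialists[e] = new
                    imp_fit[e] = f
        # imperialistic competition: weakest empire loses its weakest colony
        if len(imperialists) > 1:
            totals = [
                imp_fit[e]
                + 0.1 * float(np.mean([ev.evaluate(c) for c in empires[e]]))
                if empires[e]
                else imp_fit[e]
                for e in range(len(imperialists))
            ]
            weakest = int(np.argmax(totals))
            strongest = int(np.argmin(totals))
            if empires[weakest]:
                col_fits = [ev.evaluate(c) for c in empires[weakest]]
                worst = int(np.argmax(col_fits))
                empires[strongest].append(empires[weakest].pop(worst))
            else:
                empires[strongest].append(imperialists[weakest])
                del imperialists[weakest], imp_fit[weakest], empires[weakest]
        arch.tick()
    return arch


def _run_la(ev: FitnessEvaluator, k_max: int, iters: int, prm: dict,
            rng: np.random.Generator) -> _Archive:
    """Linear reward-inaction automata, one inclusion probability per
    wavelength; the generation-best mask is rewarded."""
    L = ev.n_wavelengths
    a = prm["learning_rate"]
    tries = prm["tries"]
    ranks = _rank_positions(ev)
    arch = _Archive()
    p = np.full(L, 0.5)
    for _ in range(iters):
        masks = [_repair(rng.random(L) < p, k_max, ranks, rng) for _ in range(tries)]
        fits = [ev.evaluate(m) for m in masks]
        for m, f in zip(masks, fits):
            arch.offer(m, f)
        best = masks[int(np.argmin(fits))]
        p = np.where(best, p + a * (1.0 - p), p * (1.0 - a))
        arch.tick()
    return arch


def _run_hts(ev: FitnessEvaluator, k_max: int, iters: int, prm: dict,
             rng: np.random.Generator) -> _Archive:
    """Heat-transfer search on continuous inclusion scores in [0,1]^L.

    Scores threshold at 0.5 into a mask.  Each iteration applies one phase
    chosen uniformly -- conduction (step toward a random partner, scaled by
    1/CDF), convection (step toward the best molecule, scaled by 10/COF),
    or radiation (uniform perturbation of width 1/RDF) -- with greedy
    per-molecule acceptance.
    """
    L = ev.n_wavelengths
    n = prm["molecules"]
    ranks = _rank_positions(ev)
    arch = _Archive()
    scores = [rng.random(L) for _ in range(n)]

    def mask_of(s: np.ndarray) -> np.ndarray:
        return _repair(s > 0.5, k_max, ranks, rng)

    masks = [mask_of(s) for s in scores]
    fits = np.array([ev.evaluate(m) for m in masks])
    for m, f in zip(masks, fits):
        arch.offer(m, f)
    for _ in range(iters):
        phase = rng.integers(3)
        best = scores[int(np.argmin(fits))].copy()
        for i in range(n):
            u = rng.random(L)
            if phase == 0:  # conduction
                j = int(rng.integers(n))
                new = scores[i] + u * (scores[j] - scores[i]) / prm["cdf"]
            elif phase == 1:  # convection
                new = scores[i] + u * (best - scores[i]) * (10.0 / prm["cof"])
            else:  # radiation: undirected emission wide enough to flip bits
                new = scores[i] + (u - 0.5) * 2.0 / prm["rdf"]
            np.clip(new, 0.0, 1.0, out=new)
            new_mask = mask_of(new)
            f = ev.evaluate(new_mask)
            arch.offer(new_mask, f)
            if f <= fits[i]:
                scores[i], masks[i], fits[i] = new, new_mask, f
        arch.tick()
    return arch


def _run_lca(ev: FitnessEvaluator, k_max: int, iters: int, prm: dict,
             rng: np.random.Generator) -> _Archive:
    """League championship: round-robin matches decided over bootstrap
    replays of the validation residuals; losers imitate winners.  At the
    end of each season (teams-1 rounds) the weakest team is replaced by a
    fresh random side -- the transfer window that keeps the small league
    from collapsing onto one line-up."""
    L = ev.n_wavelengths
    n = prm["teams"]
    match_time = prm["match_time"]
    ranks = _rank_positions(ev)
    arch = _Archive()
    p0 = _init_prob(L, k_max)
    teams = _random_masks(rng, n, L, p0, k_max, ranks)
    for m in teams:
        arch.offer(m, ev.evaluate(m))

    def play_match(mask_a: np.ndarray, mask_b: np.ndarray) -> bool:
        """True when side A wins: lower mean RMSE over ``match_time``
        bootstrap replays of the validation set, both sides scored on the
        same resampled indices (a paired comparison)."""
        res_a, res_b = ev.residuals(mask_a), ev.residuals(mask_b)
        score_a = score_b = 0.0
        for _ in range(match_time):
            idx = rng.integers(res_a.size, size=res_a.size)
            score_a += float(np.sqrt(np.mean(res_a[idx] ** 2)))
            score_b += float(np.sqrt(np.mean(res_b[idx] ** 2)))
        return score_a <= score_b

    # the iteration budget is divided into the configured number of
    # seasons; each season ends with a transfer window
    season_length = max(1, iters // int(prm.get("seasons", 10)))
    for it in range(iters):
        pairing = rng.permutation(n)
        champion = int(np.argmin([ev.evaluate(t) for t in teams]))
        for a_i, b_i in zip(pairing[::2], pairing[1::2]):
            win, lose = (a_i, b_i) if play_match(teams[a_i], teams[b_i]) else (b_i, a_i)
            if lose == champion:  # the league leader is never rebuilt mid-season
                continue
            differs = teams[lose] != teams[win]
            if not differs.any():
                # two identical line-ups: the loser rebuilds from scratch
                new = _random_masks(rng, 1, L, _init_prob(L, k_max), k_max, ranks)[0]
            else:
                copy = differs & (rng.random(L) < prm["imitation_rate"])
                new = teams[lose].copy()
                new[copy] = teams[win][copy]
                new ^= rng.random(L) < (1.0 / L)
                new = _repair(new, k_max, ranks, rng)
            teams[lose] = new
            arch.offer(new, ev.evaluate(new))
        # the champion's practice session: try one random line-up swap
        # (bench an active wavelength, field an inactive one) and keep it
        # only on strict improvement
        fits = [ev.evaluate(t) for t in teams]
        champ = int(np.argmin(fits))
        active = np.flatnonzero(teams[champ])
        inactive = np.flatnonzero(~teams[champ])
        if active.size and inactive.size:
            trial = teams[champ].copy()
            trial[rng.choice(active)] = False
            trial[rng.choice(inactive)] = True
            f_trial = ev.evaluate(trial)
            arch.offer(trial, f_trial)
            if f_trial < fits[champ]:
                teams[champ] = trial
        if (it + 1) % season_length == 0:
            worst = int(np.argmax([ev.evaluate(t) for t in teams]))
            teams[worst] = _random_masks(rng, 1, L, p0, k_max, ranks)[0]
            arch.offer(teams[worst], ev.evaluate(teams[worst]))
        arch.tick()
    return arch


def _rank_positions(ev: FitnessEvaluator) -> np.ndarray:
    """Map wavelength index -> its position in the singleton-fitness order
    (0 = best), the key used by cardinality repair."""
    order = ev.singleton_order()
    pos = np.empty_like(order)
    pos[order] = np.arange(order.size)
    return pos


ALGORITHMS = {
    "pso": _run_pso,
    "ga": _run_ga,
    "aco": _run_aco,
    "ica": _run_ica,
    "la": _run_la,
    "hts": _run_hts,
    "lca": _run_lca,
}

_RUN_SEED_OFFSET = 10_007  # fixed stride between the seeds of n_runs restarts


def run_selector(
    cfg: OptimizerConfig,
    X: np.ndarray,
    y: np.ndarray,
    wavelengths_nm: np.ndarray,
    split: SplitAssignment,
    model_spec: _models.ModelSpec | None = None,
) -> SelectionResult:
    """Run one metaheuristic selector (``cfg.n_runs`` restarts) on a fixed
    split and return the best subset with full convergence records."""
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if wavelengths_nm.size < 1:
        raise ValueError("an empty candidate pool cannot be searched")
    if cfg.k_max > wavelengths_nm.size:
        raise ValueError("k_max exceeds the candidate pool")
    ev = FitnessEvaluator(X, y, wavelengths_nm, split, model_spec)
    algo = ALGORITHMS[cfg.algorithm]
    t0 = time.perf_counter()
    best_arch: _Archive | None = None
    per_run_fitness, per_run_corr, per_run_traces = [], [], []
    for run in range(cfg.n_runs):
        rng = np.random.default_rng(cfg.seed + _RUN_SEED_OFFSET * run)
        arch = algo(ev, cfg.k_max, cfg.iterations, cfg.params, rng)
        per_run_fitness.append(arch.best_fitness)
        per_run_corr.append(ev.test_correlation(arch.best_mask))
        per_run_traces.append(np.asarray(arch.trace))
        if best_arch is None or arch.best_fitness < best_arch.best_fitness:
            best_arch = arch
    wall = time.perf_counter() - t0
    assert best_arch is not None and best_arch.best_mask is not None
    return SelectionResult(
        algorithm=cfg.algorithm,
        best_mask=best_arch.best_mask,
        best_wavelengths_nm=wavelengths_nm[best_arch.best_mask],
        best_fitness=best_arch.best_fitness,
        trace=np.asarray(best_arch.trace),
        per_run_fitness=per_run_fitness,
        per_run_test_correlation=per_run_corr,
        per_run_traces=per_run_traces,
        wall_time_s=wall,
        evaluation_count=ev.n_calls,
        unique_evaluations=ev.n_unique,
        seed=cfg.seed,
    )


def exhaustive_search(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths_nm: np.ndarray,
    split: SplitAssignment,
    model_spec: _models.ModelSpec | None = None,
    k: int = 3,
    max_subsets: int = 100_000,
) -> tuple[np.ndarray, float, int]:
    """Global optimum over all subsets of cardinality 1..k.

    Enumerates in lexicographic order, so fitness ties resolve to the
    lexicographically smallest subset.  Refuses (before evaluating
    anything) if the subset count exceeds ``max_subsets``.
    Returns (best mask, best fitness, number of subsets evaluated).
    """
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    L = wavelengths_nm.size
    total = sum(comb(L, j) for j in range(1, k + 1))
    if total > max_subsets:
        raise ValueError(
            f"{total} subsets exceed the exhaustive-search bound {max_subsets}"
        )
    ev = FitnessEvaluator(X, y, wavelengths_nm, split, model_spec)
    best_mask, best_fit = None, float("inf")
    count = 0
    for j in range(1, k + 1):
        for subset in itertools.combinations(range(L), j):
            mask = np.zeros(L, dtype=bool)
            mask[list(subset)] = True
            f = ev.evaluate(mask)
            count += 1
            if f < best_fit:
                best_fit, best_mask = f, mask
    assert best_mask is not None
    return best_mask, best_fit, count


def summarize_selectors(results: list[SelectionResult]) -> pd.DataFrame:
    """Comparison table over algorithms: subset size, mean fitness (RMSE),
    mean test correlation, mean wall time; sorted by mean fitness."""
    if not results:
        raise ValueError("no selector results to summarize")
    rows = []
    for r in results:
        rows.append(
            {
                "algorithm": r.algorithm,
                "n_selected": r.n_selected,
                "mean_fitness_rmse": float(np.mean(r.per_run_fitness)),
                "mean_test_correlation": float(np.mean(r.per_run_test_correlation)),
                "mean_wall_time_s": r.wall_time_s / max(len(r.per_run_fitness), 1),
                "n_runs": len(r.per_run_fitness),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("mean_fitness_rmse", kind="stable")
        .reset_index(drop=True)
    )
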