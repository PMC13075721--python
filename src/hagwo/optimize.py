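"""Hybrid Ant-Grey-Wolf Optimization (HAGWO) for feature-subset selection.

The hybrid couples two metaheuristics over the binary subset space:

* **Ant colony (exploration).** Each feature i carries a pheromone tau_i and
  a heuristic desirability eta_i (mutual information with the labels). Ants
  build subsets by weighted sampling under

      P_i = tau_i^alpha * eta_i^beta / sum_j tau_j^alpha * eta_j^beta

  and after evaluation pheromone evaporates and is reinforced by the fitness
  of every subset containing the feature:

      tau_i <- (1 - rho) * tau_i + sum_{sK with i} q * fitness(sK)

* **Grey wolves (exploitation).** The three best subsets of the elite pool
  lead as alpha, beta, delta. Each wolf computes a randomized distance to
  every leader, D = |c * x_leader - x| with c = 2R, steps toward each,
  x_k = x_leader - a_k * D, averages the three, and binarizes through a
  sigmoid transfer. The step scale a_k = 2*A*R - a shrinks as the control
  scalar a decays from 2 to 0 and A adapts to the fitness trajectory:

      A = 2 * (1 - T/t) * (1 + delta_fitness / fitness_max)

Three modes are exposed: ``aco`` (ants only), ``mgwo`` (wolves only from a
random start), and ``hybrid`` (ants generate, the elite seeds the wolves,
wolf-refined candidates are ranked by the fitness plus a bounded
leader-proximity bonus weighted by gamma). The best-so-far subset is always
tracked by plain fitness, so the reported best_fitness re-evaluates exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .eeg_features import FeatureTable
from .fitness import FitnessConfig, FitnessEvaluator

__all__ = [
    "AcoParams",
    "PheromoneState",
    "WolfState",
    "HagwoConfig",
    "SelectionResult",
    "selection_probabilities",
    "construct_subset",
    "update_pheromone",
    "select_elite",
    "adaptive_A",
    "wolf_step",
    "hybrid_score",
    "optimize",
    "run",
]

TAU_MIN = 1e-6
TAU_INIT = 1.0
ETA_FLOOR_FRACTION = 0.01  # floor = fraction * mean(eta), keeps zero-MI features reachable


@dataclass(frozen=True)
class AcoParams:
    alpha: float = 1.0   # pheromone exponent
    beta: float = 2.0    # heuristic exponent
    rho: float = 0.1     # evaporation rate
    q: float = 1.0       # deposit constant
    n_ants: int = 20

    def __post_init__(self):
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if self.n_ants < 3:
            raise ValueError("n_ants must be >= 3")


@dataclass(frozen=True)
class PheromoneState:
    tau: np.ndarray
    eta: np.ndarray

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        eta = np.asarray(self.eta, dtype=float)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "eta", eta)
        if tau.shape != eta.shape:
            raise ValueError("tau and eta must have equal length")
        if not np.all(tau > 0):
            raise ValueError("all pheromone values must be positive")
        if np.any(eta < 0):
            raise ValueError("heuristic values must be non-negative")


@dataclass
class WolfState:
    x_alpha: np.ndarray
    x_beta: np.ndarray
    x_delta: np.ndarray
    pack: list
    a: float = 2.0       # decays 2 -> 0 over the run


@dataclass(frozen=True)
class HagwoConfig:
    mode: str = "hybrid"
    max_iters: int = 100
    elite_fraction: float = 0.1
    gamma: float = 0.1
    stall_tol: float = 1e-4
    stall_patience: int = 10
    seed: int = 0
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    aco: AcoParams = field(default_factory=AcoParams)

    def __post_init__(self):
        if self.mode not in ("aco", "mgwo", "hybrid"):
            raise ValueError("mode must be one of aco | mgwo | hybrid")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not 0 < self.elite_fraction <= 1:
            raise ValueError("elite_fraction must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass
class SelectionResult:
    best_subset: np.ndarray
    best_fitness: float
    trace: list                # one dict per iteration: best, mean, tau_mean
    iterations_run: int
    mode: str

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.best_subset)


# ---------------------------------------------------------------------------
# Ant colony primitives
# ---------------------------------------------------------------------------

def selection_probabilities(state: PheromoneState, params: AcoParams) -> np.ndarray:
    """Per-feature selection probabilities P_i = tau^alpha * eta^beta,
    normalized. Zero-heuristic features get a floor before exponentiation so
    pure exploration can still reach them."""
    eta = state.eta.copy()
    mean_eta = float(eta.mean())
    if mean_eta > 0:
        eta = np.maximum(eta, ETA_FLOOR_FRACTION * mean_eta)
    weights = state.tau ** params.alpha * eta ** params.beta
    total = float(weights.sum())
    if not np.isfinite(total) or total <= 0:
        warnings.warn("degenerate selection weights; falling back to uniform")
        return np.full(state.tau.size, 1.0 / state.tau.size)
    return weights / total


def construct_subset(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """An ant's subset: size k drawn uniformly from {1..N}, then k distinct
    features by weighted sampling without replacement under P.

    Implemented as an exponential race (key_i = E_i / P_i, keep the k
    smallest), which is distributionally identical to sequential weighted
    draws without replacement.
    """
    P = np.asarray(P, dtype=float)
    n = P.size
    k = int(rng.integers(1, n + 1))
    keys = rng.exponential(size=n) / np.maximum(P, 1e-300)
    chosen = np.argpartition(keys, k - 1)[:k]
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    return mask


def update_pheromone(state: PheromoneState, subsets, fitnesses,
                     params: AcoParams) -> PheromoneState:
    """Evaporate then deposit q*fitness on every feature of every subset;
    the result is clamped below at TAU_MIN (negative fitness can otherwise
    drive pheromone negative)."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if not np.all(np.isfinite(fitnesses)):
        raise ValueError("fitnesses must be finite")
    masks = np.asarray([np.asarray(s).astype(float) for s in subsets])
    deposits = masks.T @ (params.q * fitnesses) if masks.size else 0.0
    tau = (1.0 - params.rho) * state.tau + deposits
    if np.any(tau < TAU_MIN):
        if np.any(tau < 0):
            warnings.warn("negative pheromone after deposit; clamped to floor")
        tau = np.maximum(tau, TAU_MIN)
    return PheromoneState(tau=tau, eta=state.eta)


def _rank_key(mask: np.ndarray, fit: float):
    # higher fitness first, then smaller subsets, then lexicographic bits
    return (-fit, int(mask.sum()), tuple(mask.astype(int)))


def select_elite(subsets, fitnesses, elite_fraction: float):
    """Top ceil(fraction * count) subsets by fitness (pool never smaller than
    three so the leaders exist); the best three become alpha, beta, delta.
    Ties break by smaller subset size, then lexicographic bit order."""
    subsets = [np.asarray(s).astype(bool) for s in subsets]
    if len(subsets) < 3:
        raise ValueError("need at least 3 evaluated subsets to pick leaders")
    order = sorted(range(len(subsets)),
                   key=lambda i: _rank_key(subsets[i], fitnesses[i]))
    pool_size = max(3, math.ceil(elite_fraction * len(subsets)))
    pool = [subsets[i] for i in order[:pool_size]]
    return pool[0], pool[1], pool[2], pool


# ---------------------------------------------------------------------------
# Grey wolf primitives
# ---------------------------------------------------------------------------

def adaptive_A(T: int, t: int, delta_fitness: float, fitness_max: float) -> float:
    """A = 2 * (1 - T/t) * (1 + delta_fitness / fitness_max), with the
    improvement clamped >= 0 and the ratio zeroed when fitness_max is at or
    below the numerical floor."""
    if not 0 <= T <= t:
        raise ValueError("need 0 <= T <= t")
    delta = max(delta_fitness, 0.0)
    if fitness_max <= 1e-9:
        warnings.warn("fitness_max at numerical floor; adaptive ratio treated as 0")
        ratio = 0.0
    else:
        ratio = delta / fitness_max
    return 2.0 * (1.0 - T / t) * (1.0 + ratio)


def wolf_step(position, wolves: WolfState, A: float,
              rng: np.random.Generator) -> np.ndarray:
    """One binary grey-wolf move: randomized distances to the three leaders,
    a step toward each, the arithmetic consensus, then a stochastic sigmoid
    binarization (bit = 1 iff U < 1/(1+exp(-consensus)))."""
    x = np.asarray(position, dtype=float)
    n = x.size
    steps = []
    for leader in (wolves.x_alpha, wolves.x_beta, wolves.x_delta):
        leader = np.asarray(leader, dtype=float)
        c = 2.0 * rng.random(n)
        D = np.abs(c * leader - x)
        a_k = 2.0 * A * rng.random(n) - wolves.a
        steps.append(leader - a_k * D)
    consensus = (steps[0] + steps[1] + steps[2]) / 3.0
    prob = 1.0 / (1.0 + np.exp(-consensus))
    mask = rng.random(n) < prob
    if not mask.any():
        # an empty subset is never a valid candidate; keep the most favored bit
        mask[int(np.argmax(prob))] = True
    return mask


def hamming_frac(a, b) -> float:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    return float(np.count_nonzero(a != b)) / a.size


def hybrid_score(subset, base_fitness: float, wolves: WolfState,
                 A_terms, gamma: float) -> float:
    """Fitness plus the bounded leader-proximity bonus

        gamma * (1/3) * sum_i [(1 - h_i) - A_i * h_i]

    where h_i is the Hamming distance to leader i divided by N. With gamma=0
    this is the plain fitness; a subset identical to all three leaders with
    zero A-terms earns the full bonus gamma."""
    A_terms = np.broadcast_to(np.asarray(A_terms, dtype=float), (3,))
    bonus = 0.0
    for A_i, leader in zip(A_terms, (wolves.x_alpha, wolves.x_beta, wolves.x_delta)):
        h = hamming_frac(subset, leader)
        bonus += (1.0 - h) - A_i * h
    return base_fitness + gamma * bonus / 3.0


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _random_subset(n: int, rng: np.random.Generator) -> np.ndarray:
    k = int(rng.integers(1, n + 1))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def _better(mask_a, fit_a, mask_b, fit_b) -> bool:
    """True if (mask_a, fit_a) outranks (mask_b, fit_b)."""
    return _rank_key(mask_a, fit_a) < _rank_key(mask_b, fit_b)


def optimize(fitness_fn, n_features: int, cfg: HagwoConfig,
             eta: np.ndarray | None = None) -> SelectionResult:
    """Run the selector on an arbitrary subset-fitness callable.

    ``fitness_fn(mask) -> float`` scores a boolean inclusion vector; ``eta``
    is the per-feature heuristic desirability (uniform when None). This is
    the engine behind :func:`run` and is directly usable with synthetic
    planted-fitness problems.
    """
    rng = np.random.default_rng(cfg.seed)
    n = n_features
    if n < 1:
        raise ValueError("need at least one feature")
    eta = np.ones(n) if eta is None else np.asarray(eta, dtype=float)
    state = PheromoneState(tau=np.full(n, TAU_INIT), eta=eta)

    best_mask: np.ndarray | None = None
    best_fit = -math.inf
    trace = []
    stall = 0
    t = cfg.max_iters

    wolves: WolfState | None = None
    if cfg.mode == "mgwo":
        # no ant colony to seed the pack: best of 3n random subsets lead
        n_pack = cfg.aco.n_ants
        initial = [_random_subset(n, rng) for _ in range(3 * n_pack)]
        fits = [fitness_fn(m) for m in initial]
        order = sorted(range(len(initial)),
                       key=lambda i: _rank_key(initial[i], fits[i]))
        wolves = WolfState(x_alpha=initial[order[0]], x_beta=initial[order[1]],
                           x_delta=initial[order[2]],
                           pack=[initial[i] for i in order[:n_pack]])
        for m, f in zip(initial, fits):
            if best_mask is None or _better(m, f, best_mask, best_fit):
                best_mask, best_fit = m.copy(), f

    iterations_run = 0
    for T in range(t):
        iterations_run = T + 1
        prev_best = best_fit
        if len(trace) >= 2 and math.isfinite(trace[-1]["best"]) and math.isfinite(trace[-2]["best"]):
            delta = max(trace[-1]["best"] - trace[-2]["best"], 0.0)
        else:
            delta = 0.0
        A = adaptive_A(T, t, delta, best_fit if math.isfinite(best_fit) else 0.0)
        a_scalar = 2.0 * (1.0 - T / t)

        subsets: list = []
        fits: list = []

        if cfg.mode in ("aco", "hybrid"):
            P = selection_probabilities(state, cfg.aco)
            for _ in range(cfg.aco.n_ants):
                m = construct_subset(P, rng)
                subsets.append(m)
                fits.append(fitness_fn(m))

        if cfg.mode == "hybrid":
            x_a, x_b, x_d, pool = select_elite(subsets, fits, cfg.elite_fraction)
            wolves = WolfState(x_alpha=x_a, x_beta=x_b, x_delta=x_d,
                               pack=list(pool), a=a_scalar)
            refined = [wolf_step(m, wolves, A, rng) for m in wolves.pack]
            refined_fits = [fitness_fn(m) for m in refined]
            # Rank the wolf-refined candidates by fitness + leader-proximity
            # bonus; the winner joins the pheromone deposit alongside the ants.
            scores = [hybrid_score(m, f, wolves, A, cfg.gamma)
                      for m, f in zip(refined, refined_fits)]
            subsets.extend(refined)
            fits.extend(refined_fits)
            trace_incumbent = float(np.max(scores)) if scores else -math.inf
        elif cfg.mode == "mgwo":
            assert wolves is not None
            wolves.a = a_scalar
            moved = [wolf_step(m, wolves, A, rng) for m in wolves.pack]
            moved_fits = [fitness_fn(m) for m in moved]
            subsets.extend(moved)
            fits.extend(moved_fits)
            wolves.pack = moved
            # leaders are the best three seen among leaders + new positions
            cands = [wolves.x_alpha, wolves.x_beta, wolves.x_delta] + moved
            cand_fits = [fitness_fn(m) for m in cands]
            order = sorted(range(len(cands)),
                           key=lambda i: _rank_key(cands[i], cand_fits[i]))
            wolves.x_alpha = cands[order[0]]
            wolves.x_beta = cands[order[1]]
            wolves.x_delta = cands[order[2]]
            trace_incumbent = cand_fits[order[0]]
        else:
            trace_incumbent = float(np.max(fits)) if fits else -math.inf

        for m, f in zip(subsets, fits):
            if best_mask is None or _better(m, f, best_mask, best_fit):
                best_mask, best_fit = m.copy(), f

        if cfg.mode in ("aco", "hybrid"):
            finite = [(m, f) for m, f in zip(subsets, fits) if math.isfinite(f)]
            if finite:
                state = update_pheromone(state, [m for m, _ in finite],
                                         [f for _, f in finite], cfg.aco)

        finite_fits = [f for f in fits if math.isfinite(f)]
        trace.append({
            "best": best_fit,
            "mean": float(np.mean(finite_fits)) if finite_fits else math.nan,
            "tau_mean": float(state.tau.mean()),
            "incumbent_score": trace_incumbent,
        })

        improvement = best_fit - prev_best if math.isfinite(prev_best) else math.inf
        stall = stall + 1 if improvement < cfg.stall_tol else 0
        if stall >= cfg.stall_patience:
            break

    assert best_mask is not None
    return SelectionResult(best_subset=best_mask, best_fitness=best_fit,
                           trace=trace, iterations_run=iterations_run,
                           mode=cfg.mode)


def run(table: FeatureTable, cfg: HagwoConfig = HagwoConfig()) -> SelectionResult:
    """Select features from a labeled table.

    Builds the memoizing CV-fitness evaluator and the mutual-information
    heuristic, then runs :func:`optimize` in the configured mode. Rejects
    single-class tables up front.
    """
    if np.unique(table.labels).size < 2:
        raise ValueError("feature table has a single class; selection is undefined")
    evaluator = FitnessEvaluator(table, cfg.fitness)
    from .fitness import mi_heuristic
    eta = mi_heuristic(table, cfg.fitness.n_bins)
    return optimize(evaluator, table.n_features, cfg, eta=eta)
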