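"""Evolutionary dynamics of social norms in the rare-mutation limit.

Norm adoption follows a pairwise-comparison (Fermi) imitation process with
selection strength s; in the rare-mutation limit the population is
homogeneous almost always and evolution reduces to a Markov chain over the
homogeneous states of the competing norm set (here a leading-eight norm,
ALLC, and ALLD).  The fixation probability of a single mutant M into a
resident population R is

    rho_MR = 1 / (1 + sum_{i=1}^{N-1} prod_{k=1}^{i} exp(-s (pi_M(k) - pi_R(k))))

where pi_M(k), pi_R(k) are the average payoffs of mutants and residents when
k players carry the mutant norm — estimated by simulating the reputation
dynamics for every two-norm composition.  Off-diagonal transition
probabilities are rho/2 (the mutant is one of the two other norms with equal
probability); the stationary distribution of the chain is the
selection-mutation equilibrium, and the equilibrium cooperation rate weights
each homogeneous population's self-cooperation rate by its abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .norms import AssessmentFrame, SocialNorm, get_norm
from .reputation import GameParams, Population, run_binary_baseline, run_reputation_dynamics

__all__ = [
    "EvolutionConfig",
    "EdgePayoffs",
    "EvolutionResult",
    "edge_payoffs",
    "fixation_probability",
    "transition_matrix",
    "stationary_distribution",
    "average_cooperation",
    "self_cooperation",
    "run_evolution_experiment",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Settings for one three-norm rare-mutation competition.

    ``binary_baseline=True`` replaces the integer-score engine with the
    direct binary-reputation model (ignoring ``frame``).
    """

    norm: str = "L1"
    N: int = 50
    s: float = 1.0
    params: GameParams = field(default_factory=GameParams)
    frame: AssessmentFrame = field(default_factory=lambda: AssessmentFrame.symmetric(5))
    T: int = 200_000
    burn_in: int | None = None
    replicates: int = 3
    seed: int = 0
    binary_baseline: bool = False

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection strength s must be >= 0")
        if self.N < 2:
            raise ValueError("population size must be >= 2")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class EdgePayoffs:
    """Composition-resolved payoffs along one two-norm simplex edge.

    ``pi_M[k-1]`` / ``pi_R[k-1]`` are the average payoffs of the k mutants
    and the N-k residents, averaged over replicate seeds, for k = 1..N-1.
    """

    mutant: str
    resident: str
    pi_M: np.ndarray
    pi_R: np.ndarray

    def reversed(self) -> "EdgePayoffs":
        """The same edge viewed from the other norm's perspective.

        With k mutants of M, the resident count of R is N-k, so the
        reversed edge's payoff vectors are the original ones read backwards.
        """
        return EdgePayoffs(self.resident, self.mutant, self.pi_R[::-1].copy(), self.pi_M[::-1].copy())


@dataclass
class EvolutionResult:
    """Outcome of one three-norm competition (norm order: L, ALLC, ALLD)."""

    norms: tuple[str, str, str]
    rho: np.ndarray          # rho[i, j] = fixation prob of mutant j in resident i; diag 0
    W: np.ndarray            # 3x3 rare-mutation transition matrix
    stationary: np.ndarray   # selection-mutation equilibrium
    self_coop: np.ndarray    # homogeneous-population cooperation rates
    avg_coop: float
    config: EvolutionConfig | None = None

    @property
    def abundance(self) -> dict[str, float]:
        return dict(zip(self.norms, self.stationary))


def _edge_seed(base: int, *key: int) -> int:
    """Deterministic per-(edge, k, replicate) seed below 2**31."""
    return int(np.random.SeedSequence((base, *key)).generate_state(1)[0] & 0x7FFFFFFF)


def _run(population: Population, config: EvolutionConfig, seed: int):
    if config.binary_baseline:
        return run_binary_baseline(population, config.params, config.T,
                                   burn_in=config.burn_in, seed=seed)
    return run_reputation_dynamics(population, config.params, config.frame,
                                   config.T, burn_in=config.burn_in, seed=seed)


def edge_payoffs(mutant: "str | SocialNorm", resident: "str | SocialNorm",
                 config: EvolutionConfig, edge_id: int = 0) -> EdgePayoffs:
    """Simulate every mixed composition along a two-norm edge.

    For each mutant count k = 1..N-1 the reputation dynamics are run
    ``config.replicates`` times with distinct deterministic seeds; payoffs
    are averaged within each norm class and across replicates.
    """
    mutant = get_norm(mutant) if isinstance(mutant, str) else mutant
    resident = get_norm(resident) if isinstance(resident, str) else resident
    N = config.N
    pi_M = np.zeros(N - 1)
    pi_R = np.zeros(N - 1)
    for k in range(1, N):
        population = Population([mutant] * k + [resident] * (N - k))
        acc_M = acc_R = 0.0
        for rep in range(config.replicates):
            seed = _edge_seed(config.seed, edge_id, k, rep)
            stats = _run(population, config, seed)
            acc_M += stats.payoff[:k].mean()
            acc_R += stats.payoff[k:].mean()
        pi_M[k - 1] = acc_M / config.replicates
        pi_R[k - 1] = acc_R / config.replicates
    return EdgePayoffs(mutant.name, resident.name, pi_M, pi_R)


def fixation_probability(edge: EdgePayoffs, s: float) -> float:
    """Fixation probability of a single mutant (pairwise-comparison process).

    Accumulates the products of exp(-s * (pi_M(k) - pi_R(k))) in log space,
    so large payoff differences at N = 50 cannot overflow.  Exactly 1/N when
    s = 0 or the payoff vectors coincide.
    """
    if s < 0:
        raise ValueError("selection strength s must be >= 0")
    diff = np.asarray(edge.pi_M) - np.asarray(edge.pi_R)
    if not np.all(np.isfinite(diff)):
        raise ValueError("payoff differences must be finite")
    # log of the cumulative products
    log_terms = np.cumsum(-s * diff)
    m = max(0.0, float(log_terms.max()))
    denom = np.exp(-m) + np.exp(log_terms - m).sum()
    return float(np.exp(-m) / denom)


def transition_matrix(rho: np.ndarray) -> np.ndarray:
    """Rare-mutation transition matrix: W_ij = rho_ij / 2 off the diagonal."""
    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    if rho.shape != (n, n) or np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho must be a square matrix of probabilities")
    W = rho / 2.0
    np.fill_diagonal(W, 0.0)
    np.fill_diagonal(W, 1.0 - W.sum(axis=1))
    if np.any(np.diag(W) < 0):
        raise ValueError("row fixation probabilities sum above 2; not a valid chain")
    return W


def stationary_distribution(W: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Left fixed vector of a row-stochastic matrix, normalized to sum 1."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not np.allclose(W.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("W must be row-stochastic")
    # v (W - I) = 0 with sum(v) = 1, solved as a bordered linear system
    A = np.vstack([(W.T - np.eye(n)), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    v, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(v < -1e-8):
        raise ValueError("chain appears reducible: negative stationary mass")
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    resid = np.abs(v @ W - v).max()
    if resid > max(tol, 1e-10):
        raise ValueError(f"stationary residual {resid:.2e} too large")
    return v


def average_cooperation(stationary: np.ndarray, self_coop: np.ndarray) -> float:
    """Equilibrium cooperation rate: abundance-weighted self-cooperation."""
    return float(np.dot(stationary, self_coop))


def self_cooperation(norm: "str | SocialNorm", config: EvolutionConfig) -> float:
    """Average cooperation rate of a homogeneous population of the norm.

    ALLC and ALLD are unconditional, so their rates are exactly 1 and 0;
    other norms are simulated (mean off-diagonal pairwise cooperation rate,
    averaged over replicates).
    """
    norm = get_norm(norm) if isinstance(norm, str) else norm
    if norm.name == "ALLC":
        return 1.0
    if norm.name == "ALLD":
        return 0.0
    population = Population([norm] * config.N)
    off = ~np.eye(config.N, dtype=bool)
    acc = 0.0
    for rep in range(config.replicates):
        stats = _run(population, config, _edge_seed(config.seed, 99, 0, rep))
        acc += stats.coop_rate[off].mean()
    return acc / config.replicates


def run_evolution_experiment(config: EvolutionConfig) -> EvolutionResult:
    """Full rare-mutation pipeline for {norm, ALLC, ALLD}.

    Simulates the three two-norm edges (each edge yields both invasion
    directions), applies the fixation-probability formula, builds the
    transition matrix, and reports the selection-mutation equilibrium and
    the equilibrium cooperation rate.
    """
    names = (config.norm, "ALLC", "ALLD")
    if len(set(names)) != 3:
        raise ValueError("norm set must contain three distinct norms")
    edges: dict[tuple[int, int], EdgePayoffs] = {}
    pairs = [(0, 1), (0, 2), (1, 2)]
    for edge_id, (a, b) in enumerate(pairs):
        e = edge_payoffs(names[a], names[b], config, edge_id=edge_id)
        edges[(a, b)] = e
        edges[(b, a)] = e.reversed()
    # rho[i, j]: fixation probability of a mutant of norm j in a resident
    # population of norm i — the chain's i -> j transition is rho[i, j] / 2.
    rho = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            if i != j:
                rho[i, j] = fixation_probability(edges[(j, i)], config.s)
    W = transition_matrix(rho)
    stationary = stationary_distribution(W)
    self_coop = np.array([self_cooperation(n, config) for n in names])
    avg_coop = average_cooperation(stationary, self_coop)
    return EvolutionResult(names, rho, W, stationary, self_coop, avg_coop, config=config)


def sweep(config: EvolutionConfig, **grids: "list") -> "list[EvolutionResult]":
    """Cross-product parameter sweep; grid keys are EvolutionConfig fields.

    Nested GameParams fields (eps, q, b, c) are accepted directly.  Each run
    derives its seed from the base seed and its position in the grid.
    """
    import itertools as it

    keys = list(grids)
    results = []
    for run_idx, values in enumerate(it.product(*(grids[k] for k in keys))):
        cfg = config
        for key, val in zip(keys, values):
            if key in ("eps", "q", "b", "c"):
                cfg = replace(cfg, params=replace(cfg.params, **{key: val}))
            else:
                cfg = replace(cfg, **{key: val})
        cfg = replace(cfg, seed=_edge_seed(config.seed, 7, run_idx, 0))
        results.append(run_evolution_experiment(cfg))
    return results
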