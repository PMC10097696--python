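"""Donation-game reputation dynamics on the private image matrix.

The population state is an N x N integer matrix ``r_ij``: the reputation
score player i privately assigns to player j (players also track their own
score, the diagonal).  Each round an ordered (donor, recipient) pair is
drawn uniformly; the donor acts according to their norm and their own
judgments; the donor, the recipient, and each third party (independently,
with probability q, misperceiving the action with probability eps) then
update the donor's score by the +-1 increment their assessment rule
prescribes, clamped to the frame range [V, A].

Long-run statistics — time-averaged judgments, pairwise cooperation rates
x_ij, and the donation-game payoffs

    pi_i = 1/(N-1) * sum_{j != i} (b * x_ji - c * x_ij)

— are accumulated after a burn-in.  A brute-force exact stationary
distribution over the full image-matrix state space is available for tiny
instances as an independent check on the simulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .norms import Action, AssessmentFrame, SocialNorm, TieRule, get_norm

__all__ = [
    "GameParams",
    "Population",
    "ImageMatrix",
    "ReputationStats",
    "init_image",
    "interaction_round",
    "run_reputation_dynamics",
    "run_binary_baseline",
    "payoff_from_rates",
    "exact_stationary_small",
    "ExactStationary",
]


@dataclass(frozen=True)
class GameParams:
    """Donation-game and information parameters.

    b, c: benefit and cost of cooperation (payoff units), 0 < c < b.
    q: probability a third party observes an interaction.
    eps: probability an observer misperceives the action (C for D or D for C).
    donor_self_update / recipient_error: the donor and recipient always
    update the donor's score; by default the donor perceives their own
    action without error while the recipient misperceives with probability
    eps like any observer.  Both choices can be toggled.
    """

    b: float = 5.0
    c: float = 1.0
    q: float = 0.9
    eps: float = 0.05
    donor_self_update: bool = True
    recipient_error: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.c < self.b):
            raise ValueError(f"need 0 < c < b, got c={self.c}, b={self.b}")
        for name in ("q", "eps"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} is not a probability")


class Population:
    """A fixed assignment of social norms to the N players."""

    def __init__(self, norms: "list[str | SocialNorm]") -> None:
        if len(norms) < 2:
            raise ValueError("population needs at least 2 players")
        resolved = [get_norm(n) if isinstance(n, str) else n for n in norms]
        uniq: list[SocialNorm] = []
        index: dict[str, int] = {}
        idx = np.empty(len(resolved), dtype=np.int64)
        for i, norm in enumerate(resolved):
            key = norm.encode()
            if key not in index:
                index[key] = len(uniq)
                uniq.append(norm)
            idx[i] = index[key]
        self.members: tuple[SocialNorm, ...] = tuple(resolved)
        self.unique_norms: tuple[SocialNorm, ...] = tuple(uniq)
        self.norm_idx: np.ndarray = idx
        self.assess_stack = np.stack([n.assessment for n in uniq]).astype(np.int64)
        self.act_stack = np.stack([n.action for n in uniq]).astype(np.int64)

    @property
    def N(self) -> int:
        return len(self.members)

    @classmethod
    def from_counts(cls, spec: "dict[str, int] | list[tuple[str, int]]") -> "Population":
        items = spec.items() if isinstance(spec, dict) else spec
        names: list[str] = []
        for name, count in items:
            names.extend([name] * count)
        return cls(names)

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of players using the named norm."""
        return np.array([m.name == name for m in self.members])


@dataclass
class ImageMatrix:
    """Full private-opinion state: scores[i, j] = r_ij, plus the frame."""

    scores: np.ndarray
    frame: AssessmentFrame
    time: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.int64)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("scores must be a square matrix")
        if s.min() < self.frame.V or s.max() > self.frame.A:
            raise ValueError("scores outside frame range")
        self.scores = s

    @property
    def N(self) -> int:
        return self.scores.shape[0]

    def judgments(self) -> np.ndarray:
        """Binary judgment matrix J_ij implied by the current scores."""
        if self.frame.tie_rule is TieRule.GOOD_AT_S:
            return (self.scores >= self.frame.S).astype(np.int64)
        return (self.scores > self.frame.S).astype(np.int64)


@dataclass
class ReputationStats:
    """Time-averaged outcome of a reputation run.

    avg_judgment[i, j]: fraction of (post-burn-in) rounds in which i judged
    j good.  coop_rate[i, j]: the pairwise cooperation rate x_ij, estimated
    as the time average of i's *intended* action toward j, act(J_ii, J_ij).
    Because the donor's move is a deterministic function of the current
    labels and the (donor, recipient) draw is state-independent, this is an
    unbiased estimator of the same quantity as the per-pair empirical
    frequency (kept in ``empirical_coop_rate``), with far lower variance —
    every round informs every pair.  payoff: donation-game payoff vector
    computed from ``coop_rate``.
    """

    avg_judgment: np.ndarray
    coop_rate: np.ndarray
    payoff: np.ndarray
    rounds_used: int
    empirical_coop_rate: np.ndarray | None = field(default=None, repr=False)
    n_unobserved_pairs: int = 0
    final: ImageMatrix | None = field(default=None, repr=False)
    snapshots: np.ndarray | None = field(default=None, repr=False)


def init_image(population: Population, frame: AssessmentFrame, initial_score: int = 0) -> ImageMatrix:
    """All-consensus image matrix: every entry equals ``initial_score``."""
    if not (frame.V <= initial_score <= frame.A):
        raise ValueError(f"initial score {initial_score} outside [{frame.V}, {frame.A}]")
    return ImageMatrix(np.full((population.N, population.N), initial_score, np.int64), frame, 0)


def _perceive(action: int, flip: bool) -> int:
    return 1 - action if flip else action


def interaction_round(M: ImageMatrix, donor: int, recipient: int,
                      population: Population, params: GameParams,
                      rng: np.random.Generator) -> tuple[ImageMatrix, Action]:
    """One donation-game round with an explicit (donor, recipient) pair.

    Mutates and returns ``M`` (only the donor's column can change) together
    with the action taken.  Updaters read judgments from the pre-round
    matrix; reference implementation of the round the fast kernels run.
    """
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    frame, scores = M.frame, M.scores
    lab = M.judgments()
    action = int(population.act_stack[population.norm_idx[donor], lab[donor, donor], lab[donor, recipient]])
    q_true = params.q * (1.0 - params.eps)
    for i in range(M.N):
        if i == donor:
            if not params.donor_self_update:
                continue
            perceived = action
        elif i == recipient:
            if params.recipient_error:
                perceived = _perceive(action, rng.random() < params.eps)
            else:
                perceived = action
        else:
            u = rng.random()
            if u < q_true:
                perceived = action
            elif u < params.q:
                perceived = 1 - action
            else:
                continue
        delta = int(population.assess_stack[population.norm_idx[i], lab[i, donor], lab[i, recipient], perceived])
        scores[i, donor] = min(frame.A, max(frame.V, scores[i, donor] + delta))
    M.time += 1
    return M, Action(action)


def _impute_rates(coop_cnt, pair_cnt, avg_judgment, population):
    """x_ij for observed pairs; intended action vs averaged judgments otherwise."""
    N = coop_cnt.shape[0]
    coop_rate = np.zeros((N, N))
    unobserved = 0
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            if pair_cnt[i, j] > 0:
                coop_rate[i, j] = coop_cnt[i, j] / pair_cnt[i, j]
            else:
                unobserved += 1
                sj = 1 if avg_judgment[i, i] >= 0.5 else 0
                rj = 1 if avg_judgment[i, j] >= 0.5 else 0
                coop_rate[i, j] = float(
                    population.act_stack[population.norm_idx[i], sj, rj]
                )
    return coop_rate, unobserved


def run_reputation_dynamics(population: Population, params: GameParams,
                            frame: AssessmentFrame, T: int,
                            burn_in: int | None = None, seed: int = 0,
                            initial_score: int = 0,
                            snapshot_every: int = 0,
                            keep_final: bool = False) -> ReputationStats:
    """Simulate T rounds and return time-averaged reputation statistics.

    ``burn_in`` defaults to T // 10; statistics cover rounds
    burn_in..T-1.  Identical seeds yield identical results.
    """
    if burn_in is None:
        burn_in = T // 10
    if not (0 <= burn_in < T):
        raise ValueError(f"need 0 <= burn_in < T, got burn_in={burn_in}, T={T}")
    M = init_image(population, frame, initial_score)
    N = population.N
    coop_cnt = np.zeros((N, N), np.int64)
    pair_cnt = np.zeros((N, N), np.int64)
    labsum = np.zeros((N, N), np.float64)
    intend_sum = np.zeros((N, N), np.float64)
    n_snaps = (T // snapshot_every) if snapshot_every > 0 else 0
    snaps = np.zeros((n_snaps, N, N), np.int64)
    _kernels.run_rounds_quant(
        M.scores, population.norm_idx, population.assess_stack, population.act_stack,
        frame.V, frame.A, frame.S, frame.tie_rule is TieRule.GOOD_AT_S,
        params.eps, params.q, params.donor_self_update, params.recipient_error,
        T, burn_in, seed, coop_cnt, pair_cnt, labsum, intend_sum, snapshot_every, snaps)
    M.time = T
    avg_judgment = labsum / (T - burn_in)
    coop_rate = intend_sum / (T - burn_in)
    np.fill_diagonal(coop_rate, 0.0)
    empirical, unobserved = _impute_rates(coop_cnt, pair_cnt, avg_judgment, population)
    payoff = payoff_from_rates(coop_rate, params.b, params.c)
    return ReputationStats(avg_judgment, coop_rate, payoff, T - burn_in,
                           empirical_coop_rate=empirical,
                           n_unobserved_pairs=unobserved,
                           final=M if keep_final else None,
                           snapshots=snaps if snapshot_every > 0 else None)


def run_binary_baseline(population: Population, params: GameParams, T: int,
                        burn_in: int | None = None, seed: int = 0,
                        initial_good: bool = True,
                        snapshot_every: int = 0,
                        keep_final: bool = False) -> ReputationStats:
    """Direct binary-reputation dynamics: labels G/B set by each assessment.

    Independent of the integer-score engine; with the binary frame
    (V=0, A=1, S=1) and a shared seed the two produce identical
    trajectories, which is the baseline-model reduction.
    """
    if burn_in is None:
        burn_in = T // 10
    if not (0 <= burn_in < T):
        raise ValueError(f"need 0 <= burn_in < T, got burn_in={burn_in}, T={T}")
    N = population.N
    labels = np.full((N, N), 1 if initial_good else 0, np.int64)
    coop_cnt = np.zeros((N, N), np.int64)
    pair_cnt = np.zeros((N, N), np.int64)
    labsum = np.zeros((N, N), np.float64)
    intend_sum = np.zeros((N, N), np.float64)
    n_snaps = (T // snapshot_every) if snapshot_every > 0 else 0
    snaps = np.zeros((n_snaps, N, N), np.int64)
    _kernels.run_rounds_binary(
        labels, population.norm_idx, population.assess_stack, population.act_stack,
        params.eps, params.q, params.donor_self_update, params.recipient_error,
        T, burn_in, seed, coop_cnt, pair_cnt, labsum, intend_sum, snapshot_every, snaps)
    avg_judgment = labsum / (T - burn_in)
    coop_rate = intend_sum / (T - burn_in)
    np.fill_diagonal(coop_rate, 0.0)
    empirical, unobserved = _impute_rates(coop_cnt, pair_cnt, avg_judgment, population)
    payoff = payoff_from_rates(coop_rate, params.b, params.c)
    final = ImageMatrix(labels, AssessmentFrame.binary(), T) if keep_final else None
    return ReputationStats(avg_judgment, coop_rate, payoff, T - burn_in,
                           empirical_coop_rate=empirical,
                           n_unobserved_pairs=unobserved,
                           final=final, snapshots=snaps if snapshot_every > 0 else None)


def payoff_from_rates(coop_rate: np.ndarray, b: float, c: float) -> np.ndarray:
    """pi_i = 1/(N-1) * sum_{j != i} (b x_ji - c x_ij); diagonal ignored."""
    x = np.asarray(coop_rate, dtype=np.float64)
    N = x.shape[0]
    if N < 2:
        raise ValueError("need at least 2 players")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("cooperation rates must lie in [0, 1]")
    off = ~np.eye(N, dtype=bool)
    gains = np.where(off, x, 0.0).sum(axis=0)   # sum_j x_ji (i's column)
    costs = np.where(off, x, 0.0).sum(axis=1)   # sum_j x_ij (i's row)
    return (b * gains - c * costs) / (N - 1)


@dataclass
class ExactStationary:
    """Stationary distribution of the exact one-round image-matrix chain."""

    distribution: np.ndarray           # over all (2R+1)^(N^2) score matrices
    levels: int
    frame: AssessmentFrame
    population: Population
    _digits: np.ndarray = field(repr=False, default=None)

    def avg_judgment(self) -> np.ndarray:
        """Stationary expectation of the judgment indicator matrix."""
        N = self.population.N
        scores = self.frame.V + self._digits.reshape(-1, N, N)
        if self.frame.tie_rule is TieRule.GOOD_AT_S:
            lab = scores >= self.frame.S
        else:
            lab = scores > self.frame.S
        return np.tensordot(self.distribution, lab.astype(float), axes=1)

    def avg_score(self) -> np.ndarray:
        N = self.population.N
        scores = self.frame.V + self._digits.reshape(-1, N, N)
        return np.tensordot(self.distribution, scores.astype(float), axes=1)


def exact_stationary_small(population: Population, params: GameParams,
                           frame: AssessmentFrame, max_states: int = 30_000,
                           tol: float = 1e-13, max_iter: int = 200_000) -> ExactStationary:
    """Exact stationary distribution of the one-round Markov chain.

    Enumerates every score matrix (``(A-V+1)**(N*N)`` states), builds the
    one-round transition matrix by marginalizing the donor/recipient draw,
    observation, and misperception, and finds its stationary distribution by
    power iteration.  Only feasible for tiny instances (e.g. N <= 3, R <= 1);
    serves as an independent oracle for the simulation engine.
    """
    N = population.N
    L = frame.n_ranks
    n_states = L ** (N * N)
    if n_states > max_states:
        raise ValueError(f"state space of {n_states} states exceeds cap {max_states}")
    digits = np.array(list(itertools.product(range(L), repeat=N * N)), dtype=np.int64)
    scores_all = frame.V + digits.reshape(n_states, N, N)
    if frame.tie_rule is TieRule.GOOD_AT_S:
        lab_all = (scores_all >= frame.S).astype(np.int64)
    else:
        lab_all = (scores_all > frame.S).astype(np.int64)
    # weight of position (i, j) in the base-L state index
    place = L ** (N * N - 1 - (np.arange(N * N)).reshape(N, N))

    eps, q = params.eps, params.q
    pair_p = 1.0 / (N * (N - 1))
    rows, cols, vals = [], [], []
    for s_idx in range(n_states):
        scores = scores_all[s_idx]
        lab = lab_all[s_idx]
        for d in range(N):
            for r in range(N):
                if d == r:
                    continue
                action = int(population.act_stack[population.norm_idx[d], lab[d, d], lab[d, r]])
                # per-updater outcome distribution over the new r_id value
                col_outcomes: list[list[tuple[int, float]]] = []
                for i in range(N):
                    cur = int(scores[i, d])
                    outs: dict[int, float] = {}

                    def add(perceived: int, p: float) -> None:
                        if p <= 0.0:
                            return
                        delta = int(population.assess_stack[
                            population.norm_idx[i], lab[i, d], lab[i, r], perceived])
                        new = min(frame.A, max(frame.V, cur + delta))
                        outs[new] = outs.get(new, 0.0) + p

                    if i == d:
                        if params.donor_self_update:
                            add(action, 1.0)
                        else:
                            outs[cur] = 1.0
                    elif i == r:
                        if params.recipient_error:
                            add(action, 1.0 - eps)
                            add(1 - action, eps)
                        else:
                            add(action, 1.0)
                    else:
                        add(action, q * (1.0 - eps))
                        add(1 - action, q * eps)
                        outs[cur] = outs.get(cur, 0.0) + (1.0 - q)
                    col_outcomes.append(list(outs.items()))
                base = s_idx - int((digits[s_idx].reshape(N, N)[:, d] * place[:, d]).sum())
                combos = [(base, pair_p)]
                for i in range(N):
                    combos = [
                        (idx + (new - frame.V) * place[i, d], p * p_new)
                        for idx, p in combos
                        for new, p_new in col_outcomes[i]
                    ]
                for t_idx, p in combos:
                    rows.append(s_idx)
                    cols.append(t_idx)
                    vals.append(p)
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    v = np.full(n_states, 1.0 / n_states)
    for _ in range(max_iter):
        v_new = v @ P
        v_new /= v_new.sum()
        if np.abs(v_new - v).sum() < tol:
            v = v_new
            break
        v = v_new
    return ExactStationary(v, L, frame, population, _digits=digits)
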