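"""Recovery from a single private disagreement under perfect information.

A homogeneous population of leading-eight players starts from the consensus
image matrix (all scores at the initial value, everyone judged good) with
exactly one off-diagonal entry lowered so that one observer judges one
player bad.  With no observation lapses or misperception (eps = 0, q = 1)
the subsequent dynamics are driven purely by the random donor/recipient
draws; the population has *recovered* once every player again judges every
player good (labels, not scores — scores need not return to consensus).

The experiment measures, per replicate, whether recovery occurred before a
round cap, how many rounds it took, and how many defections happened on the
way; and compares the quantitative frame against the binary baseline on
paired seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .norms import AssessmentFrame, SocialNorm, TieRule, get_norm
from .reputation import ImageMatrix, Population, init_image

__all__ = [
    "RecoveryConfig",
    "RecoveryResult",
    "seed_disagreement",
    "simulate_recovery",
    "compare_binary_vs_quantitative",
]


@dataclass(frozen=True)
class RecoveryConfig:
    """One recovery experiment: a norm, a population size, and a frame.

    The disagreeing observer's score of the target is set to ``S - 1`` (the
    mildest bad score) unless ``disagreement_score`` says otherwise; all
    other entries start at ``initial_score`` (consensus good).
    """

    norm: str = "L1"
    N: int = 50
    frame: AssessmentFrame = field(default_factory=lambda: AssessmentFrame.symmetric(3))
    replicates: int = 10_000
    seed: int = 0
    max_rounds: int = 10_000_000
    initial_score: int | None = None      # default: lowest good score (S)
    disagreement_score: int | None = None  # default: S - 1 (mildest bad)
    observer: int = 0
    target: int = 1

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size must be >= 2")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class RecoveryResult:
    """Per-replicate outcomes plus summary statistics."""

    config: RecoveryConfig
    recovered: np.ndarray            # bool per replicate
    time_to_recovery: np.ndarray     # rounds, valid where recovered
    defections: np.ndarray           # count per replicate

    @property
    def recovery_fraction(self) -> float:
        return float(self.recovered.mean())

    @property
    def mean_time(self) -> float:
        """Mean rounds to recovery over recovered replicates (nan if none)."""
        t = self.time_to_recovery[self.recovered]
        return float(t.mean()) if t.size else float("nan")

    @property
    def se_time(self) -> float:
        t = self.time_to_recovery[self.recovered]
        return float(t.std(ddof=1) / np.sqrt(t.size)) if t.size > 1 else float("nan")

    @property
    def mean_defections(self) -> float:
        """Mean defections before recovery, over recovered replicates.

        Replicates that hit the round cap keep defecting indefinitely, so
        including them would measure the cap, not the recovery path.
        """
        d = self.defections[self.recovered]
        return float(d.mean()) if d.size else float("nan")

    def summary(self) -> dict:
        return {
            "norm": self.config.norm,
            "N": self.config.N,
            "frame": (self.config.frame.V, self.config.frame.A, self.config.frame.S),
            "replicates": int(self.recovered.size),
            "recovery_fraction": self.recovery_fraction,
            "mean_time": self.mean_time,
            "se_time": self.se_time,
            "mean_defections": self.mean_defections,
        }


def seed_disagreement(M: ImageMatrix, observer: int, target: int,
                      new_score: int) -> ImageMatrix:
    """Set one off-diagonal opinion, leaving the rest of the consensus intact."""
    if observer == target:
        raise ValueError("observer and target must differ")
    if not (M.frame.V <= new_score <= M.frame.A):
        raise ValueError(f"score {new_score} outside [{M.frame.V}, {M.frame.A}]")
    M.scores[observer, target] = new_score
    return M


def _initial_scores(config: RecoveryConfig) -> tuple[int, int]:
    frame = config.frame
    init = config.initial_score
    if init is None:
        init = frame.S if frame.tie_rule is TieRule.GOOD_AT_S else min(frame.S + 1, frame.A)
    dis = config.disagreement_score
    if dis is None:
        dis = max(frame.V, (frame.S - 1) if frame.tie_rule is TieRule.GOOD_AT_S else frame.S)
    return init, dis


def simulate_recovery(config: RecoveryConfig) -> RecoveryResult:
    """Replicated recovery experiment from a single seeded disagreement."""
    norm = get_norm(config.norm)
    population = Population([norm] * config.N)
    frame = config.frame
    init, dis = _initial_scores(config)
    recovered = np.zeros(config.replicates, dtype=bool)
    times = np.zeros(config.replicates, dtype=np.int64)
    defections = np.zeros(config.replicates, dtype=np.int64)
    tie_good = frame.tie_rule is TieRule.GOOD_AT_S
    # seeds depend on (seed, N) only, so different frames can be paired
    seeds = np.random.SeedSequence((config.seed, config.N)) \
        .generate_state(config.replicates) & 0x7FFFFFFF
    for rep in range(config.replicates):
        M = init_image(population, frame, init)
        seed_disagreement(M, config.observer, config.target, dis)
        ok, t, dfc = _kernels.run_recovery(
            M.scores, population.norm_idx, population.assess_stack,
            population.act_stack, frame.V, frame.A, frame.S, tie_good,
            config.max_rounds, int(seeds[rep]))
        recovered[rep], times[rep], defections[rep] = ok, t, dfc
    return RecoveryResult(config, recovered, times, defections)


def compare_binary_vs_quantitative(norm: "str | SocialNorm", N_grid: "list[int]",
                                   replicates: int = 2000, seed: int = 0,
                                   R: int = 3,
                                   max_rounds: int = 10_000_000,
                                   frames: "tuple[AssessmentFrame, AssessmentFrame] | None" = None,
                                   ) -> "dict[int, dict]":
    """Paired comparison of recovery under the binary and quantitative frames.

    The replicate seeds are shared between the two frames (the donor/
    recipient sequence is identical while both runs are in progress), so the
    per-N difference in mean recovery time is a paired estimate.  Returns a
    mapping N -> {binary: summary, quantitative: summary, delta_time,
    delta_time_se}.
    """
    name = norm if isinstance(norm, str) else norm.name
    if frames is None:
        frames = (AssessmentFrame.binary(), AssessmentFrame.symmetric(R))
    out: dict[int, dict] = {}
    for N in N_grid:
        res = {}
        for label, frame in (("binary", frames[0]), ("quantitative", frames[1])):
            cfg = RecoveryConfig(norm=name, N=N, frame=frame,
                                 replicates=replicates, seed=seed,
                                 max_rounds=max_rounds)
            res[label] = simulate_recovery(cfg)
        both = res["binary"].recovered & res["quantitative"].recovered
        delta = (res["quantitative"].time_to_recovery[both]
                 - res["binary"].time_to_recovery[both]).astype(float)
        out[N] = {
            "binary": res["binary"].summary(),
            "quantitative": res["quantitative"].summary(),
            "delta_time": float(delta.mean()) if delta.size else float("nan"),
            "delta_time_se": float(delta.std(ddof=1) / np.sqrt(delta.size)) if delta.size > 1 else float("nan"),
        }
    return out
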