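"""Run configuration, result serialization, and deterministic test fixtures.

Configuration is a flat YAML mapping with the simulation's standard
defaults (N=50, R=5, S=0, eps=0.05, q=0.9, b=5, c=1, s=1); unknown keys are
rejected so typos fail loudly.  Every result file embeds the fully resolved
configuration and seed, so any output can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .norms import AssessmentFrame, TieRule, get_norm
from .reputation import GameParams, ImageMatrix, Population, ReputationStats
from .evolution import EvolutionConfig, EvolutionResult
from .recovery import RecoveryConfig, RecoveryResult

__all__ = [
    "RunConfig",
    "load_config",
    "write_results",
    "write_image_matrix",
    "read_matrix_csv",
    "Fixture",
    "generate_fixtures",
]

_EXPERIMENTS = ("reputation", "evolve", "recover", "sweep")


@dataclass
class RunConfig:
    """Fully resolved settings for one experiment run."""

    experiment: str = "evolve"
    norm: str = "L1"
    norms: list[str] | None = None       # reputation runs: per-group norms
    counts: list[int] | None = None      # reputation runs: per-group sizes
    N: int = 50
    R: int = 5
    S: int = 0
    binary: bool = False                 # use the binary baseline frame/engine
    tie_rule: str = "good_at_s"
    eps: float = 0.05
    q: float = 0.9
    b: float = 5.0
    c: float = 1.0
    s: float = 1.0
    rounds: int = 200_000
    burn_in: int | None = None
    replicates: int = 3
    seed: int = 0
    max_rounds: int = 10_000_000
    out: str | None = None
    grids: dict[str, list] | None = None  # sweep: field -> values

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(f"experiment must be one of {_EXPERIMENTS}")
        self.frame()   # validates R/S
        self.params()  # validates b, c, eps, q

    def frame(self) -> AssessmentFrame:
        tie = TieRule(self.tie_rule)
        if self.binary:
            return AssessmentFrame.binary()
        return AssessmentFrame.symmetric(self.R, self.S, tie)

    def params(self) -> GameParams:
        return GameParams(b=self.b, c=self.c, q=self.q, eps=self.eps)

    def population(self) -> Population:
        if self.norms is not None:
            counts = self.counts or [1] * len(self.norms)
            if len(counts) != len(self.norms):
                raise ValueError("norms and counts must have equal length")
            return Population.from_counts(list(zip(self.norms, counts)))
        return Population([self.norm] * self.N)

    def evolution_config(self) -> EvolutionConfig:
        return EvolutionConfig(norm=self.norm, N=self.N, s=self.s,
                               params=self.params(), frame=self.frame(),
                               T=self.rounds, burn_in=self.burn_in,
                               replicates=self.replicates, seed=self.seed,
                               binary_baseline=self.binary)

    def recovery_config(self) -> RecoveryConfig:
        return RecoveryConfig(norm=self.norm, N=self.N, frame=self.frame(),
                              replicates=self.replicates, seed=self.seed,
                              max_rounds=self.max_rounds)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path_or_mapping: "str | Path | dict") -> RunConfig:
    """Load and validate a run configuration; unknown keys are rejected."""
    if isinstance(path_or_mapping, (str, Path)):
        raw = yaml.safe_load(Path(path_or_mapping).read_text()) or {}
    else:
        raw = dict(path_or_mapping)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
    return RunConfig(**raw)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def _dump_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")


def write_image_matrix(M: ImageMatrix, out_dir: "str | Path", stem: str = "image_matrix") -> list[Path]:
    """Scores as integer CSV (row = observer, column = target) + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{stem}.csv"
    pd.DataFrame(M.scores).to_csv(csv_path, index=False)
    meta = out / f"{stem}.json"
    _dump_json({"V": M.frame.V, "A": M.frame.A, "S": M.frame.S,
                "tie_rule": M.frame.tie_rule.value, "round": M.time}, meta)
    return [csv_path, meta]


def read_matrix_csv(path: "str | Path") -> np.ndarray:
    return pd.read_csv(path).to_numpy()


def write_results(result, out_dir: "str | Path", config: RunConfig | None = None) -> list[Path]:
    """Write a result object as JSON summary plus tidy CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict() if config is not None else None
    files: list[Path] = []

    if isinstance(result, ReputationStats):
        for name, mat in (("judgments", result.avg_judgment),
                          ("coop_rates", result.coop_rate)):
            p = out / f"{name}.csv"
            pd.DataFrame(mat).to_csv(p, index=False)
            files.append(p)
        p = out / "payoffs.csv"
        pd.DataFrame({"player": np.arange(result.payoff.size), "payoff": result.payoff}).to_csv(p, index=False)
        files.append(p)
        summary = {"rounds_used": result.rounds_used,
                   "n_unobserved_pairs": result.n_unobserved_pairs,
                   "mean_payoff": float(result.payoff.mean()),
                   "config": cfg}
        p = out / "reputation_summary.json"
        _dump_json(summary, p)
        files.append(p)
        if result.final is not None:
            files += write_image_matrix(result.final, out, "final_image_matrix")
        return files

    if isinstance(result, EvolutionResult):
        p = out / "evolution_result.json"
        _dump_json({"norms": list(result.norms), "rho": result.rho,
                    "W": result.W, "stationary": result.stationary,
                    "self_coop": result.self_coop, "avg_coop": result.avg_coop,
                    "config": cfg}, p)
        files.append(p)
        p = out / "abundances.csv"
        pd.DataFrame({"norm": list(result.norms),
                      "abundance": result.stationary,
                      "self_coop": result.self_coop}).to_csv(p, index=False)
        files.append(p)
        return files

    if isinstance(result, RecoveryResult):
        p = out / "recovery.csv"
        pd.DataFrame({"replicate": np.arange(result.recovered.size),
                      "recovered": result.recovered.astype(int),
                      "time_to_recovery": result.time_to_recovery,
                      "defections": result.defections}).to_csv(p, index=False)
        files.append(p)
        p = out / "recovery_summary.json"
        _dump_json({**result.summary(), "config": cfg}, p)
        files.append(p)
        return files

    if isinstance(result, list):  # sweep results
        rows = []
        for res in result:
            c = res.config
            rows.append({"norm": res.norms[0], "N": c.N, "eps": c.params.eps,
                         "q": c.params.q, "b": c.params.b, "c": c.params.c,
                         "V": c.frame.V, "A": c.frame.A, "S": c.frame.S,
                         "abundance_norm": res.stationary[0],
                         "abundance_ALLC": res.stationary[1],
                         "abundance_ALLD": res.stationary[2],
                         "self_coop_norm": res.self_coop[0],
                         "avg_coop": res.avg_coop})
        p = out / "sweep.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        files.append(p)
        return files

    raise TypeError(f"cannot serialize result of type {type(result).__name__}")


@dataclass(frozen=True)
class Fixture:
    """A tiny, deterministic scenario with expected qualitative outcomes."""

    name: str
    config: RunConfig
    tags: tuple[str, ...] = field(default_factory=tuple)


def generate_fixtures(out_dir: "str | Path | None" = None) -> list[Fixture]:
    """The micro-scenarios the test-suite exercises across modules.

    Every fixture completes in well under ten seconds; tags record the
    qualitative outcome the scenario is expected to show.
    """
    fixtures = [
        Fixture("allc_homog",
                RunConfig(experiment="reputation", norms=["ALLC"], counts=[6],
                          rounds=20_000, seed=11),
                ("coop_rate=1", "avg_judgment=1")),
        Fixture("alld_homog",
                RunConfig(experiment="reputation", norms=["ALLD"], counts=[6],
                          rounds=20_000, seed=12),
                ("coop_rate=0",)),
        Fixture("l1_noisefree",
                RunConfig(experiment="reputation", norms=["L1"], counts=[8],
                          eps=0.0, q=1.0, rounds=20_000, seed=13),
                ("no_bad_judgments", "coop_rate=1")),
        Fixture("binary_reduction",
                RunConfig(experiment="reputation", norms=["L1", "ALLC", "ALLD"],
                          counts=[4, 2, 2], binary=True, rounds=5_000, seed=14),
                ("trajectories_identical",)),
        Fixture("tiny_oracle",
                RunConfig(experiment="reputation", norms=["L1"], counts=[3],
                          R=1, rounds=200_000, seed=15),
                ("oracle_matches",)),
        Fixture("l1_mixed_thirds",
                RunConfig(experiment="reputation", norms=["L1", "ALLC", "ALLD"],
                          counts=[6, 6, 6], rounds=100_000, seed=16),
                ("defectors_judged_bad",)),
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for fx in fixtures:
            payload = {"name": fx.name, "tags": list(fx.tags),
                       "config": fx.config.to_dict()}
            (out / f"{fx.name}.yaml").write_text(yaml.safe_dump(payload, sort_keys=True))
    return fixtures
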