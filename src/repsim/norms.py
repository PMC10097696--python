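"""Social norms for indirect reciprocity: assessment rules, action rules, and registry.

A social norm is a pair of lookup tables.  The *assessment rule* maps the
context of an observed donation-game interaction — the observer's current
binary judgment of the donor, their judgment of the recipient, and the
action they perceived — to a score increment (+1, "the action was good") or
decrement (-1, "the action was bad").  The *action rule* maps the donor's
judgment of themselves and of the recipient to cooperate/defect.

Norms are third-order: assessments may condition on both reputations and the
action.  The module provides the eight third-order norms that sustain full
cooperation under public, reliable information (the "leading eight", L1-L8),
plus the unconditional strategies ALLC and ALLD expressed in the same table
formalism so the simulation engine has a single code path.

Reputation *scores* are integers in [V, A]; an :class:`AssessmentFrame`
translates a score into the binary judgment by comparison with a threshold
``S`` (score >= S means "good" under the default tie rule).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Judgment",
    "Action",
    "SocialNorm",
    "AssessmentFrame",
    "judge",
    "assess",
    "act",
    "leading_eight",
    "allc",
    "alld",
    "get_norm",
    "list_norms",
    "is_gullible",
    "LEADING_EIGHT_NAMES",
]


class Judgment(enum.IntEnum):
    """Binary label an observer attaches to a player."""

    BAD = 0
    GOOD = 1


class Action(enum.IntEnum):
    """Donation-game moves; C confers benefit b at cost c, D does nothing."""

    D = 0
    C = 1


class TieRule(enum.Enum):
    """How a score exactly at the threshold S is labeled."""

    GOOD_AT_S = "good_at_s"
    BAD_AT_S = "bad_at_s"


@dataclass(frozen=True)
class AssessmentFrame:
    """Score range [V, A] and judgment threshold S.

    Parameters
    ----------
    V, A : int
        Minimum and maximum reputation score.
    S : int
        Judgment threshold: a player with score ``r >= S`` is judged good
        (under the default ``GOOD_AT_S`` tie rule; under ``BAD_AT_S`` the
        comparison is strict).
    tie_rule : TieRule
        Label assigned at ``r == S``.
    """

    V: int
    A: int
    S: int
    tie_rule: TieRule = TieRule.GOOD_AT_S

    def __post_init__(self) -> None:
        if self.V > self.A:
            raise ValueError(f"empty score range: V={self.V} > A={self.A}")
        if not (self.V <= self.S <= self.A):
            raise ValueError(
                f"threshold S={self.S} outside score range [{self.V}, {self.A}]"
            )

    @classmethod
    def symmetric(cls, R: int, S: int = 0, tie_rule: TieRule = TieRule.GOOD_AT_S) -> "AssessmentFrame":
        """Symmetric quantitative frame with scores in [-R, R]."""
        if R < 0:
            raise ValueError("R must be nonnegative")
        return cls(V=-R, A=R, S=S, tie_rule=tie_rule)

    @classmethod
    def binary(cls) -> "AssessmentFrame":
        """The binary baseline: scores in {0, 1}, good iff score == 1."""
        return cls(V=0, A=1, S=1)

    @property
    def n_ranks(self) -> int:
        return self.A - self.V + 1

    def judge(self, score: int) -> Judgment:
        return judge(score, self)


def judge(score: int, frame: AssessmentFrame) -> Judgment:
    """Translate an integer reputation score into a binary judgment.

    Good iff ``score >= S`` (default tie rule), strict under ``BAD_AT_S``.
    Raises ``ValueError`` if the score lies outside ``[V, A]``.
    """
    if not (frame.V <= score <= frame.A):
        raise ValueError(f"score {score} outside frame range [{frame.V}, {frame.A}]")
    if frame.tie_rule is TieRule.GOOD_AT_S:
        return Judgment.GOOD if score >= frame.S else Judgment.BAD
    return Judgment.GOOD if score > frame.S else Judgment.BAD


_CTX = ((Judgment.GOOD, Judgment.GOOD), (Judgment.GOOD, Judgment.BAD),
        (Judgment.BAD, Judgment.GOOD), (Judgment.BAD, Judgment.BAD))


@dataclass(frozen=True)
class SocialNorm:
    """A third-order assessment table plus a second-order action table.

    ``assessment[dj, rj, a]`` is the score increment (+1/-1) prescribed when
    a donor currently judged ``dj`` is perceived taking action ``a`` toward a
    recipient judged ``rj``.  ``action[sj, rj]`` is the move (C/D) a donor
    who judges themselves ``sj`` and the recipient ``rj`` takes.  Tables are
    total: all 8 assessment contexts and all 4 action contexts are defined.
    """

    name: str
    assessment: np.ndarray = field(repr=False)  # (2, 2, 2) int8, values +-1
    action: np.ndarray = field(repr=False)      # (2, 2) int8, values 0/1

    def __post_init__(self) -> None:
        a = np.asarray(self.assessment, dtype=np.int8)
        b = np.asarray(self.action, dtype=np.int8)
        if a.shape != (2, 2, 2) or not np.all(np.abs(a) == 1):
            raise ValueError("assessment must be a total (2,2,2) table of +-1")
        if b.shape != (2, 2) or not np.all((b == 0) | (b == 1)):
            raise ValueError("action must be a total (2,2) table of 0/1")
        object.__setattr__(self, "assessment", a)
        object.__setattr__(self, "action", b)
        self.assessment.setflags(write=False)
        self.action.setflags(write=False)

    def assess(self, donor_j: Judgment, recipient_j: Judgment, observed: Action) -> int:
        return int(self.assessment[donor_j, recipient_j, observed])

    def act(self, self_j: Judgment, recipient_j: Judgment) -> Action:
        return Action(int(self.action[self_j, recipient_j]))

    def encode(self) -> str:
        """Canonical 12-character string: 8 assessment signs then 4 actions.

        Bit order is donor x recipient x action: contexts (G,G), (G,B),
        (B,G), (B,B), each listing the assessment of C then of D as '+'/'-';
        then the action (C/D) for the same four judgment contexts.
        """
        signs = "".join(
            "+" if self.assessment[dj, rj, a] > 0 else "-"
            for dj, rj in _CTX for a in (Action.C, Action.D)
        )
        moves = "".join("C" if self.action[sj, rj] else "D" for sj, rj in _CTX)
        return signs + moves

    @classmethod
    def decode(cls, name: str, code: str) -> "SocialNorm":
        """Inverse of :meth:`encode`; accepts any 12-char +/-/C/D string."""
        if len(code) != 12 or set(code[:8]) - set("+-") or set(code[8:]) - set("CD"):
            raise ValueError(f"malformed norm code {code!r}")
        assessment = np.empty((2, 2, 2), dtype=np.int8)
        action = np.empty((2, 2), dtype=np.int8)
        it = iter(code[:8])
        for dj, rj in _CTX:
            for a in (Action.C, Action.D):
                assessment[dj, rj, a] = 1 if next(it) == "+" else -1
        for (sj, rj), ch in zip(_CTX, code[8:]):
            action[sj, rj] = 1 if ch == "C" else 0
        return cls(name=name, assessment=assessment, action=action)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SocialNorm):
            return NotImplemented
        return self.encode() == other.encode()

    def __hash__(self) -> int:
        return hash(self.encode())


def assess(norm: SocialNorm, donor_j: Judgment, recipient_j: Judgment, observed: Action) -> int:
    """Score increment (+1/-1) the norm prescribes for an observed action."""
    return norm.assess(donor_j, recipient_j, observed)


def act(norm: SocialNorm, self_j: Judgment, recipient_j: Judgment) -> Action:
    """Move the norm prescribes for a donor in the given judgment context."""
    return norm.act(self_j, recipient_j)


# The leading eight share five assessment bits and three action bits:
# cooperation with a good recipient is good, defection against a good
# recipient is bad, justified defection (G donor vs B recipient) keeps a good
# reputation; good players cooperate with good recipients, defect against bad
# ones, and bad players cooperate with good recipients to regain standing.
# The remaining free bits — the assessment of cooperating with a bad
# recipient by a good donor, and of either action between two bad players —
# distinguish L1..L8; the action between two bad players is the payoff-
# rational response to the norm's own (B,B) assessments.
#
# (alpha(G,B,C), alpha(B,B,C), alpha(B,B,D)) per norm:
_L_FREE_BITS = {
    1: (+1, +1, -1),
    2: (-1, +1, -1),
    3: (+1, +1, +1),   # Simple Standing
    4: (+1, -1, +1),
    5: (-1, +1, +1),
    6: (-1, -1, +1),   # Stern Judging
    7: (+1, -1, -1),
    8: (-1, -1, -1),
}

LEADING_EIGHT_NAMES = tuple(f"L{i}" for i in range(1, 9))


def leading_eight(index: int) -> SocialNorm:
    """Return leading-eight norm ``L<index>`` for ``index`` in 1..8."""
    try:
        gbc, bbc, bbd = _L_FREE_BITS[index]
    except KeyError:
        raise KeyError(f"leading-eight index must be 1..8, got {index!r}") from None
    G, B, C, D = Judgment.GOOD, Judgment.BAD, Action.C, Action.D
    assessment = np.empty((2, 2, 2), dtype=np.int8)
    assessment[G, G, C] = +1
    assessment[G, G, D] = -1
    assessment[B, G, C] = +1
    assessment[B, G, D] = -1
    assessment[G, B, D] = +1
    assessment[G, B, C] = gbc
    assessment[B, B, C] = bbc
    assessment[B, B, D] = bbd
    action = np.empty((2, 2), dtype=np.int8)
    action[G, G] = 1
    action[G, B] = 0
    action[B, G] = 1
    action[B, B] = 1 if (bbc == +1 and bbd == -1) else 0
    return SocialNorm(name=f"L{index}", assessment=assessment, action=action)


def allc() -> SocialNorm:
    """Unconditional cooperator: assesses everyone positively, always cooperates."""
    return SocialNorm("ALLC", np.full((2, 2, 2), 1, np.int8), np.full((2, 2), 1, np.int8))


def alld() -> SocialNorm:
    """Unconditional defector: assesses everyone negatively, always defects."""
    return SocialNorm("ALLD", np.full((2, 2, 2), -1, np.int8), np.zeros((2, 2), np.int8))


def _registry() -> dict[str, SocialNorm]:
    reg = {f"L{i}": leading_eight(i) for i in range(1, 9)}
    reg["ALLC"] = allc()
    reg["ALLD"] = alld()
    return reg


_REGISTRY = _registry()


def get_norm(name: str) -> SocialNorm:
    """Look up a norm by name ("L1".."L8", "ALLC", "ALLD")."""
    try:
        return _REGISTRY[name.upper()]
    except KeyError:
        raise KeyError(f"unknown norm {name!r}; known: {sorted(_REGISTRY)}") from None


def list_norms() -> list[str]:
    return list(_REGISTRY)


def is_gullible(norm: SocialNorm) -> bool:
    """True if the norm positively assesses a bad donor defecting on a bad recipient.

    Gullible norms can be exploited under private noisy information: a
    defector who is already recognized as bad regains standing by defecting
    against other ill-reputed players, so these norms fail to keep defectors
    labeled bad.  Exactly four of the leading eight are gullible (L3-L6).
    """
    return norm.assess(Judgment.BAD, Judgment.BAD, Action.D) == +1
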