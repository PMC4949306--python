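"""Contest micro-rules for winner-loser games.

Two individuals carry a resource holding potential (RHP) score. Each round
both decide, simultaneously and with full knowledge of both scores, whether
to fight or retreat: an individual with aggression threshold ``theta``
fights if and only if its RHP ratio to the opponent is at least ``theta``.
A fight is won with probability proportional to relative RHP, and outcomes
feed back multiplicatively into RHP — winning raises it, losing lowers it —
which is how winner and loser effects enter the model.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass


class Action(enum.Enum):
    FIGHT = "fight"
    RETREAT = "retreat"


class Outcome(enum.Enum):
    """Resolution of one pairwise interaction, from x's perspective."""

    X_WINS_FIGHT = "x_wins_fight"
    Y_WINS_FIGHT = "y_wins_fight"
    X_FIGHTS_Y_RETREATS = "x_fights_y_retreats"
    Y_FIGHTS_X_RETREATS = "y_fights_x_retreats"
    DOUBLE_KOWTOW = "double_kowtow"


@dataclass(frozen=True)
class GameParams:
    """Contest-rule constants.

    Parameters
    ----------
    V1 : float
        Proportional RHP gain of the winner of an escalated fight (>= 0).
    V2 : float
        Proportional RHP gain when the opponent retreats (>= 0).
    C1 : float
        Proportional RHP loss of the loser of a fight, in [0, 1).
    C2 : float
        Proportional RHP loss when retreating, in [0, 1).
    rhp_initial : float
        Common initial RHP score (> 0).
    T : int
        Contest horizon: number of interaction rounds (>= 1).

    The default preset used throughout the analytics sets ``V1 = V2 = V``,
    ``C1 = C`` and ``C2 = 0`` (retreating is free; having your opponent
    retreat is as good as beating it). Build it with :meth:`from_vc`.
    """

    V1: float
    V2: float
    C1: float
    C2: float
    rhp_initial: float = 10.0
    T: int = 20

    def __post_init__(self) -> None:
        if self.V1 < 0 or self.V2 < 0:
            raise ValueError("V1 and V2 must be non-negative")
        if not (0.0 <= self.C1 <= 1.0) or not (0.0 <= self.C2 <= 1.0):
            raise ValueError("C1 and C2 must lie in [0, 1]")
        if self.C1 >= 1.0 or self.C2 >= 1.0:
            # RHP would be annihilated and log payoffs diverge.
            raise ValueError("C1 = 1 or C2 = 1 is degenerate (log RHP undefined)")
        if self.rhp_initial <= 0:
            raise ValueError("rhp_initial must be positive")
        if int(self.T) != self.T or self.T < 1:
            raise ValueError("T must be an integer >= 1")

    @classmethod
    def from_vc(cls, V: float, C: float, rhp_initial: float = 10.0, T: int = 20) -> "GameParams":
        """Default preset: V1 = V2 = V, C1 = C, C2 = 0."""
        return cls(V1=V, V2=V, C1=C, C2=0.0, rhp_initial=rhp_initial, T=T)

    @property
    def is_default_preset(self) -> bool:
        return self.V1 == self.V2 and self.C2 == 0.0

    @property
    def V(self) -> float:
        if not self.is_default_preset:
            raise ValueError("V shorthand only defined for the default preset")
        return self.V1

    @property
    def C(self) -> float:
        if not self.is_default_preset:
            raise ValueError("C shorthand only defined for the default preset")
        return self.C1

    def to_dict(self) -> dict:
        return {
            "V1": self.V1, "V2": self.V2, "C1": self.C1, "C2": self.C2,
            "rhp_initial": self.rhp_initial, "T": self.T,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GameParams":
        """Build from a flat config mapping; (V, C) shorthand expands to the
        default preset and must not be mixed with explicit V1/C1 keys."""
        d = dict(d)
        has_short = "V" in d or "C" in d
        has_long = any(k in d for k in ("V1", "V2", "C1", "C2"))
        if has_short and has_long:
            raise ValueError("config mixes (V, C) shorthand with explicit V1/V2/C1/C2")
        kwargs = {}
        if "rhp_initial" in d:
            kwargs["rhp_initial"] = float(d["rhp_initial"])
        if "T" in d:
            kwargs["T"] = int(d["T"])
        if has_short:
            return cls.from_vc(float(d.get("V", 0.0)), float(d.get("C", 0.0)), **kwargs)
        return cls(
            V1=float(d.get("V1", 0.0)), V2=float(d.get("V2", 0.0)),
            C1=float(d.get("C1", 0.0)), C2=float(d.get("C2", 0.0)), **kwargs,
        )


@dataclass(frozen=True)
class ContestRecord:
    """Win/loss tally of one individual up to time t.

    ``a + b <= t`` because an individual may sit out rounds in groups of
    more than two.
    """

    a: int
    b: int
    t: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("win and loss counts must be non-negative")
        if self.a + self.b > self.t:
            raise ValueError("a + b cannot exceed the elapsed time t")


def decide_action(rhp_self: float, rhp_opp: float, theta: float) -> Action:
    """Fight iff rhp_self / rhp_opp >= theta (inclusive inequality)."""
    if rhp_self <= 0 or rhp_opp <= 0:
        raise ValueError("RHP scores must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return Action.FIGHT if rhp_self / rhp_opp >= theta else Action.RETREAT


def win_probability(rhp_x: float, rhp_y: float) -> float:
    """Probability that x wins an escalated fight: rhp_x / (rhp_x + rhp_y)."""
    if rhp_x <= 0 or rhp_y <= 0:
        raise ValueError("RHP scores must be positive")
    return rhp_x / (rhp_x + rhp_y)


def apply_outcome(
    rhp_x: float, rhp_y: float, outcome: Outcome, params: GameParams
) -> tuple[float, float]:
    """Multiplicative RHP update after one interaction.

    Fight winner x(1+V1), fight loser x(1-C1); fighter against a retreater
    x(1+V2), retreater x(1-C2); double kowtow: both x(1-C2).
    """
    if rhp_x <= 0 or rhp_y <= 0:
        raise ValueError("RHP scores must be positive")
    if outcome is Outcome.X_WINS_FIGHT:
        return rhp_x * (1 + params.V1), rhp_y * (1 - params.C1)
    if outcome is Outcome.Y_WINS_FIGHT:
        return rhp_x * (1 - params.C1), rhp_y * (1 + params.V1)
    if outcome is Outcome.X_FIGHTS_Y_RETREATS:
        return rhp_x * (1 + params.V2), rhp_y * (1 - params.C2)
    if outcome is Outcome.Y_FIGHTS_X_RETREATS:
        return rhp_x * (1 - params.C2), rhp_y * (1 + params.V2)
    if outcome is Outcome.DOUBLE_KOWTOW:
        return rhp_x * (1 - params.C2), rhp_y * (1 - params.C2)
    raise ValueError(f"unknown outcome: {outcome!r}")


def rhp_from_record(record: ContestRecord, params: GameParams) -> float:
    """RHP after ``a`` fight wins and ``b`` fight losses under the default
    preset: rhp_initial * (1+V)^a * (1-C)^b (path independent)."""
    if not params.is_default_preset:
        raise ValueError("rhp_from_record requires the default preset (V1=V2, C2=0)")
    V, C = params.V, params.C
    return params.rhp_initial * (1 + V) ** record.a * (1 - C) ** record.b


def log_rhp_from_counts(a: int, b: int, params: GameParams) -> float:
    """ln RHP after a wins / b losses, computed additively in log space."""
    if not params.is_default_preset:
        raise ValueError("requires the default preset (V1=V2, C2=0)")
    return (
        math.log(params.rhp_initial)
        + a * math.log1p(params.V)
        + b * math.log1p(-params.C)
    )
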