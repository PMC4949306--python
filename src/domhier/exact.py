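"""Exact two-player analysis of the threshold contest game.

Under the default preset (V1 = V2 = V, C2 = 0) a pair of mutually fighting
individuals is fully described by the win-loss difference d = a_t - b_t of
one of them: the RHP ratio is ((1+V)/(1-C))^d, so the decision rule and the
fight win probability depend on d alone. A threshold theta therefore maps
to an integer concession class k — the individual retreats exactly when its
losses exceed its wins by k — and the contest is an absorbing random walk
on d with state-dependent step probabilities. Everything in this module
(expected payoffs under two payoff functions, the stopping-time
distribution) is computed exactly by dynamic programming on (t, d); a
brute-force enumerator over the raw micro-rules serves as an independent
cross-check.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Iterator

from .dynamics import Action, GameParams, decide_action, win_probability

#: Sentinel concession class for theta > 1: retreat from the even start.
IMMEDIATE_RETREAT = 0


class PayoffKind(enum.Enum):
    """Terminal fitness measure.

    LOG_RHP: expected ln(RHP) at the horizon — appropriate when resources
    are plentiful and absolute ability matters.
    SHARE: expected share ln(RHP_x) / (ln(RHP_x) + ln(RHP_y)) — appropriate
    when a limited resource is split in proportion to relative ability
    (reproductive skew).
    """

    LOG_RHP = "log_rhp"
    SHARE = "share"


@dataclass(frozen=True)
class ThresholdClass:
    """An integer concession class k with its theta-interval.

    All thresholds in [theta_min, theta_sup) induce identical behaviour
    (retreat when wins - losses <= -k) and hence identical payoffs;
    theta_rep is the interval midpoint used as the canonical label.
    """

    k: int
    theta_min: float
    theta_sup: float
    theta_rep: float

    @property
    def immediate_retreat(self) -> bool:
        return self.k == IMMEDIATE_RETREAT


@dataclass(frozen=True)
class StoppingDistribution:
    """Exact law of the last mutual-fight round T_s, truncated at T.

    ``mass[t]`` is P(T_s = t); ``censored_mass`` is the probability that
    neither individual has conceded by the horizon.
    """

    mass: dict[int, float]
    censored_mass: float
    T: int

    def total(self) -> float:
        return sum(self.mass.values()) + self.censored_mass

    def cdf(self, t: int) -> float:
        return sum(p for s, p in self.mass.items() if s <= t)


def _log_ratio_step(V: float, C: float) -> float:
    """ln(1+V) - ln(1-C): the per-net-win increment of the log RHP ratio."""
    if V == 0.0 and C == 0.0:
        raise ValueError("V = C = 0 is degenerate: RHP never changes")
    return math.log1p(V) - math.log1p(-C)


def d_value(theta: float, V: float, C: float) -> float:
    """Continuous concession depth d = -ln(theta) / (ln(1+V) - ln(1-C)).

    theta = 0 returns +inf (never retreat); negative for theta > 1.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    step = _log_ratio_step(V, C)
    if theta == 0.0:
        return math.inf
    return -math.log(theta) / step


def theta_interval(k: int, V: float, C: float) -> tuple[float, float]:
    """[theta_min, theta_sup) mapping to class k: (q^k, q^(k-1)) with
    q = (1-C)/(1+V)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    _log_ratio_step(V, C)  # parameter validation
    q = (1 - C) / (1 + V)
    return q**k, q ** (k - 1)


def theta_rep(k: int, V: float, C: float) -> float:
    """Representative (mid-interval) threshold for class k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    _log_ratio_step(V, C)
    q = (1 - C) / (1 + V)
    return q**k * (2 + V - C) / (2 * (1 - C))


def class_from_theta(theta: float, V: float, C: float) -> ThresholdClass:
    """Map a threshold to its concession class.

    k = floor(d) + 1, which follows from applying the inclusive fight rule
    literally: with d non-integer this equals ceil(d); at exact interval
    endpoints (d integer, a measure-zero set) an individual with ratio
    exactly theta still fights, pushing it into the next class.
    theta > 1 yields the IMMEDIATE_RETREAT class (k = 0 sentinel).
    """
    if theta <= 0:
        raise ValueError("theta must be positive (theta = 0 never retreats; "
                         "no finite class exists)")
    d = d_value(theta, V, C)
    k = math.floor(d) + 1
    if k < 1:
        return ThresholdClass(IMMEDIATE_RETREAT, 1.0, math.inf, theta)
    lo, hi = theta_interval(k, V, C)
    return ThresholdClass(k, lo, hi, theta_rep(k, V, C))


def win_prob_from_diff(d: float, V: float, C: float) -> float:
    """Fight win probability given win-loss difference d: r^d / (r^d + 1)
    with r = (1+V)/(1-C), evaluated stably in log space."""
    step = math.log1p(V) - math.log1p(-C)
    return 1.0 / (1.0 + math.exp(-d * step))


# ---------------------------------------------------------------------------
# Exact dynamic programme on (t, d)

@dataclass(frozen=True)
class _Terminal:
    """One aggregated terminal event of the absorbing walk."""

    prob: float
    log_rhp_x: float
    log_rhp_y: float
    stop_time: int | None  # None for censored (no concession by T)


def _require_classes(k_x: int, k_y: int) -> None:
    for k in (k_x, k_y):
        if int(k) != k or k < 0:
            raise ValueError("concession classes must be integers >= 0 "
                             "(0 = immediate retreat)")


def _walk_terminals(k_x: int, k_y: int, params: GameParams) -> Iterator[_Terminal]:
    """Enumerate terminal events of the mutual-fight walk with probabilities.

    The walk starts at d = 0 and while -k_x < d < k_y both individuals
    fight; x wins a round with probability W(d). Absorption at d = -k_x
    freezes x (it retreats every remaining round, C2 = 0) while y gains a
    factor (1+V) per remaining round; symmetrically at d = +k_y. Paths
    still interior at T are censored.
    """
    _require_classes(k_x, k_y)
    if not params.is_default_preset:
        raise ValueError("exact analysis requires the default preset "
                         "(V1 = V2, C2 = 0); use the Monte-Carlo engine otherwise")
    V, C, T = params.V, params.C, params.T
    if V == 0.0 and C == 0.0:
        raise ValueError("V = C = 0 is degenerate: RHP never changes and "
                         "thresholds have no class mapping")
    lv, lc = math.log1p(V), math.log1p(-C)
    L0 = math.log(params.rhp_initial)

    if k_x == IMMEDIATE_RETREAT or k_y == IMMEDIATE_RETREAT:
        # No mutual fight ever happens; outcomes are deterministic.
        if k_x == IMMEDIATE_RETREAT and k_y == IMMEDIATE_RETREAT:
            yield _Terminal(1.0, L0, L0, None)  # double kowtow, C2 = 0
        elif k_x == IMMEDIATE_RETREAT:
            yield _Terminal(1.0, L0, L0 + T * lv, None)
        else:
            yield _Terminal(1.0, L0 + T * lv, L0, None)
        return

    # alpha[d] = P(interior at time t with difference d); (t + d) is even.
    alpha: dict[int, float] = {0: 1.0}
    for t in range(1, T + 1):
        nxt: dict[int, float] = {}
        for d, p in alpha.items():
            w = win_prob_from_diff(d, V, C)
            for d2, p2 in ((d + 1, p * w), (d - 1, p * (1.0 - w))):
                if p2 == 0.0:
                    continue
                a, b = (t + d2) // 2, (t - d2) // 2  # x's wins / losses
                if d2 <= -k_x:
                    # x concedes at time t; y fights alone thereafter.
                    yield _Terminal(
                        p2,
                        L0 + a * lv + b * lc,
                        L0 + b * lv + a * lc + (T - t) * lv,
                        t,
                    )
                elif d2 >= k_y:
                    yield _Terminal(
                        p2,
                        L0 + a * lv + b * lc + (T - t) * lv,
                        L0 + b * lv + a * lc,
                        t,
                    )
                else:
                    nxt[d2] = nxt.get(d2, 0.0) + p2
        alpha = nxt
        if not alpha:
            break
    for d, p in alpha.items():  # censored at the horizon
        a, b = (T + d) // 2, (T - d) // 2
        yield _Terminal(p, L0 + a * lv + b * lc, L0 + b * lv + a * lc, None)


def _payoff_from_terminals(
    terminals: Iterator[_Terminal], kind: PayoffKind
) -> float:
    total = 0.0
    for term in terminals:
        if kind is PayoffKind.LOG_RHP:
            total += term.prob * term.log_rhp_x
        else:
            lx, ly = term.log_rhp_x, term.log_rhp_y
            if lx <= 0.0 or ly <= 0.0:
                raise ValueError(
                    "terminal log RHP <= 0 on a reachable path: the share "
                    f"payoff is undefined (ln RHP_x = {lx:.4f}, ln RHP_y = {ly:.4f})"
                )
            total += term.prob * lx / (lx + ly)
    return total


def expected_payoff(
    k_x: int, k_y: int, params: GameParams, kind: PayoffKind = PayoffKind.LOG_RHP
) -> float:
    """Exact expected payoff of x playing class k_x against y playing k_y.

    Classes are integers >= 1, or IMMEDIATE_RETREAT (0). Complexity
    O(T * (k_x + k_y)); requires the default preset.
    """
    return _payoff_from_terminals(_walk_terminals(k_x, k_y, params), kind)


def stopping_distribution(
    k_x: int, k_y: int, params: GameParams
) -> StoppingDistribution:
    """Exact first-passage law of the last mutual-fight round T_s."""
    _require_classes(k_x, k_y)
    if k_x == IMMEDIATE_RETREAT or k_y == IMMEDIATE_RETREAT:
        raise ValueError("stopping time is defined for fighting classes k >= 1")
    mass: dict[int, float] = {}
    censored = 0.0
    for term in _walk_terminals(k_x, k_y, params):
        if term.stop_time is None:
            censored += term.prob
        else:
            mass[term.stop_time] = mass.get(term.stop_time, 0.0) + term.prob
    return StoppingDistribution(mass=mass, censored_mass=censored, T=params.T)


def stopping_support(k_x: int, k_y: int) -> Callable[[int], bool]:
    """Closed-form membership predicate for the support of T_s.

    x can first concede at times k_x, k_x + 2, ...; y at k_y, k_y + 2, ...;
    the support of T_s = min of the two is the union of these parity
    sequences — except k_x = k_y = 1, where the single interior state is
    left at the very first round, so T_s = 1 surely.
    """
    _require_classes(k_x, k_y)
    if k_x == IMMEDIATE_RETREAT or k_y == IMMEDIATE_RETREAT:
        raise ValueError("stopping support is defined for fighting classes k >= 1")

    if k_x == 1 and k_y == 1:
        return lambda t: t == 1

    def member(t: int) -> bool:
        return (t >= k_x and (t - k_x) % 2 == 0) or (t >= k_y and (t - k_y) % 2 == 0)

    return member


# ---------------------------------------------------------------------------
# Independent brute-force oracle over the raw micro-rules

_BRUTEFORCE_T_MAX = 14


def expected_payoff_bruteforce(
    k_x: int, k_y: int, params: GameParams, kind: PayoffKind = PayoffKind.LOG_RHP
) -> float:
    """Expected payoff by exhaustive enumeration of fight outcomes.

    Replays the per-round micro-rules (decide, win probability, RHP update)
    with the representative thresholds of the two classes, branching on
    every fight outcome. Never touches the (t, d) reduction, so it is an
    independent check of :func:`expected_payoff`. Refuses T > 14: use the
    dynamic programme for longer horizons.
    """
    _require_classes(k_x, k_y)
    if not params.is_default_preset:
        raise ValueError("brute force assumes the default preset (V1 = V2, C2 = 0)")
    if params.T > _BRUTEFORCE_T_MAX:
        raise ValueError(
            f"T = {params.T} > {_BRUTEFORCE_T_MAX}: enumeration is exponential; "
            "use expected_payoff (dynamic programme) instead"
        )
    V, C = params.V, params.C
    th_x = 2.0 if k_x == IMMEDIATE_RETREAT else theta_rep(k_x, V, C)
    th_y = 2.0 if k_y == IMMEDIATE_RETREAT else theta_rep(k_y, V, C)

    def leaf(prob: float, rx: float, ry: float) -> float:
        if kind is PayoffKind.LOG_RHP:
            return prob * math.log(rx)
        lx, ly = math.log(rx), math.log(ry)
        if lx <= 0.0 or ly <= 0.0:
            raise ValueError("terminal log RHP <= 0: share payoff undefined")
        return prob * lx / (lx + ly)

    def recurse(t: int, rx: float, ry: float, prob: float) -> float:
        if t > params.T:
            return leaf(prob, rx, ry)
        ax = decide_action(rx, ry, th_x)
        ay = decide_action(ry, rx, th_y)
        if ax is Action.FIGHT and ay is Action.FIGHT:
            w = win_probability(rx, ry)
            return recurse(t + 1, rx * (1 + V), ry * (1 - C), prob * w) + recurse(
                t + 1, rx * (1 - C), ry * (1 + V), prob * (1.0 - w)
            )
        if ax is Action.FIGHT:  # y retreats
            return recurse(t + 1, rx * (1 + V), ry, prob)
        if ay is Action.FIGHT:  # x retreats
            return recurse(t + 1, rx, ry * (1 + V), prob)
        return recurse(t + 1, rx, ry, prob)  # double kowtow, C2 = 0

    return recurse(1, params.rhp_initial, params.rhp_initial, 1.0)


def payoff_pair(
    k_x: int, k_y: int, params: GameParams, kind: PayoffKind = PayoffKind.LOG_RHP
) -> tuple[float, float]:
    """Both players' expected payoffs in one pass of the dynamic programme."""
    ex = ey = 0.0
    for term in _walk_terminals(k_x, k_y, params):
        if kind is PayoffKind.LOG_RHP:
            ex += term.prob * term.log_rhp_x
            ey += term.prob * term.log_rhp_y
        else:
            lx, ly = term.log_rhp_x, term.log_rhp_y
            if lx <= 0.0 or ly <= 0.0:
                raise ValueError("terminal log RHP <= 0: share payoff undefined")
            ex += term.prob * lx / (lx + ly)
            ey += term.prob * ly / (lx + ly)
    return ex, ey
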