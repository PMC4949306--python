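"""Payoff matrices, pure-ESS detection and the (V, C) scaling law.

A pure strategy (a concession class on the grid) is an evolutionarily
stable strategy when, fixed in the population, no rare alternative earns
more against it. For a payoff matrix this is the diagonal rule: the
diagonal entry must strictly exceed every other entry in its column
(condition 1); on an exact tie the invader must do worse against itself
than the incumbent does against it (condition 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynamics import GameParams
from .exact import (
    IMMEDIATE_RETREAT,
    PayoffKind,
    class_from_theta,
    d_value,
    expected_payoff,
    theta_interval,
    theta_rep,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PayoffMatrix:
    """Row player's expected payoff for every ordered pair of classes."""

    grid: tuple[int, ...]          # concession classes; 0 = immediate retreat
    values: np.ndarray             # values[i, j] = E[row class i vs column class j]
    kind: PayoffKind
    params: GameParams

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.grid):
            raise ValueError("values must be square and match the grid")

    @property
    def n(self) -> int:
        return len(self.grid)

    def theta_rep_of(self, index: int) -> float:
        k = self.grid[index]
        if k == IMMEDIATE_RETREAT:
            raise ValueError("immediate retreat has no representative threshold")
        return theta_rep(k, self.params.V, self.params.C)


@dataclass(frozen=True)
class ESSResult:
    """Outcome of the diagonal rule on a payoff matrix."""

    kind: str                                  # "PURE" or "NONE_FOUND"
    indices: tuple[int, ...] = ()
    classes: tuple[int, ...] = ()
    theta_rep: tuple[float, ...] = ()
    theta_interval: tuple[tuple[float, float], ...] = ()
    condition: tuple[str, ...] = ()            # "strict" or "tie+condition2"

    @property
    def found(self) -> bool:
        return self.kind == "PURE"


def build_matrix(
    k_grid: list[int], params: GameParams, kind: PayoffKind = PayoffKind.LOG_RHP
) -> PayoffMatrix:
    """Expected-payoff matrix over a grid of distinct concession classes."""
    grid = tuple(int(k) for k in k_grid)
    if not grid:
        raise ValueError("k_grid must be non-empty")
    if len(set(grid)) != len(grid):
        raise ValueError("k_grid must contain distinct classes")
    values = np.array(
        [[expected_payoff(ki, kj, params, kind) for kj in grid] for ki in grid]
    )
    return PayoffMatrix(grid=grid, values=values, kind=kind, params=params)


def default_grid(V: float, C: float, k_max: int = 8) -> list[int]:
    """Classes 1..k_max, with immediate retreat prepended when V = 0
    (fighting then has no upside and conceding at once is a live strategy)."""
    grid = list(range(1, k_max + 1))
    if V == 0.0:
        grid.insert(0, IMMEDIATE_RETREAT)
    return grid


def best_response(matrix: PayoffMatrix, column: int, tol: float = 1e-9) -> set[int]:
    """Row indices attaining the maximum of the given column (ties within tol)."""
    col = matrix.values[:, column]
    top = col.max()
    return {int(i) for i in np.nonzero(col >= top - tol)[0]}


def find_pure_ess(matrix: PayoffMatrix, tol: float = 1e-9) -> ESSResult:
    """Apply the diagonal rule to every grid point.

    Strict condition 1: values[i, i] > values[j, i] for all j != i (with a
    small tolerance so floating-point noise does not manufacture ties).
    Exact ties fall through to condition 2: E[i vs j] > E[j vs j] for every
    tying invader j. Mixed ESSs are out of scope; if no pure strategy
    qualifies the result is NONE_FOUND.
    """
    V, C = matrix.params.V, matrix.params.C
    hits: list[tuple[int, str]] = []
    for i in range(matrix.n):
        col = matrix.values[:, i]
        diag = col[i]
        others = np.delete(col, i)
        if others.size == 0:
            hits.append((i, "strict"))  # 1x1 grid: vacuously stable
            continue
        gap = diag - others.max()
        if gap > tol:
            hits.append((i, "strict"))
        elif gap >= -tol:
            tying = [j for j in range(matrix.n)
                     if j != i and abs(col[j] - diag) <= tol]
            if tying and all(
                matrix.values[i, j] > matrix.values[j, j] + tol for j in tying
            ):
                hits.append((i, "tie+condition2"))
    if not hits:
        return ESSResult(kind="NONE_FOUND")
    idx = tuple(i for i, _ in hits)
    classes = tuple(matrix.grid[i] for i in idx)
    reps = tuple(
        theta_rep(k, V, C) if k != IMMEDIATE_RETREAT else float("nan")
        for k in classes
    )
    intervals = tuple(
        theta_interval(k, V, C) if k != IMMEDIATE_RETREAT else (1.0, float("inf"))
        for k in classes
    )
    return ESSResult(
        kind="PURE",
        indices=idx,
        classes=classes,
        theta_rep=reps,
        theta_interval=intervals,
        condition=tuple(c for _, c in hits),
    )


def ess_sweep(
    V_values,
    C_values,
    kind: PayoffKind = PayoffKind.LOG_RHP,
    k_max: int = 8,
    rhp_initial: float = 10.0,
    T: int = 20,
):
    """Find the pure ESS over a grid of (V, C); returns a tidy DataFrame
    with columns V, C, payoff_kind, ess_k, theta_rep, theta_min, theta_sup.

    Degenerate combinations (V = C = 0) are skipped with a warning;
    ess_k = 0 denotes immediate retreat, ess_k = -1 no pure ESS found.
    """
    import pandas as pd

    rows = []
    for V in V_values:
        for C in C_values:
            if V == 0.0 and C == 0.0:
                logger.warning("skipping degenerate combination V = C = 0")
                continue
            params = GameParams.from_vc(V, C, rhp_initial=rhp_initial, T=T)
            matrix = build_matrix(default_grid(V, C, k_max), params, kind)
            res = find_pure_ess(matrix)
            if not res.found:
                rows.append((V, C, kind.value, -1, np.nan, np.nan, np.nan))
                continue
            k = res.classes[0]
            if k == IMMEDIATE_RETREAT:
                rows.append((V, C, kind.value, 0, np.nan, np.nan, np.nan))
            else:
                lo, hi = theta_interval(k, V, C)
                rows.append((V, C, kind.value, k, theta_rep(k, V, C), lo, hi))
    return pd.DataFrame(
        rows,
        columns=["V", "C", "payoff_kind", "ess_k", "theta_rep", "theta_min", "theta_sup"],
    )


def scale_strategy(theta: float, alpha: float) -> float:
    """Rescaled threshold theta' = theta**alpha, the strategy that behaves
    like theta when (V, C) are replaced by (alpha*V, alpha*C) with small
    V, C (first-order in the log-ratio step)."""
    if theta <= 0 or alpha <= 0:
        raise ValueError("theta and alpha must be positive")
    return theta**alpha


@dataclass(frozen=True)
class ScalingReport:
    """Exact check of the approximate scale invariance of the class map."""

    theta: float
    alpha: float
    V: float
    C: float
    k_original: int
    k_scaled: int
    d_original: float
    d_scaled: float
    class_preserved: bool
    d_abs_difference: float


def scaling_consistency(
    theta: float, V: float, C: float, alpha: float, vc_guard: float = 0.3
) -> ScalingReport:
    """Compare the concession class of theta under (V, C) with that of
    theta**alpha under (alpha*V, alpha*C).

    The invariance is first-order in V + C; ``vc_guard`` bounds V + C
    (before and after scaling) for the approximation to be meaningful —
    beyond it a warning is logged rather than an error raised.
    """
    Va, Ca = alpha * V, alpha * C
    if Ca >= 1.0:
        raise ValueError(f"scaled C = {Ca} >= 1 is out of range")
    if V + C > vc_guard or Va + Ca > vc_guard:
        logger.warning(
            "V + C = %.3f (scaled %.3f) exceeds the small-parameter guard %.2f; "
            "the scaling law may be unreliable here", V + C, Va + Ca, vc_guard,
        )
    theta_scaled = scale_strategy(theta, alpha)
    c1 = class_from_theta(theta, V, C)
    c2 = class_from_theta(theta_scaled, Va, Ca)
    d1 = d_value(theta, V, C)
    d2 = d_value(theta_scaled, Va, Ca)
    return ScalingReport(
        theta=theta, alpha=alpha, V=V, C=C,
        k_original=c1.k, k_scaled=c2.k,
        d_original=d1, d_scaled=d2,
        class_preserved=c1.k == c2.k,
        d_abs_difference=abs(d1 - d2),
    )
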