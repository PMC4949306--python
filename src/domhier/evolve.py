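"""Evolutionary simulation of aggression thresholds in groups of N.

Exact payoff analysis is tractable only for pairs; for larger groups the
evolutionarily stable aggression threshold is found by simulation. Each
generation, many groups of N individuals are formed, every individual
drawing a threshold from the current population frequencies. Within a
group, a fixed number of pairwise contests is played (a uniformly random
pair per round, resolved by the micro-rules in :mod:`domhier.dynamics`),
and each individual's terminal ln(RHP) is credited to its strategy.
Strategy frequencies are then replaced by the normalised accumulated
payoffs — discrete frequency-proportional-to-fitness dynamics without
mutation — and the process repeats. The mass typically concentrates on a
single grid strategy, which is declared the ESS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import GameParams

logger = logging.getLogger(__name__)

DEFAULT_THETA_GRID = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass(frozen=True)
class EvolutionConfig:
    """Simulation knobs.

    Desk-scale defaults (500 groups x 200 contests x 300 generations) keep
    a run in the minutes range; the study-scale setting (10,000 groups and
    10,000 generations) is available via :meth:`paper_scale`.
    """

    params: GameParams
    N: int = 2
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID
    n_groups: int = 500
    contests_per_group: int = 200
    n_generations: int = 300
    seed: int = 0
    payoff_floor: float = 0.0
    concentration_tol: float = 1e-3
    early_stop: bool | None = None  # None: on below 5000 generations
    early_stop_patience: int = 20

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("group size N must be >= 2")
        if min(self.n_groups, self.contests_per_group, self.n_generations) < 1:
            raise ValueError("all simulation counts must be >= 1")
        grid = tuple(float(t) for t in self.theta_grid)
        if any(t <= 0 for t in grid):
            raise ValueError("theta grid values must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("theta grid must be strictly increasing")
        object.__setattr__(self, "theta_grid", grid)

    @classmethod
    def paper_scale(cls, params: GameParams, N: int = 2, seed: int = 0) -> "EvolutionConfig":
        """Study-scale run: 10,000 groups x 200 contests x 10,000 generations."""
        return cls(params=params, N=N, n_groups=10_000, contests_per_group=200,
                   n_generations=10_000, seed=seed, early_stop=False)

    @property
    def early_stop_effective(self) -> bool:
        if self.early_stop is None:
            return self.n_generations < 5000
        return self.early_stop


@dataclass
class PopulationState:
    """Strategy frequencies and the per-generation payoff accumulator H."""

    p: np.ndarray
    generation: int = 0
    H: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1 or self.p.size == 0:
            raise ValueError("p must be a non-empty vector")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("p must be a probability vector")
        if self.H is None:
            self.H = np.zeros_like(self.p)


@dataclass(frozen=True)
class EvolutionResult:
    """Final state, full frequency trajectory and the declared ESS."""

    config: EvolutionConfig
    final_p: np.ndarray
    trajectory: np.ndarray          # (generations_run + 1, n_strategies)
    generations_run: int
    mode_theta: float
    mean_theta: float
    concentration: float            # max of final_p
    declared_ess: float
    concentrated: bool


def _simulate_groups(
    log_theta: np.ndarray, params: GameParams, contests: int, rng: np.random.Generator
) -> np.ndarray:
    """Play ``contests`` rounds in each of G groups simultaneously.

    ``log_theta`` has shape (G, N): each individual's log aggression
    threshold. Returns the (G, N) array of terminal ln(RHP). RHP is kept in
    log space throughout; the fight decision compares log-RHP differences
    to log thresholds and the fight win probability is a logistic in the
    log-RHP difference.
    """
    G, N = log_theta.shape
    lrhp = np.full((G, N), math.log(params.rhp_initial))
    lv1 = math.log1p(params.V1)
    lv2 = math.log1p(params.V2)
    lc1 = math.log1p(-params.C1)
    lc2 = math.log1p(-params.C2)
    rows = np.arange(G)
    for _ in range(contests):
        i = rng.integers(0, N, size=G)
        j = (i + rng.integers(1, N, size=G)) % N  # uniform unordered pair
        li = lrhp[rows, i]
        lj = lrhp[rows, j]
        fight_i = li - lj >= log_theta[rows, i]
        fight_j = lj - li >= log_theta[rows, j]
        both = fight_i & fight_j
        i_wins = rng.random(G) < 1.0 / (1.0 + np.exp(lj - li))
        only_i = fight_i & ~fight_j
        only_j = fight_j & ~fight_i
        di = np.where(
            both, np.where(i_wins, lv1, lc1), np.where(only_i, lv2, lc2)
        )
        dj = np.where(
            both, np.where(i_wins, lc1, lv1), np.where(only_j, lv2, lc2)
        )
        lrhp[rows, i] = li + di
        lrhp[rows, j] = lj + dj
    return lrhp


def play_group(
    strategies: list[float],
    params: GameParams,
    contests: int,
    rng: np.random.Generator,
) -> list[float]:
    """Simulate one group; returns each individual's final ln(RHP).

    ``strategies`` are the N aggression thresholds (theta = 0 means always
    fight). Accepts any parameter preset, including V1 != V2 or C2 > 0.
    """
    thetas = np.asarray(strategies, dtype=float)
    if thetas.size < 2:
        raise ValueError("a group needs at least two individuals")
    if np.any(thetas < 0):
        raise ValueError("thresholds must be non-negative")
    with np.errstate(divide="ignore"):
        log_theta = np.log(thetas)[None, :]  # theta = 0 -> -inf: always fight
    return _simulate_groups(log_theta, params, contests, rng)[0].tolist()


def run_generation(
    state: PopulationState, config: EvolutionConfig, rng: np.random.Generator
) -> PopulationState:
    """One generation of the frequency dynamics.

    Samples N strategies i.i.d. from p for each group, plays the contests,
    credits terminal ln(RHP) to each strategy's accumulator H and replaces
    p by H / sum(H). Payoffs below ``payoff_floor`` are clamped (with a
    warning): the proportional update is ill-defined for negative fitness.
    """
    grid = np.asarray(config.theta_grid)
    idx = rng.choice(grid.size, size=(config.n_groups, config.N), p=state.p)
    log_theta = np.log(grid)[idx]
    payoffs = _simulate_groups(log_theta, config.params, config.contests_per_group, rng)
    if np.any(payoffs < config.payoff_floor):
        n_clamped = int(np.sum(payoffs < config.payoff_floor))
        logger.warning(
            "clamped %d negative payoffs to the floor %.3g "
            "(generation %d)", n_clamped, config.payoff_floor, state.generation,
        )
        payoffs = np.maximum(payoffs, config.payoff_floor)
    H = np.bincount(idx.ravel(), weights=payoffs.ravel(), minlength=grid.size)
    total = H.sum()
    if total <= 0:
        raise ValueError(
            "total accumulated payoff is non-positive; the proportional "
            "frequency update is undefined (raise payoff_floor or rhp_initial)"
        )
    return PopulationState(p=H / total, generation=state.generation + 1, H=H)


def run_evolution(config: EvolutionConfig) -> EvolutionResult:
    """Iterate the frequency dynamics and declare the evolved ESS.

    Runs for ``n_generations`` or, when early stopping is active, until the
    mass has been concentrated on one strategy (max p >= 1 - tol) for
    ``early_stop_patience`` consecutive generations. The declared ESS is
    the modal strategy when concentrated (max p >= 0.5), otherwise the
    p-weighted mean threshold.
    """
    rng = np.random.default_rng(config.seed)
    grid = np.asarray(config.theta_grid)
    state = PopulationState(p=np.full(grid.size, 1.0 / grid.size))
    trajectory = [state.p.copy()]
    streak = 0
    for _ in range(config.n_generations):
        state = run_generation(state, config, rng)
        trajectory.append(state.p.copy())
        if config.early_stop_effective:
            if state.p.max() >= 1.0 - config.concentration_tol:
                streak += 1
                if streak >= config.early_stop_patience:
                    break
            else:
                streak = 0
    final_p = state.p
    mode_theta = float(grid[int(np.argmax(final_p))])
    mean_theta = float(np.dot(final_p, grid))
    concentration = float(final_p.max())
    concentrated = concentration >= 0.5
    return EvolutionResult(
        config=config,
        final_p=final_p,
        trajectory=np.asarray(trajectory),
        generations_run=state.generation,
        mode_theta=mode_theta,
        mean_theta=mean_theta,
        concentration=concentration,
        declared_ess=mode_theta if concentrated else mean_theta,
        concentrated=concentrated,
    )


def summarize(result: EvolutionResult) -> dict:
    """JSON-ready summary of an evolution run."""
    return {
        "declared_ess": result.declared_ess,
        "mode_theta": result.mode_theta,
        "mean_theta": result.mean_theta,
        "concentration": result.concentration,
        "concentrated": result.concentrated,
        "generations_run": result.generations_run,
        "final_p": {
            f"{t:g}": float(p)
            for t, p in zip(result.config.theta_grid, result.final_p)
        },
        "config": {
            "N": result.config.N,
            "theta_grid": list(result.config.theta_grid),
            "n_groups": result.config.n_groups,
            "contests_per_group": result.config.contests_per_group,
            "n_generations": result.config.n_generations,
            "seed": result.config.seed,
            "params": result.config.params.to_dict(),
        },
    }
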