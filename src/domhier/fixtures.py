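"""Deterministic random parameter sets for property tests.

Every fixture is a valid default-preset parameter combination; the named
presets used in the worked examples (V = C = 0.1 with T = 20; V = 0.02,
C = 0.04; the N=4 sweep grid values) are always included so that property
tests exercise them alongside the random draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import GameParams

V_RANGE = (0.01, 0.3)
C_RANGE = (0.01, 0.3)
T_RANGE = (4, 24)


@dataclass(frozen=True)
class Fixture:
    name: str
    params: GameParams
    k_grid: tuple[int, ...]


def named_presets() -> list[Fixture]:
    return [
        Fixture("example_v01_c01", GameParams.from_vc(0.1, 0.1, T=20), tuple(range(1, 9))),
        Fixture("scaling_v002_c004", GameParams.from_vc(0.02, 0.04, T=20), tuple(range(1, 9))),
        Fixture("table3_v01_c01", GameParams.from_vc(0.1, 0.1, T=20), tuple(range(1, 9))),
        Fixture("table3_v005_c005", GameParams.from_vc(0.05, 0.05, T=20), tuple(range(1, 9))),
        Fixture("table3_v015_c015", GameParams.from_vc(0.15, 0.15, T=20), tuple(range(1, 9))),
    ]


def make_fixtures(seed: int, n_random: int = 20) -> list[Fixture]:
    """Named presets plus ``n_random`` seeded random parameter sets."""
    rng = np.random.default_rng(seed)
    out = named_presets()
    for i in range(n_random):
        V = float(rng.uniform(*V_RANGE))
        C = float(rng.uniform(*C_RANGE))
        T = int(rng.integers(T_RANGE[0], T_RANGE[1] + 1))
        k_max = int(rng.integers(2, 6))
        out.append(
            Fixture(f"random_{i}", GameParams.from_vc(V, C, T=T), tuple(range(1, k_max + 1)))
        )
    return out
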