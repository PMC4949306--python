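import numpy as np
import pytest

from domhier import GameParams

# Published expected-payoff matrix (ln RHP payoff, V = C = 0.1, T = 20,
# initial RHP 10) over concession classes k = 1..8. Rows: focal player's
# class; columns: opponent's class. Values as printed (2 dp of precision).
PRINTED_LOG_MATRIX = np.array([
    [3.20, 2.87, 2.73, 2.65, 2.60, 2.58, 2.56, 2.54],
    [3.44, 3.06, 2.87, 2.76, 2.70, 2.66, 2.62, 2.60],
    [3.50, 3.10, 2.89, 2.77, 2.69, 2.65, 2.61, 2.60],
    [3.51, 3.08, 2.87, 2.74, 2.67, 2.62, 2.56, 2.56],
    [3.50, 3.05, 2.84, 2.70, 2.62, 2.57, 2.54, 2.52],
    [3.46, 3.02, 2.79, 2.66, 2.60, 2.53, 2.50, 2.47],
    [3.43, 2.99, 2.77, 2.62, 2.56, 2.50, 2.48, 2.45],
    [3.42, 2.95, 2.73, 2.60, 2.51, 2.48, 2.44, 2.41],
])

# Published resource-share matrix for the same setting (4 dp as printed).
PRINTED_SHARE_MATRIX = np.array([
    [0.5000, 0.4585, 0.4417, 0.4353, 0.4344, 0.4354, 0.4360, 0.4385],
    [0.5415, 0.5000, 0.4825, 0.4777, 0.4765, 0.4777, 0.4806, 0.4825],
    [0.5583, 0.5175, 0.5000, 0.4941, 0.4928, 0.4949, 0.4973, 0.4999],
    [0.5647, 0.5223, 0.5059, 0.5000, 0.4992, 0.5013, 0.5034, 0.5066],
    [0.5656, 0.5235, 0.5072, 0.5008, 0.5000, 0.5014, 0.5046, 0.5077],
    [0.5646, 0.5223, 0.5051, 0.4987, 0.4986, 0.5000, 0.5026, 0.5054],
    [0.5640, 0.5194, 0.5027, 0.4966, 0.4954, 0.4974, 0.5000, 0.5033],
    [0.5615, 0.5175, 0.5001, 0.4934, 0.4923, 0.4946, 0.4967, 0.5000],
])

# Published representative thresholds for k = 1..8 at V = C = 0.1 (2 dp).
PRINTED_THETA_REP = [0.91, 0.74, 0.61, 0.50, 0.41, 0.33, 0.27, 0.22]


@pytest.fixture(scope="session")
def params_example() -> GameParams:
    """The worked example's parameters: V = C = 0.1, T = 20, RHP0 = 10."""
    return GameParams.from_vc(0.1, 0.1, rhp_initial=10.0, T=20)


@pytest.fixture(scope="session")
def params_scaling() -> GameParams:
    """The scaling-law example's baseline: V = 0.02, C = 0.04."""
    return GameParams.from_vc(0.02, 0.04, rhp_initial=10.0, T=20)
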