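import numpy as np
import pytest

from triphen import ModelParams, find_fixed_points, reduced_potential, stationary_x1

# Reference parameter set used throughout: the tristable operating point
# of the circuit (a1 = 0.8, a2 = 0.85 with standard kinetic constants).


@pytest.fixture(scope="session")
def params():
    return ModelParams(a1=0.8, a2=0.85)


@pytest.fixture(scope="session")
def fixed_points(params):
    return find_fixed_points(params)


@pytest.fixture(scope="session")
def attractors(fixed_points):
    return {fp.phenotype: fp for fp in fixed_points if fp.stability == "stable"}


@pytest.fixture(scope="session")
def potential(params):
    """Reduced double-well potential on the high-x1 branch."""
    return reduced_potential(params, stationary_x1(params, "high"))


# Frozen oracle values: roots of F1/F2 computed by dense bracketing +
# Brent bisection at xtol 1e-12 (independent scalar implementation).
ORACLE_STABLE = {
    "L": (0.2409107754260, 1.7937608656547),
    "B": (0.9409199919319, 0.0742634652775),
    "S": (0.9409199919319, 0.8211074827595),
}
ORACLE_SADDLES = [
    (0.3374262692191, 1.6714649505520),
    (0.9409199919319, 0.5016494938106),
]
ORACLE_REDUCED = {  # stationary points of the x0-clamped x2 dynamics
    "x2_B": 0.0742634652775,
    "x2_u": 0.5016494938105,
    "x2_S": 0.8211074827597,
}
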