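import itertools

import numpy as np
import pytest

from phasecluster.phase_io import PhaseSet, phases_from_model
from phasecluster.synthetic import make_toy_structure


def make_random_phase_set(
    n: int, seed: int, id: str = "rand", fom: float | np.ndarray = 1.0
) -> PhaseSet:
    """Phase set over a synthetic Miller-index grid with uniform phases."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil((2 * n) ** (1 / 3))) + 2
    hkl = np.array(
        [h for h in itertools.product(range(-side, side + 1), repeat=3) if h != (0, 0, 0)]
    )[:n]
    assert len(hkl) == n
    return PhaseSet(
        id=id,
        cell=(30.0, 30.0, 30.0, 90.0, 90.0, 90.0),
        sg_symbol="P1",
        hkl=hkl,
        F=rng.lognormal(0.0, 0.5, n),
        fom=np.full(n, fom) if np.isscalar(fom) else fom,
        phi=rng.random(n) * 360.0,
    )


@pytest.fixture(scope="session")
def model_p212121():
    return make_toy_structure("P212121", 40, seed=7)


@pytest.fixture(scope="session")
def truth_p212121(model_p212121):
    return phases_from_model(model_p212121, 2.5, id="truth")


@pytest.fixture(scope="session")
def model_c2():
    return make_toy_structure("C2", 25, seed=11)


@pytest.fixture(scope="session")
def truth_c2(model_c2):
    return phases_from_model(model_c2, 2.5, id="truth")


@pytest.fixture(scope="session")
def model_p1():
    return make_toy_structure("P1", 18, seed=13)


@pytest.fixture(scope="session")
def truth_p1(model_p1):
    return phases_from_model(model_p1, 2.5, id="truth")
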