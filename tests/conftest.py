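import numpy as np
import pytest

from actomyosim import Domain, Filament, Frame, MotorMinifilament


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def domain():
    return Domain()


def make_random_frame(rng, n_fil=5, n_beads=4, n_motors=0, domain=None, spread=600.0):
    """Small random frame with straight filaments (and optional bound-free
    motors) fully inside the box."""
    domain = domain or Domain()
    fils = []
    for i in range(n_fil):
        while True:
            centre = rng.uniform([300, 300, 50], [1700, 1700, 150])
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ts = np.linspace(-0.5, 0.5, n_beads) * min(spread, 180.0)
            beads = centre + np.outer(ts, d)
            if domain.contains(beads):
                fils.append(Filament(id=f"f{i}", beads=beads))
                break
    motors = []
    for j in range(n_motors):
        p = rng.uniform([100, 100, 20], [1900, 1900, 180])
        motors.append(
            MotorMinifilament(
                id=f"m{j}", species="myosin", state="diffusing",
                endpoints=np.vstack([p, p]), n_heads=20,
            )
        )
    return Frame(time=0.0, filaments=fils, motors=motors, linkers=[], domain=domain)


@pytest.fixture
def random_frame(rng):
    return make_random_frame(rng)
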