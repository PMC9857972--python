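import numpy as np
import pytest

from hicnb import (
    BiasVector,
    ContactMatrix,
    NBParams,
    SimulationConfig,
    Structure3D,
    generate_structure,
    nb_log_likelihood,
    simulate_counts,
)

ALPHA = -3.0


@pytest.fixture(scope="session")
def helix50() -> Structure3D:
    return generate_structure(50, "helix")


@pytest.fixture(scope="session")
def small_instance():
    """A reproducible 10-bead NB instance: (structure, bias, counts, params)."""
    s = generate_structure(10, "random_walk", seed=11)
    bias = BiasVector.unit(10)
    # modest coverage keeps counts O(10): typical of a sparse Hi-C bin pair
    m = simulate_counts(
        s, bias, SimulationConfig(n_beads=10, gamma=1.0, alpha=ALPHA, beta=10.0, seed=5)
    )
    return s, bias, m, NBParams(alpha=ALPHA, r=1.0)


def pair_matrix(c: int) -> ContactMatrix:
    """2-bead contact matrix with a single off-diagonal count."""
    return ContactMatrix(np.array([[0, c], [c, 0]]))


def pair_structure(mu: float, alpha: float = ALPHA) -> Structure3D:
    """2-bead structure whose single distance gives mean mu under d^alpha."""
    d = mu ** (1.0 / alpha)
    return Structure3D(np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]))


def pair_log_pmf(c: int, mu: float, r: float) -> float:
    """log P(C = c) for one NB pair, evaluated through the model likelihood."""
    return nb_log_likelihood(pair_structure(mu), NBParams(ALPHA, r), pair_matrix(c))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR."""
    q, rr = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(rr))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
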