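import numpy as np
import pytest

from tetraswap.synthetic import GroundTruth, generate_toy_structures


@pytest.fixture(scope="session")
def truth() -> GroundTruth:
    return GroundTruth(seed=7)


@pytest.fixture(scope="session")
def toys():
    return generate_toy_structures()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def brute_force_rmsd(coords_a, coords_b, n_rotations: int = 4000, seed: int = 0) -> float:
    """Independent superposition oracle: seeded random-quaternion search with a
    Nelder-Mead polish over rotation vectors.  Shares no code with the
    closed-form superposition under test."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def rmsd_for(rot: Rotation) -> float:
        return float(np.sqrt(((ac - rot.apply(bc)) ** 2).sum() / len(ac)))

    gen = np.random.default_rng(seed)
    quats = gen.normal(size=(n_rotations, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    best_q = min(quats, key=lambda q: rmsd_for(Rotation.from_quat(q)))
    res = minimize(
        lambda v: rmsd_for(Rotation.from_rotvec(v)),
        Rotation.from_quat(best_q).as_rotvec(),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
    )
    return float(res.fun)
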