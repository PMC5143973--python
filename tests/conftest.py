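import numpy as np
import pytest

from catpi.synth import make_pair_fixture, make_scaffold


@pytest.fixture(scope="session")
def lys_tyr_pair():
    """Engineered Lys-Tyr pair at 4.0 A, 10 deg face-on approach."""
    return make_pair_fixture("LYS", "TYR", 4.0, 10.0)


@pytest.fixture(scope="session")
def scaffold30():
    """30-residue extended scaffold with one Arg/Thr and one Trp/Ser motif."""
    return make_scaffold(
        30, motif_sites={8: "ARG", 10: "THR", 20: "TRP", 22: "SER"}, seed=1
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_frame(frame, R, t):
    out = frame.copy()
    for res in out:
        for atom in res.atoms:
            atom.coords = R @ atom.coords + t
    return out
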