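import numpy as np
import pytest

import splitperox as sp

HRP_DISULFIDES = [(11, 91), (44, 49), (177, 209), (97, 301)]


@pytest.fixture(scope="session")
def hrp_sequence() -> str:
    return sp.load_reference_sequence("HRP")[1]


@pytest.fixture(scope="session")
def apx_sequence() -> str:
    return sp.load_reference_sequence("APX")[1]


@pytest.fixture(scope="session")
def helix20() -> "sp.Structure":
    return sp.make_helix(20)


@pytest.fixture(scope="session")
def synthetic_hrp_model(hrp_sequence):
    """Schematic synthetic stand-in for the HRP crystal structure."""
    return sp.make_peroxidase_model(
        hrp_sequence,
        disulfides=HRP_DISULFIDES,
        proximal_his=170,
        n_calcium=2,
        with_heme=True,
        source_id="synthetic_hrp_model",
    )


@pytest.fixture(scope="session")
def synthetic_apx_model(apx_sequence):
    """Schematic synthetic stand-in for the APX crystal structure."""
    return sp.make_peroxidase_model(
        apx_sequence,
        disulfides=[],
        proximal_his=163,
        n_calcium=0,
        with_heme=True,
        source_id="synthetic_apx_model",
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_proper_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
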