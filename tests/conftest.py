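import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oscmine.config import MiningConfig
from oscmine.profiles import ProfileHMM, build_profile, make_weighted_msa

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def random_profile(rng: np.random.Generator, L: int,
                   sharpness: float = 5.0) -> ProfileHMM:
    """A random valid profile: Dirichlet emissions, sticky M->M transitions."""
    emis = rng.dirichlet(np.full(20, 1.0 / sharpness), size=L)
    trans = np.zeros((L + 1, 7))
    for j in range(L + 1):
        trans[j, 0:3] = rng.dirichlet([20.0, 1.0, 1.0])
        trans[j, 3:5] = rng.dirichlet([8.0, 1.0])
        trans[j, 5:7] = rng.dirichlet([8.0, 1.0])
    from oscmine.alphabet import BACKGROUND
    return ProfileHMM(name=f"rand{L}", L=L, match_emis=emis,
                      insert_emis=BACKGROUND.copy(), transitions=trans,
                      background=BACKGROUND.copy())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250919)


@pytest.fixture(scope="session")
def toy_msa():
    """Gap-free 3-row toy alignment."""
    rows = [("r1", "MKVLITGAGGFLGSA"), ("r2", "MKVLITGSGGFLGSA"),
            ("r3", "MKVLVTGAGGFIGSA")]
    return make_weighted_msa(rows)


@pytest.fixture(scope="session")
def toy_profile(toy_msa):
    return build_profile(toy_msa, name="toy")


@pytest.fixture(scope="session")
def default_cfg():
    return MiningConfig()
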