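import numpy as np
import pytest

from dinoretro import SimParams, generate_transcriptome


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def clean_sim():
    """Mid-size zero-noise simulation: every planted leader is intact."""
    params = SimParams(
        n_normal=200, n_retro=100,
        p_truncate5=0.0, p_trunc_leader=0.0, leader_mut_rate=0.0, dup_rate=0.0,
        seed=7,
    )
    return generate_transcriptome(params)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-condition simulation at reduced size for pipeline tests."""
    params = SimParams(n_normal=450, n_retro=50, seed=11)
    return generate_transcriptome(params)
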