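import numpy as np
import pytest

from scamap import (
    Alignment,
    SyntheticMSASpec,
    SyntheticStructureSpec,
    gen_sector_msa,
    gen_toy_structure,
)


@pytest.fixture(scope="session")
def toy_alignment() -> Alignment:
    return Alignment(
        ["s1", "s2", "s3", "s4"],
        ["ACDEF", "ACDEF", "AC-EF", "GHKLM"],
    )


@pytest.fixture(scope="session")
def planted_msa():
    """Default planted-sector alignment (400 x 100, two 15-column sectors)."""
    spec = SyntheticMSASpec(seed=1)
    return gen_sector_msa(spec)


@pytest.fixture(scope="session")
def hollow_shell():
    return gen_toy_structure(SyntheticStructureSpec(kind="hollow-shell"))


@pytest.fixture(scope="session")
def globule():
    return gen_toy_structure(SyntheticStructureSpec(kind="globule", globule_radius=10.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
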