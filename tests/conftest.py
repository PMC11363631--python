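import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from smoltpipe.genotyping import PanelLocus
from smoltpipe.pedigree import UNKNOWN, Pedigree


@pytest.fixture
def trio():
    """Sire, dam, one offspring."""
    return Pedigree(
        ids=["s", "d", "o"],
        sire=np.array([UNKNOWN, UNKNOWN, 0]),
        dam=np.array([UNKNOWN, UNKNOWN, 1]),
        family=["f"] * 3,
        cross=["x"] * 3,
        strain=["wild"] * 3,
        role=["founder", "founder", "offspring"],
    )


@pytest.fixture
def locus():
    return PanelLocus("Ssa04", 51770537, "T", "C")


def random_pedigree(rng: np.random.Generator, n: int, n_founders: int = 10) -> Pedigree:
    """Random multi-generation pedigree for oracle tests."""
    sire = np.full(n, UNKNOWN)
    dam = np.full(n, UNKNOWN)
    for i in range(n_founders, n):
        s, d = rng.integers(0, i, size=2)
        sire[i], dam[i] = s, d
    return Pedigree(
        ids=[f"i{k}" for k in range(n)],
        sire=sire,
        dam=dam,
        family=["f"] * n,
        cross=["x"] * n,
        strain=["wild"] * n,
        role=["founder" if i < n_founders else "offspring" for i in range(n)],
    )
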