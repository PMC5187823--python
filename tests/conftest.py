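import numpy as np
import pytest

from silkspacer.synthetic import (
    MASP1_SEQUENCE,
    build_backbone,
    uniform_dihedrals,
)


@pytest.fixture(scope="session")
def masp1_strand():
    """A single MaSp1(71-121) strand in the extended-β conformation."""
    n = len(MASP1_SEQUENCE)
    return build_backbone(
        MASP1_SEQUENCE, uniform_dihedrals(n, -135.0, 135.0), first_resnum=71
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dihedrals(rng, n, lo=-179.0, hi=179.0):
    """A valid random (n, 3) dihedral spec with undefined terminal angles."""
    d = np.column_stack([
        rng.uniform(lo, hi, n), rng.uniform(lo, hi, n), rng.uniform(160, 200, n)
    ])
    d[:, 2] = np.where(d[:, 2] > 180, d[:, 2] - 360, d[:, 2])
    d[0, 0] = np.nan
    d[-1, 1] = np.nan
    return d
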