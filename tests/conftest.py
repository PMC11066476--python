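import numpy as np
import pytest

from luadmorph import desk_scale, preset
from luadmorph.lattice import GENERIC, STROMAL, Lattice, PottsParams


@pytest.fixture
def params():
    return PottsParams(temperature=10.0, neighbor_order=3, rng_seed=0)


@pytest.fixture
def desk_base():
    return desk_scale(preset("base_ppa"))


def single_cell_lattice(size=30, cell=10, lam=2.0, target=None, cell_type=STROMAL):
    """One square non-compartmental cell centered in medium."""
    lattice = Lattice(size, size)
    cid = lattice.new_cluster(cell_type, reference_volume=cell * cell)
    comp = lattice.new_compartment(
        cid, GENERIC, float(target if target is not None else cell * cell), lam
    )
    r0 = (size - cell) // 2
    lattice.paint(
        np.arange(r0, r0 + cell)[:, None], np.arange(r0, r0 + cell)[None, :], comp
    )
    lattice.validate()
    return lattice, cid, comp
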