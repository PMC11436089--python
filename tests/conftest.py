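import numpy as np
import pytest

from gliolabels.phantom import PhantomSpec, generate


@pytest.fixture(scope="session")
def tumour_phantom():
    """Full concentric tumour (core / shell / halo) plus a 30- and an 80-voxel
    NET island, straddling the 50 mm³ cluster threshold."""
    spec = PhantomSpec(net_islands=(((50, 32, 32), 30), ((32, 50, 32), 80)))
    return spec, generate(spec)


@pytest.fixture(scope="session")
def cavity_phantom():
    """Small off-centre tumour plus one 2500 mm³ fluid-filled cavity."""
    spec = PhantomSpec(
        tumour_centre=(22, 22, 22),
        core_radius=3.0,
        shell_radius=4.5,
        halo_radius=6.0,
        cavities=(((42, 42, 42), 2500),),
    )
    return spec, generate(spec)


@pytest.fixture(scope="session")
def small_cavity_phantom():
    """Same layout with the cavity shrunk to 1500 mm³, below the 2 cm³ floor."""
    spec = PhantomSpec(
        tumour_centre=(22, 22, 22),
        core_radius=3.0,
        shell_radius=4.5,
        halo_radius=6.0,
        cavities=(((42, 42, 42), 1500),),
    )
    return spec, generate(spec)


@pytest.fixture()
def ball():
    """Factory for voxelised balls on a given lattice."""

    def _ball(shape, centre, radius):
        idx = np.indices(shape, dtype=float)
        return np.sqrt(sum((idx[a] - centre[a]) ** 2 for a in range(3))) <= radius

    return _ball
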