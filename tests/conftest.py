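import numpy as np
import pytest

from spinemorph.phantom import DeformityClass, PhantomSpec, generate_spine


@pytest.fixture(scope="session")
def wedge_phantom():
    """Single 15 mm vertebra with a wedge deformity targeting HLR = 1/3."""
    spec = PhantomSpec(
        n_vertebrae=1,
        base_posterior_height_mm=15.0,
        deformity_plan=((0, DeformityClass.WEDGE, 1.0 / 3.0),),
        seed=7,
    )
    return generate_spine(spec)


@pytest.fixture(scope="session")
def five_vertebra_phantom():
    """Five 25 mm vertebrae: one wedge, one biconcave, one crush, two normal."""
    spec = PhantomSpec(
        n_vertebrae=5,
        deformity_plan=(
            (1, DeformityClass.WEDGE, 0.30),
            (2, DeformityClass.CRUSH, 0.30),
            (3, DeformityClass.BICONCAVE, 0.35),
        ),
        seed=3,
    )
    return generate_spine(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
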