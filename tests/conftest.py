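import numpy as np
import pytest
import trimesh

from osteolattice import (
    CompressionSpecimen,
    CorticalPair,
    CurveParams,
    LatticeSpec,
)
from osteolattice.synthetic import (
    gen_phantom,
    load_bundled_calibration,
)


@pytest.fixture(scope="session")
def bone_cal():
    return load_bundled_calibration("human_bone_vs_hu")


@pytest.fixture(scope="session")
def tough_cal():
    return load_bundled_calibration("tough2000_vs_tl")


@pytest.fixture(scope="session")
def clear_cal():
    return load_bundled_calibration("clear_v4_vs_tl")


@pytest.fixture
def canonical_specimen():
    """The drilled bone core: Ø6 x 12 mm."""
    return CompressionSpecimen(6.0, 12.0)


@pytest.fixture
def default_params():
    """Bone-like ground truth for one synthetic compression curve."""
    return CurveParams(E_true=150.0, sigma_y_true=3.1, sigma_p_true=2.4, seed=7)


@pytest.fixture(scope="session")
def sphere_pair():
    """Concentric cortical surfaces: Ø24 outer, Ø20 inner (2 mm shell)."""
    return CorticalPair(
        outer=trimesh.creation.icosphere(subdivisions=3, radius=12.0),
        inner=trimesh.creation.icosphere(subdivisions=3, radius=10.0),
    )


@pytest.fixture(scope="session")
def asymmetric_phantom():
    """Shell phantom, 2 mm cortex, interior means (90, 310) HU."""
    return gen_phantom(interior_means=(90.0, 310.0), cortical_thickness_mm=2.0, seed=11)


@pytest.fixture
def lattice_spec_02():
    return LatticeSpec.from_ratio(0.2)  # t = 0.4 mm, L = 2 mm


def piecewise_linear_curve(knots, n_per_segment=200):
    """Dense (strain, stress) samples through the given (eps, sigma) knots."""
    eps_parts, sig_parts = [], []
    for (e0, s0), (e1, s1) in zip(knots[:-1], knots[1:]):
        e = np.linspace(e0, e1, n_per_segment, endpoint=False)
        s = np.interp(e, [e0, e1], [s0, s1])
        eps_parts.append(e)
        sig_parts.append(s)
    eps_parts.append(np.array([knots[-1][0]]))
    sig_parts.append(np.array([knots[-1][1]]))
    return np.concatenate(eps_parts), np.concatenate(sig_parts)
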