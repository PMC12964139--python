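import numpy as np
import pytest

from anisomre.forward import NITIVolume, default_actuations, simulate_multi_excitation
from anisomre.material import PhysicsConstants
from anisomre.phantom import CohortConfig, build_atlas, sample_cohort


@pytest.fixture(scope="session")
def constants():
    return PhysicsConstants()


@pytest.fixture(scope="session")
def atlas32():
    return build_atlas((32, 32, 32))


@pytest.fixture(scope="session")
def cohort32(atlas32):
    """Default-parameter cohort on the 32^3 atlas (20 young + 18 old)."""
    return sample_cohort(atlas32, CohortConfig(seed=42))


def homogeneous_volume(shape, mu_storage, mu_loss=0.0, phi=0.0, zeta=0.0, fiber=(0.0, 0.0, 1.0)):
    fib = np.zeros(tuple(shape) + (3,))
    fib[:] = np.asarray(fiber) / np.linalg.norm(fiber)
    return NITIVolume(
        mu2_storage=np.full(shape, float(mu_storage)),
        mu2_loss=np.full(shape, float(mu_loss)),
        phi=np.full(shape, float(phi)),
        zeta=np.full(shape, float(zeta)),
        fibers=fib,
    )


@pytest.fixture(scope="session")
def two_compartment_fields(constants):
    """Noiseless AP+LR solves of a stiff anisotropic inclusion in a softer
    background: the shared input of the inversion recovery tests."""
    n, h = 10, 3e-3
    shape = (n, n, n)
    vol = homogeneous_volume(shape, 2500.0, 750.0, 0.1, 0.8)
    inc = (slice(3, 7),) * 3
    vol.mu2_storage[inc] = 3500.0
    vol.mu2_loss[inc] = 1050.0
    vol.phi[inc] = 0.35
    vol.zeta[inc] = 1.2
    acts = default_actuations((n + 1,) * 3)
    fields = simulate_multi_excitation(vol, constants, acts.values(), spacing_m=h)
    return {"fields": fields, "truth": vol, "inclusion": inc, "spacing": h}
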