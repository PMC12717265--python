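import numpy as np
import pytest

from vapredict.cohort_synth import GeneratorConfig, generate_cohort
from vapredict.wavefront_optics import PupilGrid, ZernikeSet


@pytest.fixture(scope="session")
def small_grid():
    """Coarse pupil grid, fast enough for per-test PSFs."""
    return PupilGrid(n=128, pad_factor=3)


@pytest.fixture(scope="session")
def zero_zernikes():
    return ZernikeSet.zeros()


@pytest.fixture
def defocus_zernikes():
    def make(c4_um: float) -> ZernikeSet:
        z = ZernikeSet.zeros()
        c = z.coeffs.copy()
        c[4] = c4_um
        return z.with_coeffs(c)

    return make


@pytest.fixture(scope="session")
def study_cohort():
    """The 135-subject study-sized cohort with 11 injected missing VA cells."""
    return generate_cohort(GeneratorConfig(n_subjects=135, seed=7, missing_va=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject cohort with complete data, for fast structural tests."""
    return generate_cohort(GeneratorConfig(n_subjects=12, seed=3, missing_va=0))
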