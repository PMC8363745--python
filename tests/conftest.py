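import numpy as np
import pytest

from dentomorph.synthetic import CohortSpec, GroupSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20210813)


@pytest.fixture
def small_cohort():
    """Ten ldm2 dentinal-crown specimens, one population, fixed seed."""
    spec = CohortSpec(
        tooth_class="ldm2",
        feature_set="dentinal_crown",
        groups=[GroupSpec("Baka", 10, sex_labels=True)],
        noise_sd=0.02,
        seed=101,
    )
    return generate_cohort(spec)


@pytest.fixture
def outline_cohort():
    """Twenty udm2 cervical-outline specimens in a common frame."""
    spec = CohortSpec(
        tooth_class="udm2",
        feature_set="cervical_outline",
        groups=[GroupSpec("Baka", 10), GroupSpec("European", 10)],
        noise_sd=0.02,
        rigid_transforms=False,
        seed=202,
    )
    return generate_cohort(spec)
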