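import pytest

from rhizotraits.calibration import fit_all_curves
from rhizotraits.normalization import assemble_trait_matrix
from rhizotraits.synthetic import fixture_config, generate_study


@pytest.fixture(scope="session")
def tiny_study():
    """Small seeded dataset exercising the full schema (8 isolates)."""
    return generate_study(fixture_config("tiny"), seed=1)


@pytest.fixture(scope="session")
def tiny_noiseless():
    """Tiny dataset with zero measurement noise (exact chain inversion)."""
    return generate_study(fixture_config("tiny").noiseless(), seed=3)


@pytest.fixture(scope="session")
def tiny_curves(tiny_study):
    return fit_all_curves(tiny_study.standards)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_study, tiny_curves):
    """Weighted trait matrix assembled from the tiny dataset."""
    return assemble_trait_matrix(
        tiny_study.plate_readings,
        tiny_study.assays,
        tiny_study.isolates,
        tiny_curves,
        weight=True,
    )
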