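import pytest

from peffkit import chambers, synthbeam


@pytest.fixture(scope="session")
def farmer():
    return chambers.load_chamber("ptw_30013")


@pytest.fixture()
def pristine_330():
    """Noise-free synthetic 330 MeV/u Bragg curve on a 0.1 mm grid."""
    return synthbeam.generate_pristine(synthbeam.BeamModel(energy=330.0), 0.1)
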