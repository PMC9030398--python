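import pytest

from wristopt import load_parameter_ranges, worked_example_instance


@pytest.fixture
def worked_instance():
    """Three wrist extensors (ECU, ECRB, ECRL) balancing a 10 N*m moment."""
    return worked_example_instance()


@pytest.fixture(scope="session")
def ranges():
    """Packaged literature min/max parameter bounds."""
    return load_parameter_ranges()
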