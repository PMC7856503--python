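import dataclasses

import pytest

from epidqa.synthetic import (SyntheticBeamSpec, WedgeSpec,
                              generate_portal_image)


@pytest.fixture(scope="session")
def default_spec() -> SyntheticBeamSpec:
    """Noiseless 10x10 cm flattened beam, 0.25 mm isocenter pixels."""
    return SyntheticBeamSpec()


@pytest.fixture(scope="session")
def open_image(default_spec):
    return generate_portal_image(default_spec)


@pytest.fixture(scope="session")
def wedge_image(default_spec):
    return generate_portal_image(
        dataclasses.replace(default_spec, wedge=WedgeSpec(), seed=1))


@pytest.fixture(scope="session")
def fff_spec(default_spec) -> SyntheticBeamSpec:
    return dataclasses.replace(default_spec, beam_type="fff", beam_label="6FFF")


@pytest.fixture(scope="session")
def fff_image(fff_spec):
    return generate_portal_image(fff_spec)
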