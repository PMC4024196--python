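import numpy as np
import pytest

import mpmaging as m


@pytest.fixture(scope="session")
def protocol():
    return m.default_protocol()


@pytest.fixture(scope="session")
def geometry24():
    return m.build_phantom(m.default_geometry_spec(24))


@pytest.fixture(scope="session")
def geometry48():
    return m.build_phantom(m.default_geometry_spec(48))


@pytest.fixture(scope="session")
def aging():
    return m.default_aging_model()


@pytest.fixture(scope="session")
def zero_noise_aging(aging):
    """Aging model with all between-subject SDs zeroed (deterministic truth)."""
    import dataclasses

    def strip(entry):
        return dataclasses.replace(entry, sd=m.ParamSet())

    return m.AgingModel(
        tissues={k: strip(v) for k, v in aging.tissues.items()},
        rois={k: strip(v) for k, v in aging.rois.items()},
        reference_age=aging.reference_age,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
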