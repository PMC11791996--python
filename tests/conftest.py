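import numpy as np
import pytest

import valvemesh as vm


@pytest.fixture(scope="session")
def spec():
    return vm.FixtureSpec()


@pytest.fixture(scope="session")
def template(spec):
    return vm.make_template(spec)


@pytest.fixture(scope="session")
def labelmaps(template):
    return vm.make_labelmaps(template, spacing_mm=1.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
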