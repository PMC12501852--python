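import numpy as np
import pytest

from amodalfruit.pipeline import run_generate, tiny_profile


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_profile(seed=1)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_config):
    """One shared 20-scene 96x96 dataset for pipeline-level tests."""
    out = tmp_path_factory.mktemp("tinyds")
    manifest = run_generate(tiny_config, out)
    return {"dir": out, "manifest": manifest, "config": tiny_config}
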