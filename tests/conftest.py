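import importlib.resources

import numpy as np
import pytest

from simtox.chemio import read_structures, standardize_all
from simtox.synthdata import GeneratorConfig, generate


@pytest.fixture(scope="session")
def fixture_smi_path(tmp_path_factory):
    text = (importlib.resources.files("simtox") / "data" / "fixtures.smi").read_text()
    p = tmp_path_factory.mktemp("data") / "fixtures.smi"
    p.write_text(text)
    return p


@pytest.fixture(scope="session")
def fixture_records(fixture_smi_path):
    return read_structures(fixture_smi_path, "smiles")


@pytest.fixture(scope="session")
def std_records(fixture_records):
    good, _bad = standardize_all(fixture_records)
    return good


@pytest.fixture(scope="session")
def small_tables():
    """Separable-but-noisy synthetic train/external pair for learner tests."""
    cfg = GeneratorConfig(
        n_train=200, n_external=60, active_fraction=0.25,
        n_bits=64, template_distance=24, flip_prob=0.1, seed=11,
    )
    return generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
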