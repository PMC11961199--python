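import numpy as np
import pytest

from screenkit.synthetic import GeneratorConfig, generate_dataset, emit_fixture_set


@pytest.fixture(scope="session")
def small_config():
    """Small but non-trivial generator settings shared by unit tests."""
    return GeneratorConfig(n_enzymes=6, residues_per_enzyme=40,
                           catalytic_per_enzyme=4, n_classes=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    records, graphs = generate_dataset(small_config)
    return records, graphs


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A tiny emitted on-disk dataset (PDB/PSSM/HMM/embeddings/labels)."""
    out = tmp_path_factory.mktemp("fixtures")
    cfg = GeneratorConfig(n_enzymes=3, residues_per_enzyme=30,
                          catalytic_per_enzyme=3, seed=23)
    emit_fixture_set(cfg, out)
    return out, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
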