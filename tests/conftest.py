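import numpy as np
import pytest

from medcap.corpus import split_corpus, write_manifest_csv
from medcap.synthetic import SynthSpec, generate_corpus


@pytest.fixture(scope="session")
def synth_corpus(tmp_path_factory):
    """Default-condition synthetic corpus (3 triples x 60 images), curated
    with a 60/20/20 split. Shared across tests that only read it."""
    root = tmp_path_factory.mktemp("corpus")
    spec = SynthSpec(seed=42)
    manifest = generate_corpus(spec, root)
    manifest = split_corpus(manifest, seed=7)
    write_manifest_csv(manifest, root / "curated.csv")
    return root, spec, manifest


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A 3x10 corpus for fast training-path tests."""
    root = tmp_path_factory.mktemp("small_corpus")
    spec = SynthSpec(n_per_triple=10, image_size=(32, 32), noise_sd=4.0, seed=5)
    manifest = generate_corpus(spec, root)
    manifest = split_corpus(manifest, seed=5)
    write_manifest_csv(manifest, root / "curated.csv")
    return root, spec, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
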