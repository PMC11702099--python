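import numpy as np
import pytest

from he2ihc.config import benchmark_config
from he2ihc.stain_io import SplitSpec, split_manifest
from he2ihc.synthetic import SynthConfig, make_dataset


@pytest.fixture(scope="session")
def bench_cfg():
    return benchmark_config(side=64)


@pytest.fixture(scope="session")
def synth_root(tmp_path_factory):
    """A small synthetic paired-stain dataset on disk (6 pairs per level)."""
    root = tmp_path_factory.mktemp("synth")
    make_dataset(SynthConfig(side=64, n_per_class=6, seed=11), root)
    return root


@pytest.fixture(scope="session")
def synth_splits(synth_root):
    from he2ihc.stain_io import build_manifest
    manifest = build_manifest(synth_root)
    return split_manifest(manifest, SplitSpec((0.7, 0.2, 0.1), seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
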