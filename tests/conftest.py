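import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from edrnet.atlas import split_label
from edrnet.synthetic import AtlasSpec, make_atlas


@pytest.fixture(scope="session")
def atlas75():
    """The standard 75-region synthetic atlas (37 bilateral pairs + 1 central)."""
    return make_atlas(AtlasSpec(n_pairs=37, n_central=1, seed=0))


@pytest.fixture(scope="session")
def mirrored_hierarchy(atlas75):
    """Hemisphere-symmetric hierarchy scores: partners share their base score."""
    rng = np.random.default_rng(99)
    scores = {}
    return np.array(
        [scores.setdefault(split_label(l)[0], rng.uniform(0, 1)) for l in atlas75.labels]
    )


def random_digraph(rng, n, p=0.4):
    A = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A


def random_weighted_digraph(rng, n, p=0.5):
    A = random_digraph(rng, n, p)
    w = np.where(A, rng.uniform(0.01, 0.9, (n, n)), 0.0)
    return w
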