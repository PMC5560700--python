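import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for naive_oracle

from relnet.io import CountMatrix, GroupAssignment


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_counts(rng):
    """10 entities x 12 samples in 3 groups of 4, random counts."""
    counts = rng.integers(0, 60, size=(10, 12)).astype(float)
    counts[3, :] += 500  # one high-expression entity
    eids = np.array([f"g{i:02d}" for i in range(10)], dtype=object)
    sids = np.array([f"s{j:02d}" for j in range(12)], dtype=object)
    cm = CountMatrix(counts, eids, sids)
    groups = GroupAssignment.from_labels(sids, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
    return cm, groups


@pytest.fixture
def sample_labels():
    def _labels(groups, cm):
        codes = groups.codes(cm.sample_ids)
        return [groups.labels[c] for c in codes]

    return _labels
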