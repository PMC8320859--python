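import numpy as np
import pandas as pd
import pytest

from mpcaface import ShapeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_labels(groups, subjects_per_group, conditions):
    rows = []
    for g in range(groups):
        for s in range(subjects_per_group):
            for c in range(conditions):
                rows.append({
                    "dataset_id": "t", "group_id": f"g{g + 1}",
                    "subject_id": f"g{g + 1}s{s + 1}",
                    "condition_id": f"c{c + 1}", "frame_index": "",
                })
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_dataset(rng):
    """2 groups x 2 subjects x 2 conditions, length-4 vectors."""
    labels = make_labels(2, 2, 2)
    X = rng.normal(size=(len(labels), 4))
    return ShapeDataset(X, labels, d=2)
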