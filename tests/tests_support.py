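"""Shared helpers for the test suite."""

import numpy as np

from mpcaface import MultilevelPCA, ShapeDataset

from conftest import make_labels


def random_dataset(rng, n=10, k=6, d=2):
    """Random dataset with an arbitrary (balanced-ish) label layout."""
    rows = []
    for i in range(n):
        rows.append({"dataset_id": "t", "group_id": f"g{i % 2 + 1}",
                     "subject_id": f"s{i // 2 + 1}",
                     "condition_id": f"c{i % 2 + 1}", "frame_index": ""})
    import pandas as pd
    return ShapeDataset(rng.normal(size=(n, k * d)), pd.DataFrame(rows), d=d)


def manual_mpca(rng, p=12, r=(2, 3, 2), orthogonal_between=False, kappa=0.01):
    """Hand-assembled multilevel model with a random (optionally
    between-level-orthogonal) basis, for exercising the joint fit."""
    model = MultilevelPCA(kappa=kappa)
    if orthogonal_between:
        Q, _ = np.linalg.qr(rng.normal(size=(p, sum(r))))
        comps = [Q[:, :r[0]].T, Q[:, r[0]:r[0] + r[1]].T, Q[:, r[0] + r[1]:].T]
    else:
        comps = []
        for ri in r:
            Q, _ = np.linalg.qr(rng.normal(size=(p, ri)))
            comps.append(Q.T)
    model.grand_mean_ = rng.normal(size=p)
    model.components_ = comps
    model.eigenvalues_ = [np.sort(rng.uniform(0.5, 3.0, ri))[::-1] for ri in r]
    model.n_components_ = tuple(r)
    model.n_features_in_ = p
    model.level_names_ = ("top", "middle", "bottom")
    return model
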