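import numpy as np
import pandas as pd
import pytest

from mpcaface import (HierarchySpec, MultilevelPCA, ShapeDataset,
                      ShapeSimConfig, fit_mpca, generate_hierarchical_shapes,
                      level_covariances, score_centroids)

from conftest import make_labels
from tests_support import manual_mpca, random_dataset


def brute_force_covariances(X, labels):
    """Nested-loop reference for the (top, middle, bottom) matrices of the
    group/subject/condition hierarchy."""
    p = X.shape[1]
    df = labels.copy()
    df["row"] = np.arange(len(df))
    subj_means, bottom_mats = {}, []
    for (g, s), grp in df.groupby(["group_id", "subject_id"], sort=False):
        rows = X[grp["row"].to_numpy()]
        m = rows.mean(axis=0)
        subj_means[(g, s)] = m
        C = np.zeros((p, p))
        if rows.shape[0] > 1:
            for r in rows:
                C += np.outer(r - m, r - m)
            C /= rows.shape[0] - 1
        bottom_mats.append(C)
    bottom = np.mean(bottom_mats, axis=0)

    group_means, middle_mats = {}, []
    for g in df["group_id"].unique():
        means = np.stack([m for (gg, _), m in subj_means.items() if gg == g])
        gm = means.mean(axis=0)
        group_means[g] = gm
        C = np.zeros((p, p))
        for m in means:
            C += np.outer(m - gm, m - gm)
        middle_mats.append(C / (means.shape[0] - 1))
    middle = np.mean(middle_mats, axis=0)

    gms = np.stack(list(group_means.values()))
    center = gms.mean(axis=0)
    top = sum(np.outer(m - center, m - center) for m in gms) / (len(gms) - 1)
    return top, middle, bottom


class TestLevelCovariances:
    def test_matches_brute_force_on_tiny_dataset(self, tiny_dataset):
        got = level_covariances(tiny_dataset, HierarchySpec.static_faces())
        want = brute_force_covariances(tiny_dataset.X, tiny_dataset.labels)
        for g, w in zip(got, want):
            np.testing.assert_allclose(g, w, atol=1e-12)

    def test_two_groups_give_rank_one_top_level(self, rng):
        ds, _ = generate_hierarchical_shapes(
            ShapeSimConfig(n_subjects_per_group=5, seed=0))
        top, _, _ = level_covariances(ds, HierarchySpec.static_faces())
        vals = np.linalg.eigvalsh(top)
        assert np.sum(vals > 1e-10 * np.trace(top)) == 1

    def test_identical_observations_give_zero_matrices(self, tiny_dataset):
        ds = tiny_dataset.with_vectors(np.tile(tiny_dataset.X[0],
                                               (tiny_dataset.n, 1)))
        for C in level_covariances(ds, HierarchySpec.static_faces()):
            np.testing.assert_allclose(C, 0, atol=1e-12)

    def test_single_top_group_rejected(self, rng):
        labels = make_labels(1, 3, 2)
        ds = ShapeDataset(rng.normal(size=(len(labels), 4)), labels, d=2)
        with pytest.raises(ValueError, match="two units"):
            level_covariances(ds, HierarchySpec.static_faces())

    def test_single_observation_subject_contributes_zero(self, rng, caplog):
        labels = make_labels(2, 2, 2).iloc[:-1]  # last subject: one condition
        ds = ShapeDataset(rng.normal(size=(len(labels), 4)), labels, d=2)
        import logging
        with caplog.at_level(logging.INFO, logger="mpcaface.mpca"):
            got = level_covariances(ds, HierarchySpec.static_faces())
        assert "single observation" in caplog.text
        assert np.all(np.isfinite(got[2]))

    def test_nested_averaging_for_smile_hierarchy(self, rng):
        """Per-subject averaging over phases, then over subjects."""
        rows = []
        for s in range(2):
            for ph in ("rest", "apex"):
                for f in range(3):
                    rows.append({"dataset_id": "t", "group_id": "",
                                 "subject_id": f"s{s}", "condition_id": ph,
                                 "frame_index": f})
        labels = pd.DataFrame(rows)
        X = rng.normal(size=(len(labels), 4))
        _, _, bottom = level_covariances(X, HierarchySpec.smile_frames(), labels)
        cell_covs = []
        for s in range(2):
            per_subject = []
            for ph in ("rest", "apex"):
                mask = ((labels["subject_id"] == f"s{s}")
                        & (labels["condition_id"] == ph)).to_numpy()
                per_subject.append(np.cov(X[mask].T, ddof=1))
            cell_covs.append(np.mean(per_subject, axis=0))
        np.testing.assert_allclose(bottom, np.mean(cell_covs, axis=0), atol=1e-12)

    def test_permutation_invariance(self, rng):
        ds = random_dataset(rng, n=12, k=4, d=2)
        got = level_covariances(ds, HierarchySpec.static_faces())
        perm = rng.permutation(ds.n)
        ds_p = ShapeDataset(ds.X[perm], ds.labels.iloc[perm], d=2)
        got_p = level_covariances(ds_p, HierarchySpec.static_faces())
        for a, b in zip(got, got_p):
            np.testing.assert_allclose(a, b, atol=1e-10)


class TestFit:
    def test_planted_group_effect_dominates_top_level(self):
        cfg = ShapeSimConfig(sigma_group=5.0, sigma_subject=0.0,
                             sigma_condition=0.0, sigma_noise=0.5, seed=1)
        ds, _ = generate_hierarchical_shapes(cfg)
        model = fit_mpca(ds, HierarchySpec.static_faces())
        top = model.eigenvalues_[0][0]
        others = max(model.eigenvalues_[1][0], model.eigenvalues_[2][0])
        assert top / others > 10

    def test_eigenvalues_permutation_invariant(self, rng):
        ds = random_dataset(rng, n=16, k=5, d=2)
        m1 = fit_mpca(ds, HierarchySpec.static_faces())
        perm = rng.permutation(ds.n)
        ds_p = ShapeDataset(ds.X[perm], ds.labels.iloc[perm], d=2)
        m2 = fit_mpca(ds_p, HierarchySpec.static_faces())
        for a, b in zip(m1.eigenvalues_, m2.eigenvalues_):
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_grand_mean_is_mean_of_all_vectors(self, tiny_dataset):
        model = fit_mpca(tiny_dataset, HierarchySpec.static_faces())
        np.testing.assert_allclose(model.grand_mean_,
                                   tiny_dataset.X.mean(axis=0))

    def test_within_level_orthonormality(self, rng):
        ds = random_dataset(rng, n=16, k=5, d=2)
        model = fit_mpca(ds, HierarchySpec.static_faces())
        for comps in model.components_:
            np.testing.assert_allclose(comps @ comps.T,
                                       np.eye(comps.shape[0]), atol=1e-8)

    def test_sklearn_param_interface(self):
        model = MultilevelPCA()
        params = model.get_params()
        assert "kappa" in params
        model.set_params(kappa=0.02)
        assert model.kappa == 0.02
        with pytest.raises(ValueError):
            model.set_params(bogus=1)


class TestJointFit:
    def test_grand_mean_gives_zero_coefficients(self, rng):
        model = manual_mpca(rng)
        for method in ("direct", "gradient"):
            coeffs = model.project(model.grand_mean_, method=method)
            for a in coeffs:
                np.testing.assert_allclose(a, 0, atol=1e-10)

    def test_orthogonal_between_levels_decouples_to_scalar_products(self, rng):
        model = manual_mpca(rng, orthogonal_between=True)
        z = rng.normal(size=model.n_features_in_)
        coeffs = model.project(z, method="direct")
        for a, comps in zip(coeffs, model.components_):
            np.testing.assert_allclose(a, comps @ (z - model.grand_mean_),
                                       atol=1e-8)

    def test_gradient_matches_direct_on_random_instances(self):
        """Gradient iteration and least squares find the same minimizer even
        with non-orthogonal between-level bases."""
        rng = np.random.default_rng(7)
        for trial in range(50):
            p = int(rng.integers(20, 41))
            r = tuple(int(x) for x in rng.integers(1, 6, size=3))
            model = manual_mpca(rng, p=p, r=r)
            z = model.grand_mean_ + rng.normal(size=p)
            direct = np.concatenate(model.project(z, "direct"))
            grad = np.concatenate(model.project(z, "gradient"))
            np.testing.assert_allclose(grad, direct, atol=1e-6)

    def test_solution_beats_random_coefficient_vectors(self, rng):
        model = manual_mpca(rng)
        z = model.grand_mean_ + rng.normal(size=model.n_features_in_)
        coeffs = model.project(z, "direct")
        best = np.sum((z - model.reconstruct(coeffs)) ** 2)
        flat = np.concatenate(coeffs)
        for _ in range(1000):
            pert = flat + rng.normal(0, 0.3, size=flat.shape)
            split = model._split(pert)
            resid = np.sum((z - model.reconstruct(list(split))) ** 2)
            assert best <= resid + 1e-10

    def test_converges_with_nondiagonal_between_level_gram(self, rng):
        """Between-level eigenvectors need not be orthogonal; the fit still
        converges and the two routes agree."""
        model = manual_mpca(rng, p=10, r=(2, 2, 2))
        U = model._stacked_basis
        gram = U.T @ U
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() > 1e-3  # genuinely non-orthogonal instance
        z = model.grand_mean_ + rng.normal(size=10)
        d = np.concatenate(model.project(z, "direct"))
        g = np.concatenate(model.project(z, "gradient"))
        np.testing.assert_allclose(g, d, atol=1e-6)

    def test_zero_coefficients_reconstruct_grand_mean(self, rng):
        model = manual_mpca(rng)
        zeros = [np.zeros(r) for r in model.n_components_]
        np.testing.assert_allclose(model.reconstruct(zeros), model.grand_mean_)

    def test_residual_shrinks_as_retention_grows(self, rng):
        ds = random_dataset(rng, n=20, k=6, d=2)
        z = rng.normal(size=12)
        resids = []
        for r in (1, 2, 4):
            model = MultilevelPCA(HierarchySpec.static_faces(),
                                  n_components=(1, r, r)).fit(ds)
            rec = model.reconstruct(model.project(z))
            resids.append(np.sum((z - rec) ** 2))
        assert resids[0] >= resids[1] >= resids[2] - 1e-12

    def test_length_mismatch_rejected(self, rng):
        model = manual_mpca(rng)
        with pytest.raises(ValueError, match="length"):
            model.project(np.zeros(model.n_features_in_ + 1))
        bad = [np.zeros(r + 1) for r in model.n_components_]
        with pytest.raises(ValueError, match="length"):
            model.reconstruct(bad)


class TestScores:
    def test_sqrt_eigenvalue_standardizes_to_one(self, rng):
        model = manual_mpca(rng)
        coeffs = [np.sqrt(v) for v in model.eigenvalues_]
        std = model.standardize(coeffs)
        for s in std:
            np.testing.assert_allclose(s, 1.0)

    def test_zero_coefficients_standardize_to_zero(self, rng):
        model = manual_mpca(rng)
        std = model.standardize([np.zeros(r) for r in model.n_components_])
        for s in std:
            np.testing.assert_allclose(s, 0)

    def test_planted_groups_separate_in_top_level_scores(self):
        cfg = ShapeSimConfig(n_subjects_per_group=15, seed=5)
        ds, _ = generate_hierarchical_shapes(cfg)
        model = fit_mpca(ds, HierarchySpec.static_faces())
        top = model.transform(ds.X)[0][:, 0]
        g = ds.labels["group_id"].to_numpy()
        c1, c2 = top[g == "g1"], top[g == "g2"]
        pooled = np.sqrt((c1.var(ddof=1) + c2.var(ddof=1)) / 2)
        assert abs(c1.mean() - c2.mean()) / pooled > 2


class TestCentroids:
    def test_single_group_centroid_is_column_mean(self, rng):
        scores = rng.normal(size=(6, 3))
        cent = score_centroids(scores, ["a"] * 6)
        np.testing.assert_allclose(cent.loc["a"], scores.mean(axis=0))

    def test_symmetric_groups_mirror_about_origin(self, rng):
        s = rng.normal(size=(10, 2))
        scores = np.vstack([s, -s])
        labels = ["a"] * 10 + ["b"] * 10
        cent = score_centroids(scores, labels)
        np.testing.assert_allclose(cent.loc["a"], -cent.loc["b"], atol=1e-12)

    def test_balanced_centered_scores_average_to_zero(self, rng):
        scores = rng.normal(size=(8, 2))
        scores -= scores.mean(axis=0)
        labels = ["a", "b"] * 4
        cent = score_centroids(scores, labels)
        np.testing.assert_allclose(cent.to_numpy().mean(axis=0), 0, atol=1e-12)
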