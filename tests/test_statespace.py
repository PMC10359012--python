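"""Standardization, PCA and separation statistics."""

import numpy as np
import pytest
from sklearn.decomposition import PCA

from mousemime.statespace import (
    coverage_2sd,
    pca3,
    separation_score,
    total_variance,
    zscore,
)


def test_zscore_standardizes_columns():
    rng = np.random.default_rng(0)
    X = rng.normal(5, 3, (200, 10))
    Z, stats = zscore(X)
    np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
    np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-10)
    assert stats.kept.all()


def test_zscore_excludes_constant_column_with_warning():
    X = np.random.default_rng(1).normal(size=(50, 3))
    X[:, 1] = 7.0
    with pytest.warns(UserWarning):
        Z, stats = zscore(X)
    assert Z.shape == (50, 2)
    assert not stats.kept[1]


def test_zscore_roundtrip():
    X = np.random.default_rng(2).normal(2, 5, (30, 4))
    Z, stats = zscore(X)
    np.testing.assert_allclose(stats.unstandardize(Z), X, atol=1e-10)


def test_pca_agrees_with_eigendecomposition_oracle():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(6, 10))
    Z = X - X.mean(axis=0)
    emb = pca3(Z)
    evals = np.sort(np.linalg.eigvalsh(np.cov(Z.T)))[::-1]
    np.testing.assert_allclose(
        emb.explained_variance_fraction,
        evals[:3] / evals.sum(), atol=1e-10)
    # cross-check scores against sklearn up to component sign
    sk = PCA(n_components=3).fit_transform(Z)
    for j in range(3):
        dot = np.abs(np.dot(sk[:, j], emb.scores[:, j]))
        norms = np.linalg.norm(sk[:, j]) * np.linalg.norm(emb.scores[:, j])
        assert dot == pytest.approx(norms, rel=1e-8)


def test_pca_loadings_orthonormal_and_ordered():
    Z, _ = zscore(np.random.default_rng(4).normal(size=(100, 10)))
    emb = pca3(Z)
    np.testing.assert_allclose(emb.loadings.T @ emb.loadings, np.eye(3),
                               atol=1e-8)
    ev = emb.explained_variance_fraction
    assert (np.diff(ev) <= 1e-12).all()


def test_pca_isotropic_noise_spreads_variance():
    Z = np.random.default_rng(5).normal(size=(10_000, 10))
    Zs, _ = zscore(Z)
    emb = pca3(Zs)
    np.testing.assert_allclose(emb.explained_variance_fraction, 0.1,
                               atol=0.01)


def test_pca_planar_data_has_two_components():
    rng = np.random.default_rng(6)
    basis = rng.normal(size=(2, 10))
    coords = rng.normal(size=(50, 2))
    Z = coords @ basis
    with pytest.warns(UserWarning):
        emb = pca3(Z)
    assert emb.scores.shape[1] == 2


def test_total_variance_of_standardized_table():
    Z, _ = zscore(np.random.default_rng(7).normal(size=(500, 10)))
    assert total_variance(Z) == pytest.approx(10.0, abs=1e-8)


def test_pca_scores_invariant_to_row_permutation():
    rng = np.random.default_rng(8)
    Z, _ = zscore(rng.normal(size=(80, 10)))
    emb = pca3(Z)
    perm = rng.permutation(80)
    emb_p = pca3(Z[perm])
    np.testing.assert_allclose(emb_p.scores, emb.scores[perm], atol=1e-8)


def test_coverage_2sd_gaussian():
    rng = np.random.default_rng(9)
    neutral = rng.normal(0, 1, 200_000)
    cov = coverage_2sd(neutral, neutral)
    assert cov["within"] == pytest.approx(95.45, abs=0.3)
    shifted = coverage_2sd(neutral, neutral + 10)
    assert shifted["above"] == 100.0
    assert cov["above"] + cov["below"] + cov["within"] == pytest.approx(100)


def test_separation_score_behaviour():
    rng = np.random.default_rng(10)
    blobs = np.concatenate([rng.normal(c, 1, (100, 3))
                            for c in (0, 10, 20)])
    labels = np.repeat(["a", "b", "c"], 100)
    assert separation_score(blobs, labels) >= 0.5
    shuffled = rng.permutation(labels)
    assert abs(separation_score(blobs, shuffled)) < 0.05


def test_separation_excludes_singleton_class():
    pts = np.array([[0.0], [0.1], [5.0], [5.1], [99.0]])
    labels = np.array(["a", "a", "b", "b", "c"])
    with pytest.warns(UserWarning):
        s = separation_score(pts, labels)
    assert -1 <= s <= 1


def test_multivariate_space_beats_single_parameters(morpho_analysis):
    """No single standardized parameter (mouth opening aside) separates
    the three states as well as the 3-PC embedding — the states overlap
    feature-by-feature but split apart multivariately."""
    sil_pca = morpho_analysis["silhouette_pca"]
    singles = {k: v for k, v in morpho_analysis["silhouette_single"].items()
               if k != "mouth_opening"}
    assert sil_pca > max(singles.values())
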