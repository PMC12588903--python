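import numpy as np
import pytest

from pmtox import (
    SyntheticConfig,
    autoscale,
    fit_oplsda,
    fit_pca,
    generate_compound_table,
    hca,
    pca_q2,
    permutation_test,
    two_group_config,
)
from conftest import pair_counting_agreement


# ---------------------------------------------------------------------------
# autoscaling


def test_autoscale_unit_variance_example():
    sm = autoscale(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
    assert np.allclose(sm.values[:, 0], [-1.0, 0.0, 1.0])
    # constant column: centered zeros, flagged
    assert np.allclose(sm.values[:, 1], 0.0)
    assert list(sm.constant_columns) == [1]


def test_autoscale_modes_and_errors():
    X = np.array([[1.0, 2.0], [3.0, 8.0], [5.0, 4.0]])
    assert np.allclose(autoscale(X, "none").values, X)
    uv = autoscale(X, "unit_variance").values
    assert np.allclose(uv.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(uv.std(axis=0, ddof=1), 1.0)
    pareto = autoscale(X, "pareto").values
    assert np.allclose(pareto.std(axis=0, ddof=1), np.sqrt(X.std(axis=0, ddof=1)))
    with pytest.raises(ValueError):
        autoscale(X[:1])
    with pytest.raises(ValueError):
        autoscale(X, "rank")


# ---------------------------------------------------------------------------
# PCA


def test_pca_rank1_explains_everything():
    rng = np.random.default_rng(0)
    X = np.outer(rng.normal(size=12), rng.normal(size=5))
    X -= X.mean(axis=0)
    model = fit_pca(X, 1)
    assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_full_rank_reconstruction_and_fraction_sum():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10, 6))
    X -= X.mean(axis=0)
    k = min(X.shape[0] - 1, X.shape[1])
    model = fit_pca(X, k)
    recon = model.scores @ model.loadings.T
    assert np.allclose(recon, X, atol=1e-8)
    assert model.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)
    # fractions are non-increasing and loadings orthonormal
    assert np.all(np.diff(model.explained_variance_fraction) <= 1e-12)
    assert np.allclose(model.loadings.T @ model.loadings, np.eye(k), atol=1e-8)


def test_pca_rejects_too_many_components():
    with pytest.raises(ValueError):
        fit_pca(np.zeros((4, 3)), 4)


def test_pca_two_components_dominate_when_groups_dominate():
    # group-level profile differences with small within-group noise: the
    # between-group subspace carries most of the autoscaled variance
    cfg = SyntheticConfig(seed=3, compound_cv=0.05)
    table = generate_compound_table(cfg)
    model = fit_pca(autoscale(table.concentrations), 2)
    assert model.explained_variance_fraction.sum() > 0.6


# ---------------------------------------------------------------------------
# cross-validated Q² (Wold element-wise deletion)


def test_q2_near_one_for_rank1_structure():
    rng = np.random.default_rng(5)
    X = np.outer(rng.normal(size=30, scale=2.0), rng.normal(size=10))
    X = X + 1e-4 * rng.normal(size=X.shape)
    X -= X.mean(axis=0)
    q2 = pca_q2(X, 1, seed=1)
    assert q2[0] > 0.95


def test_q2_low_for_pure_noise():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 10))
    X -= X.mean(axis=0)
    q2 = pca_q2(X, 1, seed=1)
    assert q2[0] <= 0.1


def test_q2_deterministic_given_seed():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(21, 6))
    assert np.array_equal(pca_q2(X, 2, seed=9), pca_q2(X, 2, seed=9))


# ---------------------------------------------------------------------------
# HCA


def test_hca_separable_clouds_recovered():
    rng = np.random.default_rng(2)
    a = rng.normal(0.0, 0.2, size=(8, 3))
    b = rng.normal(5.0, 0.2, size=(7, 3))
    labels, _ = hca(np.vstack([a, b]), k=2)
    truth = [0] * 8 + [1] * 7
    assert pair_counting_agreement(truth, labels) == pytest.approx(1.0)


def test_hca_singleton_and_errors():
    labels, tree = hca(np.zeros((1, 3)), k=1)
    assert list(labels) == [1]
    with pytest.raises(ValueError):
        hca(np.zeros((3, 2)), k=4)
    with pytest.raises(ValueError):
        hca(np.zeros((3, 2)), linkage="ward", metric="correlation", k=2)


def test_hca_row_permutation_invariance():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(0, 0.3, (6, 4)), rng.normal(4, 0.3, (6, 4))])
    labels, _ = hca(X, k=2)
    perm = rng.permutation(X.shape[0])
    labels_p, _ = hca(X[perm], k=2)
    assert pair_counting_agreement(np.asarray(labels)[perm], labels_p) == pytest.approx(1.0)


def test_hca_recovers_synthetic_groups(default_table):
    scaled = autoscale(default_table.concentrations)
    labels, _ = hca(scaled.values, linkage="ward", metric="euclidean", k=4)
    truth = [default_table.group[b] for b in default_table.batch_ids]
    assert pair_counting_agreement(truth, labels) >= 0.9


# ---------------------------------------------------------------------------
# OPLS-DA


def _two_class_data(seed=0, n=24, p=6, delta=4.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X[y == "b", 0] += delta  # single variable carries the separation
    return X, y


def test_oplsda_single_informative_variable_gets_max_vip():
    X, y = _two_class_data(seed=11)
    model = fit_oplsda(autoscale(X), y, n_orthogonal=1)
    assert int(np.argmax(model.vip)) == 0
    assert model.vip[0] > 1.0


def test_vip_normalization_identity():
    X, y = _two_class_data(seed=12)
    for n_orth in (0, 1, 2):
        model = fit_oplsda(autoscale(X), y, n_orthogonal=n_orth)
        assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-8)
        assert np.sum(model.vip**2) == pytest.approx(X.shape[1], abs=1e-8)


def test_oplsda_scores_mutually_orthogonal():
    X, y = _two_class_data(seed=13, p=8)
    model = fit_oplsda(autoscale(X), y, n_orthogonal=2)
    for j in range(model.orthogonal_scores.shape[1]):
        dot = model.predictive_scores @ model.orthogonal_scores[:, j]
        assert abs(dot) < 1e-8


def test_oplsda_zero_orthogonal_equals_pls1_oracle():
    """With no orthogonal filtering the predictive component must coincide
    with the first component of an independent PLS1 implementation."""
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    rng = np.random.default_rng(21)
    X = rng.normal(size=(10, 5))
    y = rng.normal(size=10)
    y_lab = np.where(y > np.median(y), "hi", "lo")
    scaled = autoscale(X)
    model = fit_oplsda(scaled, y_lab, n_orthogonal=0)
    yc = np.where(y_lab == "hi", 1.0, -1.0)
    pls = sklearn.PLSRegression(n_components=1, scale=False)
    pls.fit(scaled.values, yc - yc.mean())
    t_ours = model.predictive_scores
    t_oracle = pls.x_scores_[:, 0]
    sign = np.sign(t_ours @ t_oracle)
    assert np.allclose(t_ours, sign * t_oracle, atol=1e-8)


def test_oplsda_rejects_single_class():
    X = np.random.default_rng(0).normal(size=(6, 3))
    with pytest.raises(ValueError):
        fit_oplsda(autoscale(X), ["a"] * 6, 1)


def test_oplsda_separates_synthetic_groups():
    cfg = two_group_config({"THSG": (12.5, 45.0), "EG": (0.3, 3.0)}, seed=4)
    table = generate_compound_table(cfg)
    y = [table.group[b] for b in table.batch_ids]
    model = fit_oplsda(autoscale(table.concentrations), y, 1)
    assert model.r2y > 0.5 and model.q2 > 0.5


# ---------------------------------------------------------------------------
# permutation test


def test_permutation_valid_on_separable_data():
    cfg = two_group_config({"THSG": (12.5, 45.0), "EG": (0.3, 3.0)}, seed=5)
    table = generate_compound_table(cfg)
    y = [table.group[b] for b in table.batch_ids]
    report = permutation_test(autoscale(table.concentrations), y, 1,
                              n_permutations=200, seed=1)
    assert report.valid
    assert report.q2_intercept < 0
    assert report.permuted_q2.size == 200
    assert np.all(report.permuted_q2 < report.original_q2)


def test_permutation_invalid_on_label_independent_noise():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(38, 26))
    y = ["a"] * 19 + ["b"] * 19
    report = permutation_test(autoscale(X), y, 1, n_permutations=200, seed=2)
    assert not report.valid


def test_oplsda_auto_orthogonal_selection():
    cfg = two_group_config({"THSG": (12.5, 45.0), "EG": (0.3, 3.0)}, seed=6)
    table = generate_compound_table(cfg)
    y = [table.group[b] for b in table.batch_ids]
    model = fit_oplsda(autoscale(table.concentrations), y, n_orthogonal="auto")
    # auto mode returns a fitted model whose Q2 is not beaten by >=0.01 by
    # adding one more orthogonal component
    more = fit_oplsda(autoscale(table.concentrations), y, model.n_orthogonal + 1)
    assert more.q2 < model.q2 + 0.01
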