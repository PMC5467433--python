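"""Sparse PLS core: SVD oracle for the dense case, a frozen mixOmics
cross-check for the sparse case, keep-count invariants, and the masked
correlation matrix."""

import numpy as np
import pytest

from omicnet import (
    SplsConfig,
    association_ma,
    dependency_pairs,
    generate_blocks,
    log_transform,
    spls_fit,
)
from omicnet.spls import SplsFit, soft_threshold


def _standardize(a):
    return (a - a.mean(0)) / a.std(0, ddof=1)


def _sign_fix(v):
    return v * np.sign(v[np.argmax(np.abs(v))])


def test_soft_threshold_definition():
    assert soft_threshold(np.array([0.5]), 0.2)[0] == pytest.approx(0.3)
    assert soft_threshold(np.array([-0.5]), 0.2)[0] == pytest.approx(-0.3)
    assert soft_threshold(np.array([0.1]), 0.2)[0] == 0.0


def test_dense_single_component_equals_svd(rng):
    """With no sparsity and one component, the loadings are the leading
    singular vectors of the standardized cross-product matrix."""
    X = rng.normal(size=(20, 15))
    Y = rng.normal(size=(20, 10))
    fit = spls_fit(X, Y, SplsConfig(ncomp=1))
    M = _standardize(X).T @ _standardize(Y)
    u_svd, _, vt = np.linalg.svd(M)
    np.testing.assert_allclose(
        fit.x_loadings[:, 0], _sign_fix(u_svd[:, 0]), atol=1e-8
    )
    np.testing.assert_allclose(
        fit.y_loadings[:, 0], _sign_fix(vt[0]), atol=1e-8
    )


def test_identical_blocks_select_identically(rng):
    X = rng.normal(size=(15, 8))
    fit = spls_fit(X, X.copy(), SplsConfig(ncomp=1))
    assert fit.selected_x[0] == fit.selected_y[0]
    np.testing.assert_allclose(fit.x_scores[:, 0], fit.y_scores[:, 0], atol=1e-8)


def test_keep_counts_and_orthogonal_scores(rng):
    for _ in range(20):
        n, nx, ny = 12, 9, 7
        X = rng.normal(size=(n, nx))
        Y = rng.normal(size=(n, ny))
        kx, ky = int(rng.integers(1, nx + 1)), int(rng.integers(1, ny + 1))
        ncomp = int(rng.integers(1, 4))
        fit = spls_fit(X, Y, SplsConfig(ncomp=ncomp, keep_x=kx, keep_y=ky))
        for h in range(ncomp):
            assert np.count_nonzero(fit.x_loadings[:, h]) <= kx
            assert np.count_nonzero(fit.y_loadings[:, h]) <= ky
            assert np.linalg.norm(fit.x_loadings[:, h]) == pytest.approx(1.0)
        gram = fit.x_scores.T @ fit.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


def test_sparse_fit_matches_mixomics_oracle():
    """Frozen oracle: mixOmics::spls (regression mode, scale=TRUE,
    ncomp=2, keepX=3, keepY=2) on this exact fixture (seed 7) selects
    these supports with these loading magnitudes."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(12, 8))
    Y = 0.5 * X[:, :6] + rng.normal(size=(12, 6))
    fit = spls_fit(X, Y, SplsConfig(ncomp=2, keep_x=3, keep_y=2))
    assert fit.selected_x == [{0, 5, 6}, {2, 4, 7}]
    assert fit.selected_y == [{0, 5}, {1, 2}]
    oracle_x = {
        (0, 0): 0.39496604,
        (5, 0): 0.90345379,
        (6, 0): 0.16665256,
        (2, 1): 0.44280945,
        (4, 1): 0.19337062,
        (7, 1): 0.87551562,
    }
    oracle_y = {
        (0, 0): 0.91890064,
        (5, 0): 0.39448904,
        (1, 1): 0.57090081,
        (2, 1): 0.82101904,
    }
    for (i, h), v in oracle_x.items():
        assert abs(fit.x_loadings[i, h]) == pytest.approx(v, abs=5e-3)
    for (j, h), v in oracle_y.items():
        assert abs(fit.y_loadings[j, h]) == pytest.approx(v, abs=5e-3)


def test_fit_input_validation(rng):
    X = rng.normal(size=(10, 5))
    Y = rng.normal(size=(9, 4))
    with pytest.raises(ValueError, match="sample mismatch"):
        spls_fit(X, Y, SplsConfig(ncomp=1))
    with pytest.raises(ValueError, match="ncomp"):
        spls_fit(X, rng.normal(size=(10, 4)), SplsConfig(ncomp=5))
    Xc = X.copy()
    Xc[:, 0] = 3.0
    with pytest.raises(ValueError, match="constant column"):
        spls_fit(Xc, rng.normal(size=(10, 4)), SplsConfig(ncomp=1))


def test_planted_pair_is_selected_under_sparsity():
    """A single planted |r| = 0.9 pair among pure-noise features should
    enter the first sparse component's selected sets in nearly every
    seeded run.  Small panels (8 features a side, 30 samples) keep the
    planted covariance dominant over the noise spectrum; in larger noise
    panels the leading singular direction is noise-dominated and no
    method could single the pair out on component 1.
    """
    from omicnet import BlockSpec, PlantedPair, SimConfig

    hits = 0
    runs = 100
    for seed in range(runs):
        cfg = SimConfig(
            block_specs=[
                BlockSpec("a", 8, 30),
                BlockSpec("b", 8, 30),
            ],
            planted_pairs=[PlantedPair("a", 3, "b", 4, 0.9)],
            seed=500 + seed,
        )
        blocks, _ = generate_blocks(cfg)
        bx, by = (log_transform(b) for b in blocks)
        shared = [s for s in bx.sample_ids if s in set(by.sample_ids)]
        X = bx.subset_samples(shared).values.T
        Y = by.subset_samples(shared).values.T
        fit = spls_fit(X, Y, SplsConfig(ncomp=1, keep_x=5, keep_y=5))
        if 3 in fit.selected_x[0] and 4 in fit.selected_y[0]:
            hits += 1
    assert hits >= 0.95 * runs


# ------------------------------------------------------ dependency pairs


def _fit_with(selected_x, selected_y, nx=3, ny=3):
    ncomp = len(selected_x)
    U = np.zeros((nx, ncomp))
    V = np.zeros((ny, ncomp))
    for h, (sx, sy) in enumerate(zip(selected_x, selected_y)):
        for i in sx:
            U[i, h] = 1.0
        for j in sy:
            V[j, h] = 1.0
    return SplsFit(
        x_loadings=U,
        y_loadings=V,
        x_scores=np.zeros((4, ncomp)),
        y_scores=np.zeros((4, ncomp)),
        selected_x=[set(s) for s in selected_x],
        selected_y=[set(s) for s in selected_y],
    )


def test_dependency_pairs_singleton_and_disjoint():
    assert dependency_pairs(_fit_with([{0}], [{1}])) == {(0, 1)}
    # pairing is per component: no cross terms between components
    assert dependency_pairs(_fit_with([{0}, {1}], [{0}, {1}])) == {
        (0, 0),
        (1, 1),
    }


def test_dependency_pairs_full_keep_is_all_pairs():
    fit = _fit_with([{0, 1, 2}], [{0, 1, 2}])
    assert dependency_pairs(fit) == {(i, j) for i in range(3) for j in range(3)}


# ------------------------------------------------------ association matrix


def test_association_matrix_values(rng):
    X = rng.normal(size=(10, 3))
    Y = rng.normal(size=(10, 3))
    Y[:, 0] = X[:, 0]  # identical columns
    ma = association_ma(X, Y, {(0, 0)})
    assert ma[0, 0] == pytest.approx(1.0)
    assert np.all(ma[ma != ma[0, 0]] == 0.0)  # Eq-zero branch everywhere else


def test_association_hand_pearson():
    X = np.array([[1.0], [2.0], [3.0]])
    Y = np.array([[6.0], [4.0], [2.0]])
    ma = association_ma(X, Y, {(0, 0)})
    assert ma[0, 0] == pytest.approx(-1.0)


def test_association_non_dependent_is_exactly_zero(rng):
    X = rng.normal(size=(8, 2))
    Y = np.column_stack([X[:, 0], rng.normal(size=8)])
    ma = association_ma(X, Y, {(1, 1)})
    assert ma[0, 0] == 0.0  # truly correlated but not dependent
    assert ma[1, 1] != 0.0


def test_association_zero_variance_error(rng):
    X = rng.normal(size=(8, 2))
    X[:, 1] = 5.0
    Y = rng.normal(size=(8, 2))
    with pytest.raises(ValueError, match="zero-variance feature 1 of X"):
        association_ma(X, Y, {(1, 0)})


def test_association_values_in_unit_interval(rng):
    X = rng.normal(size=(20, 6))
    Y = rng.normal(size=(20, 5))
    pairs = {(i, j) for i in range(6) for j in range(5)}
    ma = association_ma(X, Y, pairs)
    assert np.all(np.abs(ma) <= 1.0 + 1e-12)
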