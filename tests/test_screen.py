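"""Differential screen: log transform, cell-means OLS, empirical-Bayes
moderation (checked against a frozen limma run), BH FDR and selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from omicnet import (
    BlockSpec,
    OmicsBlock,
    SimConfig,
    bh_adjust,
    fit_group_model,
    generate_blocks,
    log_transform,
    moderate_statistics,
    screen_block,
    select_significant,
)


def _block(values, groups_per_sample, reference="g1", data_type="toy"):
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    samples = [f"s{j}" for j in range(ns)]
    return OmicsBlock(
        values=values,
        feature_ids=[f"f{i}" for i in range(nf)],
        sample_ids=samples,
        data_type=data_type,
        groups=dict(zip(samples, groups_per_sample)),
        reference_group=reference,
    )


# ---------------------------------------------------------------- log2


def test_log_transform_values(toy_block):
    assert log_transform(_block([[8.0]], ["g1"], reference=None)).values[0, 0] == 3.0
    assert (
        log_transform(_block([[0.0]], ["g1"], reference=None), offset=1.0).values[0, 0]
        == 0.0
    )
    ones = _block(np.ones((3, 4)), ["g1"] * 4, reference=None)
    assert np.all(log_transform(ones).values == 0.0)
    out = log_transform(toy_block)
    assert out.sample_ids == toy_block.sample_ids
    assert out.data_type == toy_block.data_type


def test_log_transform_rejects_nonpositive_and_names_cell():
    block = _block([[4.0, 0.0]], ["g1", "g1"], reference=None)
    with pytest.raises(ValueError, match=r"feature 'f0'.*sample 's1'"):
        log_transform(block)


# ------------------------------------------------------- group model


def test_group_model_exact_means_zero_variance():
    block = _block([[1, 1, 3, 3]], ["g1", "g1", "g2", "g2"])
    fit = fit_group_model(block)
    assert fit.coefficients[0, 0] == 2.0
    assert fit.residual_variances[0] == 0.0


def test_group_model_hand_ols_two_groups():
    """Hand OLS on 4 points: means 1 and 2, RSS = 4 over df = 2."""
    block = _block([[0, 2, 1, 3]], ["g1", "g1", "g2", "g2"])
    fit = fit_group_model(block)
    assert fit.coefficients[0, 0] == pytest.approx(1.0)
    assert fit.residual_df == 2
    assert fit.residual_variances[0] == pytest.approx(2.0)
    assert fit.stdev_unscaled[0] == pytest.approx(1.0)  # sqrt(1/2 + 1/2)


def test_group_model_invariant_to_sample_order(rng):
    values = rng.normal(size=(5, 9))
    groups = ["g1", "g1", "g1", "g2", "g2", "g2", "g3", "g3", "g3"]
    block = _block(values, groups)
    perm = rng.permutation(9)
    shuffled = _block(values[:, perm], [groups[j] for j in perm])
    a, b = fit_group_model(block), fit_group_model(shuffled)
    np.testing.assert_allclose(a.coefficients, b.coefficients)
    np.testing.assert_allclose(a.residual_variances, b.residual_variances)


def test_group_model_errors():
    with pytest.raises(ValueError, match="residual degrees"):
        fit_group_model(_block([[1, 2]], ["g1", "g2"]))
    block = _block([[1, 2, 3]], ["g1", "g1", "g1"])
    with pytest.raises(ValueError, match="non-reference"):
        fit_group_model(block)


# ------------------------------------------------------- moderation


def _toy_fit(rng, nf=40):
    groups = ["g1"] * 4 + ["g2"] * 4 + ["g3"] * 4
    vals = rng.normal(5, 1, size=(nf, 12)) * rng.uniform(0.5, 2, size=(nf, 1))
    vals[:5, 4:8] += 2.0
    return fit_group_model(_block(vals, groups))


def test_prior_df_zero_recovers_ordinary_t(rng):
    fit = _toy_fit(rng)
    mod = moderate_statistics(fit, prior_df=0.0)
    ordinary = fit.coefficients / (
        np.sqrt(fit.residual_variances)[:, None] * fit.stdev_unscaled[None, :]
    )
    np.testing.assert_allclose(mod["moderated_t"], ordinary)


def test_prior_df_infinite_pins_variances(rng):
    fit = _toy_fit(rng)
    mod = moderate_statistics(fit, prior_df=np.inf, prior_variance=1.7)
    assert np.all(mod["posterior_variances"] == 1.7)


def test_moderated_stats_match_limma_oracle():
    """Frozen oracle: limma lmFit/contrasts.fit/eBayes on this exact
    fixture (seed 42) gives these prior and per-feature statistics."""
    fit = _toy_fit(np.random.default_rng(42))
    mod = moderate_statistics(fit)
    assert mod["prior_df"] == pytest.approx(4.396334551, rel=1e-8)
    assert mod["prior_variance"] == pytest.approx(0.8822056653, rel=1e-8)
    expected_t = np.array(
        [
            [0.80412535579, -0.07103819389],
            [2.10336521781, -0.28510284686],
            [3.15446307545, 0.13923363489],
        ]
    )
    expected_p = np.array(
        [
            [0.435362707909, 0.944416950359],
            [0.054860347618, 0.779925523659],
            [0.007364427746, 0.891336980908],
        ]
    )
    np.testing.assert_allclose(mod["moderated_t"][:3], expected_t, rtol=1e-8)
    np.testing.assert_allclose(mod["p_values"][:3], expected_p, rtol=1e-8)


def test_null_p_values_are_uniform(rng):
    groups = ["g1"] * 6 + ["g2"] * 6
    vals = rng.normal(0, 1, size=(500, 12))
    mod = moderate_statistics(fit_group_model(_block(vals, groups)))
    ks = stats.kstest(mod["p_values"][:, 0], "uniform")
    assert ks.pvalue > 0.01


def test_all_zero_variances_error():
    block = _block([[1, 1, 2, 2], [3, 3, 5, 5]], ["g1", "g1", "g2", "g2"])
    with pytest.raises(ValueError, match="moderation undefined"):
        moderate_statistics(fit_group_model(block))


# --------------------------------------------------------------- BH


def _bh_brute_force(p):
    """Literal step-up definition: adj_i = min over p_j >= p_i of
    min(1, n*p_j/rank_j)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, n * p[i] / rank)
        adj[i] = running
    return adj


def test_bh_worked_example():
    np.testing.assert_allclose(
        bh_adjust(np.array([0.01, 0.02, 0.03, 0.04, 0.05])), [0.05] * 5
    )
    assert bh_adjust(np.array([0.5]))[0] == 0.5
    np.testing.assert_allclose(bh_adjust(np.ones(4)), np.ones(4))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.1, 1.2]))
    with pytest.raises(ValueError):
        bh_adjust(np.array([-0.1]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
)
def test_bh_matches_brute_force_and_is_monotone(p_list):
    p = np.array(p_list)
    adj = bh_adjust(p)
    np.testing.assert_allclose(adj, _bh_brute_force(p), atol=1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)


# -------------------------------------------------------- selection


def test_select_threshold_logic():
    fdr = np.array([[0.2, 0.04, 0.9], [0.3, 0.3, 0.3]])
    assert select_significant(fdr, ["f1", "f2"], 0.05) == {"f1"}
    assert select_significant(fdr, ["f1", "f2"], 1.0) == {"f1", "f2"}


def test_empty_selection_warns_not_raises():
    fdr = np.array([[0.9, 0.9]])
    with pytest.warns(UserWarning, match="no feature passed"):
        assert select_significant(fdr, ["f1"], 0.001) == set()


def test_screen_recovers_planted_responsive_features():
    """Power check by direct simulation: at effect 3x the noise sd and
    6 mice/group, >= 90% of planted diet-responsive features are
    recovered at FDR 0.05 (averaged over seeds)."""
    recalls = []
    for seed in range(10):
        cfg = SimConfig(
            block_specs=[
                BlockSpec("a", 200, 36, responsive_fraction=0.2),
                BlockSpec("b", 5, 36),
            ],
            effect_size=3.0,
            seed=100 + seed,
        )
        blocks, truth = generate_blocks(cfg)
        res = screen_block(blocks[0], fdr_threshold=0.05)
        planted = truth.responsive_features["a"]
        recalls.append(len(planted & res.selected_features) / len(planted))
    assert np.mean(recalls) >= 0.9


def test_screen_false_discovery_fraction_controlled():
    """On pure-null blocks the average fraction of selected features at
    threshold q stays at or below q (200 simulated repeats)."""
    q = 0.05
    gen = np.random.default_rng(2024)
    groups = np.repeat([f"g{k}" for k in range(6)], 6)
    fracs = []
    for _ in range(200):
        vals = gen.normal(6, 1, size=(100, 36))
        block = _block(vals, list(groups))
        res = screen_block(block, fdr_threshold=q, already_log=True)
        fracs.append(len(res.selected_features) / 100)
    assert np.mean(fracs) <= q


def test_screen_invariant_to_feature_order(toy_block):
    res = screen_block(toy_block, fdr_threshold=1.0)
    flipped = OmicsBlock(
        values=toy_block.values[::-1].copy(),
        feature_ids=toy_block.feature_ids[::-1],
        sample_ids=toy_block.sample_ids,
        data_type=toy_block.data_type,
        groups=toy_block.groups,
        reference_group=toy_block.reference_group,
    )
    res2 = screen_block(flipped, fdr_threshold=1.0)
    np.testing.assert_allclose(
        res.p_values, res2.p_values[::-1], rtol=1e-10
    )
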