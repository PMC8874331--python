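import numpy as np
import pytest
import scipy.linalg

from cranioshape.integration import (
    pls_axis_shapes,
    pls_group_slopes,
    pls_permutation_test,
    rv_coefficient,
    two_block_pls,
)
from cranioshape.morphospace import pca
from cranioshape.procrustes import gpa
from cranioshape.simulate import default_config, simulate_shape_cohort

from conftest import make_aligned


def _noise_blocks(rng, n=20, k1=3, k2=4, d=2, groups=None):
    g = groups or ["G"] * n
    b1 = make_aligned(rng.standard_normal((n, k1, d)), groups=g)
    b2 = make_aligned(rng.standard_normal((n, k2, d)), groups=g)
    return b1, b2


# ---------------------------------------------------------------------------
# two-block PLS
# ---------------------------------------------------------------------------

def test_self_covariation_duplicated_block(rng):
    b1, _ = _noise_blocks(rng, n=15)
    result = two_block_pls(b1, b1)
    assert result.axis_correlations[0] == pytest.approx(1.0, abs=1e-9)
    assert result.rv == pytest.approx(1.0, abs=1e-9)
    # axis-1 share of squared covariance equals PC1's share of squared
    # eigenvalue mass (covariance of a block with itself)
    eig = pca(b1).eigenvalues
    expected = 100.0 * eig[0] ** 2 / np.sum(eig**2)
    assert result.percent_covariance[0] == pytest.approx(expected, rel=1e-9)
    assert pls_group_slopes(result)["G"] == pytest.approx(1.0, abs=1e-12)


def test_singular_values_match_independent_svd(rng):
    b1, b2 = _noise_blocks(rng, n=18)
    result = two_block_pls(b1, b2)
    X = b1.flattened()
    Y = b2.flattened()
    C = (X - X.mean(axis=0)).T @ (Y - Y.mean(axis=0)) / (X.shape[0] - 1)
    oracle = scipy.linalg.svdvals(C)
    np.testing.assert_allclose(result.singular_values, oracle[: result.n_axes], atol=1e-12)
    # total squared covariance identity
    assert np.sum(result.singular_values**2) == pytest.approx(
        np.sum(C**2), rel=1e-9
    )
    assert result.percent_covariance.sum() == pytest.approx(100.0, abs=1e-6)


def test_axis_pairs_are_uncorrelated_across_blocks(rng):
    """Distinct axis pairs carry no shared covariation: the axes are
    orthonormal within each block and the cross-block covariance between
    non-matching score columns is zero."""
    b1, b2 = _noise_blocks(rng, n=25)
    result = two_block_pls(b1, b2)
    for axes in (result.block1_axes, result.block2_axes):
        gram = axes @ axes.T
        np.testing.assert_allclose(gram, np.eye(axes.shape[0]), atol=1e-10)
    cross = result.block1_scores.T @ result.block2_scores / (result.n - 1)
    off_diag = cross - np.diag(np.diag(cross))
    assert np.max(np.abs(off_diag)) <= 1e-10 * max(1.0, np.max(np.abs(cross)))


def test_pls_ordering_invariance(rng):
    b1, b2 = _noise_blocks(rng, n=12)
    result = two_block_pls(b1, b2)
    perm = list(rng.permutation(12))
    ids = [b1.specimen_ids[i] for i in perm]
    result2 = two_block_pls(b1.subset(ids), b2.subset(ids))
    np.testing.assert_allclose(result.singular_values, result2.singular_values, atol=1e-12)
    assert result.rv == pytest.approx(result2.rv, abs=1e-12)


def test_pls_requires_overlap_and_n(rng):
    b1, b2 = _noise_blocks(rng, n=5)
    b2.specimen_ids = [f"other{i}" for i in range(5)]
    b2.groups = {s: "G" for s in b2.specimen_ids}
    with pytest.raises(ValueError, match="overlap"):
        two_block_pls(b1, b2)
    s1, s2 = _noise_blocks(rng, n=2)
    with pytest.raises(ValueError):
        two_block_pls(s1, s2)


def test_pls_axis_shapes_identities(rng):
    b1, b2 = _noise_blocks(rng, n=10)
    result = two_block_pls(b1, b2)
    s1, s2 = pls_axis_shapes(result, 0, 0.0)
    np.testing.assert_allclose(s1, result.block1_mean)
    np.testing.assert_allclose(s2, result.block2_mean)
    plus1, _ = pls_axis_shapes(result, 0, 0.1)
    minus1, _ = pls_axis_shapes(result, 0, -0.1)
    np.testing.assert_allclose((plus1 + minus1) / 2, result.block1_mean, atol=1e-12)
    # projecting the block-1 shape back on its axis recovers the score
    recovered = (plus1.reshape(-1) - result.block1_mean.reshape(-1)) @ result.block1_axes[0]
    assert recovered == pytest.approx(0.1, abs=1e-9)


# ---------------------------------------------------------------------------
# RV coefficient
# ---------------------------------------------------------------------------

def test_rv_self_is_one(rng):
    X = rng.standard_normal((12, 6))
    assert rv_coefficient(X, X) == pytest.approx(1.0, abs=1e-12)


def test_rv_single_columns_reduce_to_squared_pearson(rng):
    x = rng.standard_normal(30)
    y = 0.6 * x + rng.standard_normal(30)
    r = np.corrcoef(x, y)[0, 1]
    assert rv_coefficient(x, y) == pytest.approx(r**2, rel=1e-9)


def test_rv_hand_computed_two_variable_blocks():
    X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 3.0]])
    Y = np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0], [4.0, 4.0]])
    n = 4
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S11 = Xc.T @ Xc / (n - 1)
    S22 = Yc.T @ Yc / (n - 1)
    S12 = Xc.T @ Yc / (n - 1)
    hand = np.trace(S12 @ S12.T) / np.sqrt(np.trace(S11 @ S11) * np.trace(S22 @ S22))
    assert rv_coefficient(X, Y) == pytest.approx(hand, rel=1e-12)


def test_rv_orthogonal_invariance(rng):
    X = rng.standard_normal((15, 5))
    Y = rng.standard_normal((15, 7))
    base = rv_coefficient(X, Y)
    Q, _ = np.linalg.qr(rng.standard_normal((7, 7)))
    assert abs(rv_coefficient(X, Y @ Q) - base) <= 1e-9


def test_rv_zero_variance_errors():
    with pytest.raises(ValueError):
        rv_coefficient(np.zeros((5, 3)), np.random.default_rng(0).standard_normal((5, 3)))


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def test_pls_permutation_p_lower_bound(rng):
    b1, b2 = _noise_blocks(rng, n=8)
    result = two_block_pls(b1, b2)
    for statistic in ("rv", "axis1_singular_value"):
        p = pls_permutation_test(result, n_permutations=19, seed=0, statistic=statistic).p_value
        assert p >= 1 / 20


def test_pls_permutation_power_with_latent_factor():
    cfg = default_config(seed=5, integration_strength=3.0)
    cfg.groups = {"G": 20}
    cfg.stages = {"PD14": 1.0}
    cohort = simulate_shape_cohort(cfg)
    b = gpa(cohort.sample_set("brain", "PD14"))
    s = gpa(cohort.sample_set("skull", "PD14"))
    result = two_block_pls(b, s)
    p = pls_permutation_test(result, n_permutations=999, seed=7).p_value
    assert p <= 0.01


def test_pls_permutation_type_i_error():
    """Independent blocks: rejection rate at alpha=0.05 inside the 95%
    binomial interval over 500 simulated datasets."""
    n_sims = 500
    rejections = 0
    for i in range(n_sims):
        rng_i = np.random.default_rng(31_000 + i)
        b1, b2 = _noise_blocks(rng_i, n=15, k1=3, k2=3, d=2)
        result = two_block_pls(b1, b2)
        p = pls_permutation_test(result, n_permutations=199, seed=i).p_value
        rejections += p <= 0.05
    rate = rejections / n_sims
    half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
    assert 0.05 - half_width <= rate <= 0.05 + half_width


def test_independent_blocks_axis_correlation_matches_permutation_oracle(rng):
    """At large n the (upward-biased) axis-1 correlation of truly
    independent blocks matches the value obtained after explicitly breaking
    the pairing, which realizes the same independence null."""
    n_rep = 40
    observed = np.empty(n_rep)
    oracle = np.empty(n_rep)
    for i in range(n_rep):
        rng_i = np.random.default_rng(52_000 + i)
        b1, b2 = _noise_blocks(rng_i, n=200, k1=3, k2=3, d=2)
        observed[i] = abs(two_block_pls(b1, b2).axis_correlations[0])
        ids = list(rng_i.permutation(b2.specimen_ids))
        shuffled = b2.subset(ids)
        shuffled.specimen_ids = b2.specimen_ids  # re-pair rows arbitrarily
        shuffled.groups = b2.groups
        oracle[i] = abs(two_block_pls(b1, shuffled).axis_correlations[0])
    se = np.sqrt(observed.var(ddof=1) / n_rep + oracle.var(ddof=1) / n_rep)
    assert abs(observed.mean() - oracle.mean()) <= 1.96 * se


def test_recovery_increases_with_integration_strength():
    """Estimated RV and axis-1 correlation respond monotonically to the
    generating strength (small replicate version; the full grid runs in the
    acceptance suite)."""
    def mean_stats(rho, n_rep=15):
        rvs, corrs = [], []
        for i in range(n_rep):
            cfg = default_config(seed=9000 + i, integration_strength=rho)
            cfg.groups = {"G": 25}
            cfg.stages = {"PD14": 1.0}
            cohort = simulate_shape_cohort(cfg)
            b = gpa(cohort.sample_set("brain", "PD14"))
            s = gpa(cohort.sample_set("skull", "PD14"))
            result = two_block_pls(b, s)
            rvs.append(result.rv)
            corrs.append(result.axis_correlations[0])
        return np.mean(rvs), np.mean(corrs)

    rv0, corr0 = mean_stats(0.0)
    rv4, corr4 = mean_stats(4.0)
    assert rv4 > rv0
    assert corr4 > corr0
    assert corr4 >= 0.9
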