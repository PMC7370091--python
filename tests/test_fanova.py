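"""RW2 structure and functional-ANOVA posterior correctness."""

import numpy as np
import pytest
from scipy import linalg

import respfanova as rf
from respfanova.fanova import (
    HyperGridConfig,
    _FanovaCore,
    normalize_weights,
)

from conftest import make_single_var_config, make_toy_dataset


# ---------------------------------------------------------------------------
# RW2 prior structure
# ---------------------------------------------------------------------------


def test_rw2_n4_matches_hand_computation():
    Q = rf.build_rw2(4).Q
    expected = np.array(
        [[1, -2, 1, 0], [-2, 5, -4, 1], [1, -4, 5, -2], [0, 1, -2, 1]], dtype=float
    )
    assert np.array_equal(Q, expected)


@pytest.mark.parametrize("n", [4, 10, 50, 121])
@pytest.mark.parametrize("scaled", [False, True])
def test_rw2_null_space_and_rank(n, scaled):
    prior = rf.build_rw2(n, scaled=scaled)
    ones = np.ones(n)
    lin = np.arange(n, dtype=float)
    assert np.allclose(prior.Q @ ones, 0.0, atol=1e-9)
    assert np.allclose(prior.Q @ lin, 0.0, atol=1e-7)
    assert np.linalg.matrix_rank(prior.Q, tol=1e-8 * n) == n - 2


@pytest.mark.parametrize("n", [4, 10, 50, 121])
def test_rw2_scaled_reference_variance_geometric_mean_one(n):
    prior = rf.build_rw2(n, scaled=True)
    # independent route: eigendecomposition-based pseudo-inverse diagonal
    vals, vecs = np.linalg.eigh(prior.Q)
    sigma2 = (vecs[:, 2:] ** 2 / vals[2:][None, :]).sum(axis=1)
    assert np.isclose(np.exp(np.mean(np.log(sigma2))), 1.0, atol=1e-6)


def test_rw2_too_small_grid_rejected():
    with pytest.raises(ValueError):
        rf.build_rw2(2)


# ---------------------------------------------------------------------------
# Posterior vs dense brute force
# ---------------------------------------------------------------------------


def dense_reference(series, grid, theta, scaled=True):
    """Brute-force GLS via an explicit observation-by-latent design matrix."""
    n = len(grid)
    Q = rf.build_rw2(n, scaled=scaled).Q
    rows, ys = [], []
    for (subj, cond, var), y in sorted(series.items()):
        for k in range(n):
            a = np.zeros(2 * n)
            a[k] = 1.0
            if cond == "FB":
                a[n + k] = 1.0
            rows.append(a)
            ys.append(y[k])
    A, y = np.array(rows), np.array(ys)
    tau = np.exp(theta[2])
    Qpr = np.zeros((2 * n, 2 * n))
    Qpr[:n, :n] = np.exp(theta[0]) * Q
    Qpr[n:, n:] = np.exp(theta[1]) * Q
    Qpost = Qpr + tau * A.T @ A
    mean = np.linalg.solve(Qpost, tau * A.T @ y)
    var = np.diag(np.linalg.inv(Qpost))
    return mean, var


@pytest.mark.parametrize("n,n_subjects", [(6, 1), (10, 3), (20, 2)])
def test_posterior_matches_dense_oracle(n, n_subjects):
    rng = np.random.default_rng(123)
    grid = 60.0 + 5.0 * np.arange(n)
    per_subject = {
        f"S{j}": {
            "ONB": 100 + rng.normal(0, 5, n),
            "FB": 103 + rng.normal(0, 5, n),
        }
        for j in range(n_subjects)
    }
    ds = make_toy_dataset(grid, per_subject)
    theta = (1.0, 0.5, np.log(1 / 25.0))
    fit = rf.fit(ds, "HR", hyper=HyperGridConfig(n_points=1, center=theta))
    mean, var = dense_reference(ds.series, grid, theta)
    got_mean = np.concatenate([fit.mu_mean, fit.alpha_mean])
    got_var = np.concatenate([fit.mu_sd, fit.alpha_sd]) ** 2
    assert np.abs(got_mean - mean).max() < 1e-8
    assert np.abs(got_var - var).max() < 1e-8


def test_constant_shift_identified_noise_free():
    n = 12
    grid = 60.0 + 5.0 * np.arange(n)
    mu = 80.0 + 0.1 * np.arange(n)
    ds = make_toy_dataset(
        grid,
        {f"S{j}": {"ONB": mu.copy(), "FB": mu + 2.0} for j in range(3)},
    )
    # diffuse effect prior, tight likelihood
    fit = rf.fit(
        ds, "HR", hyper=HyperGridConfig(n_points=1, center=(0.0, -10.0, np.log(1e6)))
    )
    assert np.abs(fit.alpha_mean[2:-2] - 2.0).max() < 1e-3


def test_null_effect_stays_within_three_posterior_sds(single_var_config):
    cfg = single_var_config(
        effect=rf.EffectCurve("zero"),
        sigma=0.05,
        n_subjects=50,
        grid_step_s=20.0,
        seed=0,
    )
    fit = rf.fit(rf.generate_dataset(cfg), "Tin")
    assert np.all(np.abs(fit.alpha_mean) < 3.0 * fit.alpha_sd)


def test_increasing_residual_precision_never_inflates_alpha_sd(single_var_config):
    ds = rf.generate_dataset(single_var_config(grid_step_s=30.0, seed=4))
    sds = []
    for log_tau in (0.0, 1.0, 2.0):
        f = rf.fit(
            ds, "Tin", hyper=HyperGridConfig(n_points=1, center=(1.0, 1.0, log_tau))
        )
        sds.append(f.alpha_sd.mean())
    assert sds[0] >= sds[1] >= sds[2]


def test_subject_intercept_variant_runs_and_recovers_effect(single_var_config):
    cfg = single_var_config(
        sigma=0.2, sigma_subject=0.3, grid_step_s=30.0, n_subjects=12, seed=9
    )
    ds = rf.generate_dataset(cfg)
    f = rf.fit(ds, "Tin", subject_intercept=True)
    assert np.isfinite(f.alpha_mean).all() and np.isfinite(f.alpha_sd).all()
    assert abs(f.alpha_mean.mean() - 0.4) < 0.2


# ---------------------------------------------------------------------------
# Evidence and mixture weights
# ---------------------------------------------------------------------------


def test_prior_normalization_doubling_identity(single_var_config):
    ds = rf.generate_dataset(single_var_config(grid_step_s=30.0))
    core = _FanovaCore(ds, "Tin")
    core.N = 0  # no-data model: only the prior pseudo-determinant term remains
    n = ds.grid.size
    base = core.log_marginal_likelihood(np.array([1.0, 2.0, 0.0]))
    doubled = core.log_marginal_likelihood(np.array([1.0 + np.log(2), 2.0 + np.log(2), 0.0]))
    assert np.isclose(doubled - base, (n - 2) * np.log(2.0), atol=1e-10)


def test_single_node_weight_is_one(single_var_config):
    ds = rf.generate_dataset(single_var_config(grid_step_s=30.0))
    f = rf.fit(ds, "Tin", hyper=HyperGridConfig(n_points=1, center=(1.0, 1.0, 1.0)))
    assert np.allclose(f.hyper.weights, [1.0])


def test_weights_normalized_and_shift_invariant(single_var_config):
    ds = rf.generate_dataset(single_var_config(grid_step_s=30.0))
    f = rf.fit(ds, "Tin", hyper=HyperGridConfig(n_points=3, span=1.0))
    w = f.hyper.weights
    assert np.isclose(w.sum(), 1.0)
    assert np.all(w >= 0)
    assert np.allclose(normalize_weights(f.hyper.log_marginal + 123.4), w)
    # equal evidence -> equal weights
    assert np.allclose(normalize_weights(np.array([5.0, 5.0])), [0.5, 0.5])


def test_log_marginal_likelihood_public_api(single_var_config):
    ds = rf.generate_dataset(single_var_config(grid_step_s=30.0))
    val = rf.log_marginal_likelihood(ds, "Tin", (1.0, 1.0, 1.0))
    assert np.isfinite(val)


def test_missing_variable_is_lookup_error(single_var_config):
    ds = rf.generate_dataset(single_var_config(grid_step_s=30.0))
    with pytest.raises(KeyError):
        rf.fit(ds, "VE")
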