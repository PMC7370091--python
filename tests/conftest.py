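import numpy as np
import pytest
from scipy import linalg

import respfanova as rf
from respfanova.fanova import FanovaFit, HyperGrid


def make_single_var_config(
    name="Tin",
    effect=rf.EffectCurve("constant", 0.4),
    sigma=0.2,
    n_subjects=18,
    grid_end_s=660.0,
    grid_step_s=5.0,
    sigma_subject=0.0,
    seed=1,
):
    return rf.SimConfig(
        variables=[rf.VARIABLES[name]],
        mean_curves={name: rf.MeanCurve(baseline=1.0, amplitude=0.3, tau_s=60.0)},
        effect_curves={name: effect},
        sigma_noise={name: sigma},
        n_subjects=n_subjects,
        grid_end_s=grid_end_s,
        grid_step_s=grid_step_s,
        sigma_subject=sigma_subject,
        seed=seed,
    )


@pytest.fixture
def single_var_config():
    return make_single_var_config


def make_toy_dataset(grid, per_subject):
    """Build a TrialDataset from {subject: {"ONB": vec, "FB": vec}} for 'HR'."""
    series = {}
    for subj, conds in per_subject.items():
        for cond, vec in conds.items():
            series[(subj, cond, "HR")] = np.asarray(vec, dtype=float)
    return rf.TrialDataset(grid=np.asarray(grid, dtype=float), series=series)


class _StubCore:
    """Minimal sampler backend for hand-built Gaussian posteriors."""

    def __init__(self, mean, cov):
        self.mean = np.asarray(mean, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self._Q = np.linalg.inv(self.cov)
        self._L = np.linalg.cholesky(self._Q)

    def conditional_posterior(self, theta):
        return self.mean, self._L, np.diag(self.cov).copy()


def make_toy_fit(alpha_mean, alpha_cov, grid=None):
    """FanovaFit with a single hyperparameter node and a known alpha posterior.

    mu is pinned to a near-degenerate independent block so that only the
    alpha block matters for excursions.
    """
    alpha_mean = np.asarray(alpha_mean, dtype=float)
    n = alpha_mean.size
    if grid is None:
        grid = 60.0 + 5.0 * np.arange(n)
    mean_full = np.concatenate([np.zeros(n), alpha_mean])
    cov_full = linalg.block_diag(1e-10 * np.eye(n), np.asarray(alpha_cov, dtype=float))
    core = _StubCore(mean_full, cov_full)
    hyper = HyperGrid(
        axes=(np.array([0.0]),) * 3,
        thetas=np.zeros((1, 3)),
        log_marginal=np.array([0.0]),
        weights=np.array([1.0]),
    )
    return FanovaFit(
        variable="toy",
        grid=np.asarray(grid, dtype=float),
        mu_mean=np.zeros(n),
        mu_sd=np.full(n, 1e-5),
        alpha_mean=alpha_mean,
        alpha_sd=np.sqrt(np.diag(np.asarray(alpha_cov, dtype=float))),
        hyper=hyper,
        _core=core,
        _node_means=mean_full[None, :],
        _node_sds=np.sqrt(np.diag(cov_full))[None, :],
    )
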