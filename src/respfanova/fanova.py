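"""Bayesian one-way functional ANOVA with intrinsic RW2 priors.

Model
-----
For a single variable observed on an equally spaced grid t_1..t_n, subject j
and breathing condition i in {ONB, FB}:

    y_{i,j}(t_k) | mu, alpha, tau  ~  N( mu(t_k) + alpha_i(t_k), 1/tau )

with ``alpha_ONB = 0`` for identifiability, so the latent field is
``x = (mu(t_1..t_n), alpha_FB(t_1..t_n))``.  Both mu and alpha_FB carry
intrinsic second-order random-walk (RW2) priors — Gaussian Markov random
fields penalizing second differences, with a null space spanned by constant
and linear trends — optionally scaled so their reference marginal variance
has geometric mean 1 (which makes the precision hyperparameters comparable
across grids).

Inference is fully Gaussian given the three log-precisions
``theta = (theta_mu, theta_alpha, theta_tau)``: the conditional posterior of
x is Gaussian with precision

    Q_post(theta) = blockdiag(e^{theta_mu} Q_rw2, e^{theta_alpha} Q_rw2)
                    + tau * A^T A,

and the marginal likelihood of each theta is available in closed form (the
intrinsic priors enter through their pseudo-determinants).  The hyperposterior
is handled by empirical-Bayes mode finding followed by a finite grid of
nodes around the mode; posterior summaries and joint samples are mixtures
over the grid nodes with normalized evidence-times-hyperprior weights.

The intrinsic priors are improper but the posterior is proper because both
conditions are observed at every grid point, so ``A^T A`` is positive on
every latent coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, optimize

from .dataset import TrialDataset
from .errors import NumericalError

_LOG2PI = float(np.log(2.0 * np.pi))

# log-gamma(shape=1, rate=5e-5) hyperprior on each log-precision theta:
# density on theta includes the Jacobian e^theta of the precision.
_HYPERPRIOR_SHAPE = 1.0
_HYPERPRIOR_RATE = 5e-5


def _log_hyperprior(theta: np.ndarray) -> float:
    theta = np.asarray(theta, dtype=float)
    return float(
        np.sum(_HYPERPRIOR_SHAPE * theta - _HYPERPRIOR_RATE * np.exp(theta))
    )


# ---------------------------------------------------------------------------
# RW2 prior structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RW2Prior:
    """Intrinsic second-order random-walk precision structure.

    ``Q = D2^T D2`` with ``D2`` the (n-2) x n second-difference operator;
    rank n-2, null space spanned by (1, 1, ..) and (0, 1, 2, ..).  When
    ``scaled``, Q is multiplied by the geometric mean of the reference
    marginal variances (diagonal of the Moore-Penrose pseudo-inverse), so
    that the scaled structure has reference geometric-mean variance 1.
    """

    n: int
    step: float
    scaled: bool
    Q: np.ndarray
    rank: int
    log_pdet: float


def second_difference_operator(n: int) -> np.ndarray:
    """The (n-2) x n matrix mapping a vector to its second differences."""
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


def build_rw2(n: int, step: float = 1.0, scaled: bool = False) -> RW2Prior:
    """Construct the RW2 precision structure for an n-point equally spaced grid.

    Raises
    ------
    ValueError
        If ``n < 3`` (the second-difference penalty needs 3 points).
    """
    if n < 3:
        raise ValueError(f"RW2 needs n >= 3 grid points, got {n}")
    D2 = second_difference_operator(n)
    Q = D2.T @ D2
    # one eigendecomposition yields both the reference marginal variances
    # (pseudo-inverse diagonal, null space excluded) and the pseudo-determinant
    vals, vecs = linalg.eigh(Q)
    vals_pos = vals[2:]  # the two smallest are the (numerically zero) null space
    if scaled:
        sigma2 = (vecs[:, 2:] ** 2 / vals_pos[None, :]).sum(axis=1)
        ref_var = float(np.exp(np.mean(np.log(sigma2))))
        Q = Q * ref_var
        vals_pos = vals_pos * ref_var
    log_pdet = float(np.sum(np.log(vals_pos)))
    return RW2Prior(n=n, step=step, scaled=scaled, Q=Q, rank=n - 2, log_pdet=log_pdet)


# ---------------------------------------------------------------------------
# Hyperparameter grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HyperGridConfig:
    """Configuration of the hyperparameter exploration.

    ``n_points`` grid points per log-precision axis, spanning ``+/- span``
    around the empirical-Bayes mode.  Passing an explicit ``center``
    (and/or ``optimize=False``) pins the grid; a single-node grid with a
    given center reduces the fit to one conditional Gaussian — useful for
    oracle comparisons.
    """

    n_points: int = 7
    span: float = 3.0
    center: tuple[float, float, float] | None = None
    optimize: bool = True
    max_opt_iter: int = 400


@dataclass
class HyperGrid:
    """Evaluated hyperparameter grid with normalized posterior weights."""

    axes: tuple[np.ndarray, ...]
    thetas: np.ndarray  # (K, 3) node coordinates (log precisions)
    log_marginal: np.ndarray  # (K,) log evidence + log hyperprior, unnormalized
    weights: np.ndarray  # (K,) normalized

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.log_marginal)):
            raise NumericalError("non-finite log marginal likelihood on grid")


def normalize_weights(log_values: np.ndarray) -> np.ndarray:
    """Softmax that is invariant to adding a constant to all log values."""
    log_values = np.asarray(log_values, dtype=float)
    w = np.exp(log_values - log_values.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# Sufficient statistics and Gaussian linear algebra
# ---------------------------------------------------------------------------


class _FanovaCore:
    """Sufficient statistics for one variable plus the Gaussian machinery.

    Because every subject contributes both conditions at every grid point,
    ``A^T A`` reduces to per-grid-point observation counts and the fit never
    materializes the full design matrix.  With the optional subject
    intercept the latent vector is extended by one iid coordinate per
    subject (precision e^{theta_b}).
    """

    def __init__(
        self,
        dataset: TrialDataset,
        variable: str,
        scaled: bool = True,
        subject_intercept: bool = False,
    ):
        if variable not in dataset.variables:
            raise KeyError(f"variable {variable!r} not in dataset")
        self.grid = dataset.grid
        self.n = dataset.grid.size
        self.subjects = dataset.subjects
        self.S = len(self.subjects)
        self.subject_intercept = subject_intercept
        Y_O = dataset.values_matrix(variable, "ONB")  # (S, n)
        Y_F = dataset.values_matrix(variable, "FB")
        self.c_O = float(Y_O.shape[0])
        self.c_F = float(Y_F.shape[0])
        self.s_O = Y_O.sum(axis=0)
        self.s_F = Y_F.sum(axis=0)
        self.row_sums = Y_O.sum(axis=1) + Y_F.sum(axis=1)  # per subject
        self.yy = float(np.sum(Y_O**2) + np.sum(Y_F**2))
        self.N = int(Y_O.size + Y_F.size)
        self.prior = build_rw2(self.n, step=dataset.step, scaled=scaled)
        # crude data-driven starting point for the optimizer
        if Y_O.shape[0] >= 2:
            resid_var = 0.5 * (np.var(Y_O, axis=0, ddof=1).mean()
                               + np.var(Y_F, axis=0, ddof=1).mean())
        else:
            resid_var = float(np.var(np.diff(Y_O, axis=1))) + 1e-12
        self._theta0_tau = float(-np.log(max(resid_var, 1e-12)))
        mean_curve = 0.5 * (Y_O.mean(axis=0) + Y_F.mean(axis=0))
        curve_var = float(np.var(mean_curve)) + 1e-8
        self._theta0_smooth = float(-np.log(curve_var))

    @property
    def n_hyper(self) -> int:
        return 4 if self.subject_intercept else 3

    def theta0(self) -> np.ndarray:
        base = [self._theta0_smooth, self._theta0_smooth, self._theta0_tau]
        if self.subject_intercept:
            base.append(self._theta0_tau)
        return np.array(base)

    def _posterior_system(self, theta: Sequence[float]):
        """Posterior precision (dense) and linear term b = tau * A^T y."""
        n, Q = self.n, self.prior.Q
        k_mu, k_al, tau = np.exp(theta[0]), np.exp(theta[1]), np.exp(theta[2])
        p = 2 * n + (self.S if self.subject_intercept else 0)
        Qp = np.zeros((p, p))
        Qp[:n, :n] = k_mu * Q
        Qp[n : 2 * n, n : 2 * n] = k_al * Q
        idx = np.arange(n)
        Qp[idx, idx] += tau * (self.c_O + self.c_F)
        Qp[n + idx, n + idx] += tau * self.c_F
        Qp[idx, n + idx] += tau * self.c_F
        Qp[n + idx, idx] += tau * self.c_F
        b = np.concatenate([tau * (self.s_O + self.s_F), tau * self.s_F])
        if self.subject_intercept:
            k_b = np.exp(theta[3])
            sl = slice(2 * n, p)
            jdx = np.arange(self.S)
            Qp[sl, sl][jdx, jdx] += k_b + tau * 2.0 * n
            # coupling: subject j's rows touch mu at every point (both
            # conditions) and alpha at every point (FB only)
            Qp[2 * n + jdx[:, None], idx[None, :]] = 2.0 * tau
            Qp[idx[:, None], 2 * n + jdx[None, :]] = 2.0 * tau
            Qp[2 * n + jdx[:, None], n + idx[None, :]] = tau
            Qp[n + idx[:, None], 2 * n + jdx[None, :]] = tau
            b = np.concatenate([b, tau * self.row_sums])
        return Qp, b

    def _log_prior_normconst(self, theta: Sequence[float]) -> float:
        """Normalizing constant of the (improper) latent prior.

        Uses the pseudo-determinant convention: each intrinsic RW2 block
        contributes rank * theta + log_pdet; a proper subject block
        contributes its full determinant.
        """
        r = self.prior.rank
        val = r * (theta[0] + theta[1]) + 2.0 * self.prior.log_pdet
        total_rank = 2 * r
        if self.subject_intercept:
            val += self.S * theta[3]
            total_rank += self.S
        return 0.5 * val - 0.5 * total_rank * _LOG2PI

    def log_marginal_likelihood(self, theta: Sequence[float]) -> float:
        """Closed-form Gaussian evidence log p(y | theta).

        Consistent across nodes up to an additive constant (all that the
        mixture weights need).  With no observations the data terms vanish
        and the prior normalizing constant (pseudo-determinant convention)
        is returned.
        """
        lp = self._log_prior_normconst(theta)
        if self.N == 0:
            return lp
        tau = np.exp(theta[2])
        Qp, b = self._posterior_system(theta)
        try:
            cho = linalg.cho_factor(Qp, lower=True)
        except linalg.LinAlgError as exc:  # pragma: no cover - guarded by design
            raise NumericalError(f"singular posterior precision at theta={theta}") from exc
        m = linalg.cho_solve(cho, b)
        logdet_post = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        p = Qp.shape[0]
        val = (
            lp
            + 0.5 * self.N * (theta[2] - _LOG2PI)
            + 0.5 * p * _LOG2PI
            - 0.5 * logdet_post
            + 0.5 * (b @ m - tau * self.yy)
        )
        if not np.isfinite(val):
            raise NumericalError(f"non-finite marginal likelihood at theta={theta}")
        return float(val)

    def log_posterior(self, theta: Sequence[float]) -> float:
        return self.log_marginal_likelihood(theta) + _log_hyperprior(theta)

    def conditional_posterior(self, theta: Sequence[float]):
        """Mean, Cholesky factor of precision, and marginal variances of x | theta."""
        Qp, b = self._posterior_system(theta)
        try:
            L = np.linalg.cholesky(Qp)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular posterior precision at theta={theta}") from exc
        m = linalg.cho_solve((L, True), b)
        inv = linalg.cho_solve((L, True), np.eye(Qp.shape[0]))
        return m, L, np.diag(inv).copy()


# ---------------------------------------------------------------------------
# Fit object
# ---------------------------------------------------------------------------


@dataclass
class FanovaFit:
    """Fitted functional ANOVA for one variable.

    Posterior summary curves are mixtures over the hyperparameter grid;
    :meth:`sample` draws exact joint samples of (mu, alpha_FB) from the same
    mixture, deterministically for a given seed.
    """

    variable: str
    grid: np.ndarray
    mu_mean: np.ndarray
    mu_sd: np.ndarray
    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    hyper: HyperGrid
    _core: _FanovaCore
    _node_means: np.ndarray  # (K, p)
    _node_sds: np.ndarray  # (K, 2n) per-node marginal posterior SDs

    @property
    def n(self) -> int:
        return self.grid.size

    def _allocate_draws(self, n_draws: int) -> np.ndarray:
        """Deterministic largest-remainder allocation of draws to nodes."""
        w = self.hyper.weights
        raw = w * n_draws
        counts = np.floor(raw).astype(int)
        short = n_draws - counts.sum()
        if short > 0:
            order = np.argsort(-(raw - counts), kind="stable")
            counts[order[:short]] += 1
        return counts

    def node_draw_groups(
        self, n_draws: int, seed: int = 0, method: str = "sobol"
    ) -> list[tuple[float, np.ndarray]]:
        """Joint posterior draws of (mu, alpha_FB) grouped by grid node.

        Returns a list of ``(weight, draws)`` pairs where ``draws`` has
        shape (n_i, 2n); draw counts are allocated to nodes proportionally
        to their weights.  ``method`` is ``"sobol"`` (scrambled quasi-random,
        default) or ``"mc"`` (pseudo-random); both are deterministic given
        ``seed``.
        """
        counts = self._allocate_draws(n_draws)
        p = self._node_means.shape[1]
        if method == "sobol":
            from scipy.stats import qmc, norm

            sob = qmc.Sobol(d=p, scramble=True, seed=seed)
            u = sob.random(int(counts.sum()))
            # clip away exact 0/1 before the normal quantile transform
            eps = np.finfo(float).tiny
            z_all = norm.ppf(np.clip(u, eps, 1.0 - eps))
        elif method == "mc":
            rng = np.random.default_rng(seed)
            z_all = rng.standard_normal((int(counts.sum()), p))
        else:
            raise ValueError(f"unknown sampling method {method!r}")
        groups: list[tuple[float, np.ndarray]] = []
        pos = 0
        for k in np.nonzero(counts)[0]:
            n_k = int(counts[k])
            z = z_all[pos : pos + n_k]
            pos += n_k
            _, L, _ = self._core.conditional_posterior(self.hyper.thetas[k])
            # x = m + L^{-T} z  gives draws from N(m, Q^{-1}), Q = L L^T
            x = self._node_means[k] + linalg.solve_triangular(
                L, z.T, lower=True, trans="T"
            ).T
            groups.append((float(self.hyper.weights[k]), x[:, : 2 * self.n]))
        return groups

    def sample(
        self, n_draws: int, seed: int = 0, method: str = "sobol"
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pooled joint draws: arrays (n_draws, n) for mu and alpha_FB."""
        groups = self.node_draw_groups(n_draws, seed=seed, method=method)
        x = np.vstack([g for _, g in groups])
        return x[:, : self.n], x[:, self.n :]

    def export_summary(self):
        """Fit summary as a DataFrame (grid in s and min, curves, SDs)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.grid,
                "time_min": self.grid / 60.0,
                "mu_mean": self.mu_mean,
                "mu_sd": self.mu_sd,
                "alpha_mean": self.alpha_mean,
                "alpha_sd": self.alpha_sd,
            }
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _build_grid_axes(center: np.ndarray, cfg: HyperGridConfig) -> list[np.ndarray]:
    if cfg.n_points == 1:
        return [np.array([c]) for c in center]
    offsets = np.linspace(-cfg.span, cfg.span, cfg.n_points)
    return [c + offsets for c in center]


def fit(
    dataset: TrialDataset,
    variable: str,
    *,
    scaled: bool = True,
    hyper: HyperGridConfig | None = None,
    subject_intercept: bool = False,
) -> FanovaFit:
    """Fit the functional ANOVA for one variable.

    Finds the empirical-Bayes mode of the hyperposterior over the
    log-precisions, lays a finite grid around it, and mixes the per-node
    Gaussian posteriors of ``(mu, alpha_FB)`` with normalized weights.

    Parameters
    ----------
    dataset : TrialDataset
        Must contain both conditions for ``variable`` on an equally spaced grid.
    variable : str
        Which variable to fit (on its analysis scale).
    scaled : bool
        Use the variance-scaled RW2 structure (default).
    hyper : HyperGridConfig
        Grid resolution/span; a 1-point grid with a fixed center disables
        hyperparameter mixing.
    subject_intercept : bool
        Add iid subject intercepts to the latent field (sensitivity
        analysis; the default model has no subject term).
    """
    cfg = hyper or HyperGridConfig()
    core = _FanovaCore(
        dataset, variable, scaled=scaled, subject_intercept=subject_intercept
    )

    if cfg.center is not None:
        center = np.asarray(cfg.center, dtype=float)
        if center.size < core.n_hyper:
            center = np.concatenate([center, core.theta0()[center.size :]])
    else:
        center = core.theta0()
    if cfg.optimize and cfg.center is None:
        res = optimize.minimize(
            lambda th: -core.log_posterior(th),
            center,
            method="Nelder-Mead",
            options={
                "maxiter": cfg.max_opt_iter,
                "xatol": 0.05,
                "fatol": 0.05,
            },
        )
        center = res.x

    axes = _build_grid_axes(center[:3], cfg)
    mesh = np.meshgrid(*axes, indexing="ij")
    thetas3 = np.stack([m.ravel() for m in mesh], axis=1)
    if core.n_hyper == 4:
        thetas = np.column_stack([thetas3, np.full(len(thetas3), center[3])])
    else:
        thetas = thetas3
    log_post = np.array([core.log_posterior(th) for th in thetas])
    weights = normalize_weights(log_post)
    grid_obj = HyperGrid(
        axes=tuple(axes), thetas=thetas, log_marginal=log_post, weights=weights
    )

    n = core.n
    p = 2 * n + (core.S if subject_intercept else 0)
    node_means = np.zeros((len(thetas), p))
    node_sds = np.zeros((len(thetas), 2 * n))
    mean_acc = np.zeros(2 * n)
    second_acc = np.zeros(2 * n)
    for k, th in enumerate(thetas):
        m, _, var = core.conditional_posterior(th)
        node_means[k] = m
        node_sds[k] = np.sqrt(var[: 2 * n])
        w = weights[k]
        mean_acc += w * m[: 2 * n]
        second_acc += w * (var[: 2 * n] + m[: 2 * n] ** 2)
    mix_var = np.maximum(second_acc - mean_acc**2, 0.0)
    mix_sd = np.sqrt(mix_var)

    return FanovaFit(
        variable=variable,
        grid=core.grid.copy(),
        mu_mean=mean_acc[:n],
        mu_sd=mix_sd[:n],
        alpha_mean=mean_acc[n:],
        alpha_sd=mix_sd[n:],
        hyper=grid_obj,
        _core=core,
        _node_means=node_means,
        _node_sds=node_sds,
    )


def log_marginal_likelihood(
    dataset: TrialDataset,
    variable: str,
    theta: Sequence[float],
    *,
    scaled: bool = True,
) -> float:
    """Evidence log p(y | theta) for one hyperparameter node (closed form)."""
    core = _FanovaCore(dataset, variable, scaled=scaled)
    return core.log_marginal_likelihood(np.asarray(theta, dtype=float))
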