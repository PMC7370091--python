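"""Paired comparisons, effect sizes, and repeated-measures power.

Covers the scalar statistics around the functional analysis: paired t-tests
for post-test outcomes (maximal inspiratory pressure, perceived exertion),
Cohen's d from summary statistics, and the a-priori power / sample-size
computation for a two-group repeated-measures ANOVA within-between
interaction via the noncentral F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError


@dataclass(frozen=True)
class PairedResult:
    """Paired t-test summary with a difference-based effect size."""

    mean_1: float
    sd_1: float
    mean_2: float
    sd_2: float
    t: float
    df: int
    p: float
    d: float


def paired_t(x: np.ndarray, y: np.ndarray) -> PairedResult:
    """Two-sided paired t-test of y vs x on the per-subject differences.

    The reported effect size ``d`` is the pooled-SD Cohen's d of the two
    measurement columns (see :func:`cohens_d_pooled`).

    Raises
    ------
    DegenerateInputError
        If the differences have zero variance (t undefined/infinite).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = y - x
    sd_diff = np.std(diff, ddof=1)
    if sd_diff == 0.0:
        raise DegenerateInputError("differences have zero variance")
    t = float(diff.mean() / (sd_diff / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PairedResult(
        mean_1=float(x.mean()),
        sd_1=float(np.std(x, ddof=1)),
        mean_2=float(y.mean()),
        sd_2=float(np.std(y, ddof=1)),
        t=t,
        df=df,
        p=p,
        d=cohens_d_pooled(x.mean(), np.std(x, ddof=1), y.mean(), np.std(y, ddof=1)),
    )


def cohens_d_pooled(mean_1: float, sd_1: float, mean_2: float, sd_2: float) -> float:
    """Cohen's d from summary statistics with the pooled-SD denominator:

    ``d = (mean_2 - mean_1) / sqrt((sd_1^2 + sd_2^2) / 2)``.
    """
    if sd_1 < 0 or sd_2 < 0:
        raise ValueError("standard deviations must be >= 0")
    denom = np.sqrt((sd_1**2 + sd_2**2) / 2.0)
    if denom == 0.0:
        raise DegenerateInputError("both SDs are zero; d undefined")
    return float((mean_2 - mean_1) / denom)


def cohens_d_diff(diff_mean: float, diff_sd: float) -> float:
    """Difference-score Cohen's d: mean of differences / SD of differences."""
    if diff_sd <= 0:
        raise DegenerateInputError("difference SD must be > 0")
    return float(diff_mean / diff_sd)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the repeated-measures interaction power computation.

    ``f`` is the standardized effect size; ``groups``/``measurements`` the
    between- and within-subject factor sizes; ``rho`` the correlation
    between repeated measures; ``epsilon`` the nonsphericity correction.
    """

    f: float = 0.25
    alpha: float = 0.05
    power: float = 0.80
    groups: int = 2
    measurements: int = 10
    rho: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0, 1)")
        if self.groups < 2 or self.measurements < 2:
            raise ValueError("need >= 2 groups and >= 2 measurements")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if not 0.0 < self.epsilon <= 1.0:
            raise ValueError("epsilon must be in (0, 1]")


def rm_anova_interaction_power(spec: PowerSpec, n_total: int) -> float:
    """Achieved power of the within-between interaction F test at total N.

    Noncentral-F convention: df1 = (g-1)(m-1)eps, df2 = (N-g)(m-1)eps and
    noncentrality lambda = f^2 * N * m * eps / (1 - rho).
    """
    g, m, eps = spec.groups, spec.measurements, spec.epsilon
    if n_total <= g:
        raise ValueError("n_total must exceed the number of groups")
    df1 = (g - 1) * (m - 1) * eps
    df2 = (n_total - g) * (m - 1) * eps
    lam = spec.f**2 * n_total * m * eps / (1.0 - spec.rho)
    f_crit = stats.f.isf(spec.alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def sample_size(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest total N whose interaction power reaches the target."""
    n = spec.groups + 1
    while n <= n_max:
        if rm_anova_interaction_power(spec, n) >= spec.power:
            return n
        n += 1
    raise RuntimeError(f"target power not reached for N <= {n_max}")
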