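"""Excursion sets: where is the condition effect *jointly* significant?

A pointwise 95% band answers "is alpha(t) nonzero at this t?"; the excursion
set answers the simultaneous question: the largest set of grid points D such
that the joint posterior probability of the directional event holding at
*every* point of D is at least 1 - level.

Construction (one-parameter family over nested candidate sets):

1. compute the marginal posterior probability of the event at each grid
   point under the hyperparameter mixture;
2. order grid points by decreasing marginal probability (ties broken by
   time index, earlier first) — candidate sets are the prefixes D(1) c
   D(2) c ... of this ordering;
3. evaluate the joint probability of each prefix by numerical integration
   over the Gaussian mixture (quasi-random or fixed-seed Monte Carlo draws
   allocated to hyperparameter nodes by weight — the law of total
   probability);
4. return the largest prefix whose joint probability is >= 1 - level.

The excursion function F(t) records, per point, the highest confidence
level at which that point enters the set; membership at level ``a`` is
``F(t) >= 1 - a``, which makes sets automatically nested across levels.

Directions: ``positive`` ({alpha(t) > 0}), ``negative`` ({alpha(t) < 0}),
or ``nonzero`` — the two-sided version, realized by requiring the event
matched to the sign of the posterior mean at each point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import NumericalError
from .fanova import FanovaFit

_DIRECTIONS = ("positive", "negative", "nonzero")


@dataclass(frozen=True)
class MCConfig:
    """Numerical-integration settings for joint probabilities.

    ``sobol`` (default) uses scrambled quasi-random sequences; ``mc`` plain
    Monte Carlo.  Both are deterministic given ``seed``.
    """

    n_draws: int = 2**15
    seed: int = 0
    method: str = "sobol"

    def __post_init__(self) -> None:
        if self.n_draws < 10_000:
            raise ValueError("joint probabilities need >= 10^4 draws")


@dataclass
class ExcursionResult:
    """Excursion set at one confidence level.

    ``F`` is the excursion function (values in [0, 1]); ``member`` the
    per-grid-point membership at ``level``; ``intervals`` the maximal runs
    of members in minutes; ``joint_prob`` the joint probability of the
    returned set and ``mc_se`` its integration standard error.
    """

    level: float
    direction: str
    member: np.ndarray
    F: np.ndarray
    intervals: list[tuple[float, float]]
    joint_prob: float
    mc_se: float
    marginal_prob: np.ndarray = field(repr=False, default=None)

    def export(self, fit: FanovaFit):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": fit.grid,
                "time_min": fit.grid / 60.0,
                "alpha_mean": fit.alpha_mean,
                "alpha_sd": fit.alpha_sd,
                "marginal_prob": self.marginal_prob,
                "F": self.F,
                "member": self.member,
            }
        )


def _event_signs(fit: FanovaFit, direction: str) -> np.ndarray:
    if direction == "positive":
        return np.ones(fit.n)
    if direction == "negative":
        return -np.ones(fit.n)
    if direction == "nonzero":
        s = np.sign(fit.alpha_mean)
        s[s == 0] = 1.0
        return s
    raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")


def marginal_event_probabilities(fit: FanovaFit, direction: str) -> np.ndarray:
    """Mixture marginal probability of the directional event per grid point."""
    signs = _event_signs(fit, direction)
    n = fit.n
    means = fit._node_means[:, n : 2 * n]
    sds = fit._node_sds[:, n : 2 * n]
    z = signs[None, :] * means / sds
    return fit.hyper.weights @ norm.cdf(z)


def excursion_set(
    fit: FanovaFit,
    level: float = 0.05,
    direction: str = "nonzero",
    mc: MCConfig | None = None,
) -> ExcursionResult:
    """Largest set of grid points where the event holds jointly with prob >= 1-level.

    Parameters
    ----------
    fit : FanovaFit
        Fitted model with its joint sampler.
    level : float
        Significance level alpha in (0, 0.5].
    direction : str
        ``"positive"``, ``"negative"`` or ``"nonzero"`` (two-sided,
        sign-matched to the posterior mean).
    mc : MCConfig
        Integration settings (draw count, seed, sobol/mc).
    """
    if not 0.0 < level <= 0.5:
        raise ValueError(f"level must be in (0, 0.5], got {level}")
    mc = mc or MCConfig()
    n = fit.n
    signs = _event_signs(fit, direction)
    marg = marginal_event_probabilities(fit, direction)

    # prefix ordering: decreasing marginal probability, earlier time first
    order = np.argsort(-marg, kind="stable")

    # joint probability of each prefix, via the fail-position of each draw
    groups = fit.node_draw_groups(mc.n_draws, seed=mc.seed, method=mc.method)
    prefix_prob = np.zeros(n)
    total_weight = 0.0
    total_draws = 0
    for w, draws in groups:
        alpha = draws[:, n:]
        if not np.all(np.isfinite(alpha)):
            raise NumericalError("non-finite posterior draws")
        ok = (signs[None, :] * alpha > 0.0)[:, order]  # (n_i, n) in prefix order
        all_ok = ok.all(axis=1)
        fail = np.where(all_ok, n, np.argmin(ok, axis=1))  # first failure index
        # P(event holds on prefix of length j) = #(fail >= j) / n_i
        counts = np.bincount(fail, minlength=n + 1)
        survive = np.cumsum(counts[::-1])[::-1]  # survive[j] = #(fail >= j)
        prefix_prob += w * survive[1:] / draws.shape[0]
        total_weight += w
        total_draws += draws.shape[0]
    prefix_prob /= total_weight
    # analytic bound: joint probability cannot exceed any member's marginal
    prefix_prob = np.minimum(np.minimum.accumulate(prefix_prob), marg[order])

    F = np.zeros(n)
    F[order] = np.clip(prefix_prob, 0.0, 1.0)
    member = F >= 1.0 - level
    j_star = int(np.sum(prefix_prob >= 1.0 - level))
    joint = float(prefix_prob[j_star - 1]) if j_star > 0 else float("nan")
    se = (
        float(np.sqrt(max(joint * (1.0 - joint), 0.0) / total_draws))
        if j_star > 0
        else 0.0
    )
    intervals = _member_intervals(member, fit.grid)
    return ExcursionResult(
        level=level,
        direction=direction,
        member=member,
        F=F,
        intervals=intervals,
        joint_prob=joint,
        mc_se=se,
        marginal_prob=marg,
    )


def _member_intervals(member: np.ndarray, grid: np.ndarray) -> list[tuple[float, float]]:
    """Maximal runs of member points as (start_min, end_min) intervals."""
    intervals = []
    in_run = False
    start = 0
    for k, m in enumerate(member):
        if m and not in_run:
            in_run, start = True, k
        elif not m and in_run:
            intervals.append((grid[start] / 60.0, grid[k - 1] / 60.0))
            in_run = False
    if in_run:
        intervals.append((grid[start] / 60.0, grid[-1] / 60.0))
    return intervals


def _format_minute(minutes: float) -> str:
    """Format minutes at 5-s resolution: '1', '2:50', '10:05'."""
    total_s = int(round(minutes * 60.0 / 5.0)) * 5
    m, s = divmod(total_s, 60)
    return f"{m}" if s == 0 else f"{m}:{s:02d}"


def summarize_intervals(result: ExcursionResult) -> str:
    """Human-readable interval summary, e.g. ``"minute 1 to 11"``.

    Multiple intervals are joined with "; "; an empty set reads ``"none"``.
    """
    if not result.intervals:
        return "none"
    parts = [
        f"minute {_format_minute(a)} to {_format_minute(b)}"
        for a, b in result.intervals
    ]
    return "; ".join(parts)
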